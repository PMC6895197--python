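"""Generalized Procrustes alignment, mean shapes, PCA shape space, PROTEST.

GPA removes position, orientation and size: each configuration is centred,
scaled to unit centroid size, and rotated by *proper* rotations (no
reflection — homologous biological configurations must not be mirrored) onto
the running consensus until the consensus stabilizes.  Scaling is not
re-adjusted after rotation (partial Procrustes), so centroid size is the size
variable removed from shape.

PROTEST compares two 2D ordinations by Procrustean superimposition (here
reflection *is* allowed, as is conventional) with a row-permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import LandmarkTable

__all__ = [
    "GPAResult",
    "ShapeSpace",
    "gpa",
    "species_means",
    "shape_pca",
    "protest",
    "centroid_size",
    "optimal_rotation",
    "ordinary_procrustes",
]

GPA_TOL = 1e-10
GPA_MAX_ITER = 100


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared distances of landmarks to their centroid."""
    c = config - config.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def optimal_rotation(source: np.ndarray, target: np.ndarray, allow_reflection: bool = False) -> np.ndarray:
    """Orthogonal matrix R minimizing ||source @ R - target||_F.

    With ``allow_reflection=False`` the result is a proper rotation
    (det(R) = +1), flipping the smallest singular direction if needed.
    """
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def ordinary_procrustes(source: np.ndarray, target: np.ndarray, scale: bool = True,
                        allow_reflection: bool = False):
    """Superimpose ``source`` onto ``target`` by translation/rotation(/scale).

    Returns ``(transformed, transform)`` where ``transform`` is a dict with
    keys ``rotation``, ``scale``, ``source_centroid``, ``target_centroid``
    such that ``transformed = (source - source_centroid) @ rotation * scale
    + target_centroid``.  ``apply_procrustes_transform`` maps further points
    through the same similarity transform.
    """
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    a = source - mu_s
    b = target - mu_t
    r = optimal_rotation(a, b, allow_reflection=allow_reflection)
    if scale:
        denom = (a**2).sum()
        if denom == 0:
            raise ValueError("degenerate source configuration (all points coincident)")
        beta = float(np.trace(b.T @ (a @ r))) / denom
    else:
        beta = 1.0
    transform = {"rotation": r, "scale": beta, "source_centroid": mu_s, "target_centroid": mu_t}
    return apply_procrustes_transform(source, transform), transform


def apply_procrustes_transform(points: np.ndarray, transform: dict) -> np.ndarray:
    return (points - transform["source_centroid"]) @ transform["rotation"] * transform["scale"] + transform["target_centroid"]


@dataclass
class GPAResult:
    aligned: np.ndarray  # (n, p, 3)
    consensus: np.ndarray  # (p, 3)
    centroid_sizes: np.ndarray  # (n,)
    iterations: int
    converged: bool
    specimen_ids: list[str] | None = None
    species_ids: list[str] | None = None
    groups: list[str] | None = None
    landmark_labels: list[str] | None = None


def gpa(table: LandmarkTable | np.ndarray) -> GPAResult:
    """Generalized Procrustes alignment of all specimens.

    Iterates rotate-onto-consensus / recompute-consensus until the consensus
    moves by less than ``GPA_TOL`` (summed squared coordinate change) or 100
    iterations.  Input must be free of missing landmarks (impute first).
    """
    meta = {}
    if isinstance(table, LandmarkTable):
        if table.has_missing:
            raise ValueError("landmark table contains missing landmarks; run estimate_missing first")
        coords = table.coords
        meta = dict(specimen_ids=list(table.specimen_ids), species_ids=list(table.species_ids),
                    groups=list(table.groups), landmark_labels=list(table.landmark_labels))
    else:
        coords = np.asarray(table, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("expected (n, p, 3) coordinate array")
    n, p, _ = coords.shape
    if n < 2:
        raise ValueError("need at least 2 specimens")
    if p < 4:
        raise ValueError("need at least 4 landmarks")

    centred = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centred**2).sum(axis=(1, 2)))
    if np.any(sizes <= 0):
        bad = int(np.argmin(sizes))
        raise ValueError(f"degenerate configuration (zero centroid size) at index {bad}")
    scaled = centred / sizes[:, None, None]
    for x in scaled:
        if np.linalg.matrix_rank(x) < 2:
            raise ValueError("degenerate configuration: all landmarks collinear or coincident")

    aligned = scaled.copy()
    consensus = aligned[0].copy()
    converged = False
    it = 0
    for it in range(1, GPA_MAX_ITER + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)
        new_consensus = aligned.mean(axis=0)
        delta = float(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        if delta < GPA_TOL:
            converged = True
            break
    return GPAResult(aligned=aligned, consensus=consensus, centroid_sizes=sizes,
                     iterations=it, converged=converged, **meta)


def species_means(result: GPAResult, species_ids: list[str] | None = None) -> LandmarkTable:
    """Per-species mean of aligned coordinates; singleton species pass through.

    Group labels are carried over when they are constant within species.
    """
    species = species_ids if species_ids is not None else result.species_ids
    if species is None:
        raise ValueError("species labels required")
    if len(species) != result.aligned.shape[0]:
        raise ValueError("species label count does not match alignment")
    order = list(dict.fromkeys(species))
    groups = result.groups or [""] * len(species)
    labels = result.landmark_labels or [str(k + 1) for k in range(result.aligned.shape[1])]
    means, out_groups = [], []
    for sp in order:
        rows = [i for i, s in enumerate(species) if s == sp]
        means.append(result.aligned[rows].mean(axis=0))
        gset = {groups[i] for i in rows}
        out_groups.append(gset.pop() if len(gset) == 1 else "")
    arr = np.array(means)
    return LandmarkTable(order, list(order), out_groups, labels, arr,
                         np.zeros(arr.shape[:2], dtype=bool))


@dataclass
class ShapeSpace:
    scores: np.ndarray  # (n, k)
    loadings: np.ndarray  # (3p, k)
    eigenvalues: np.ndarray  # (k,)
    pct_variance: np.ndarray  # (k,) sums to 100
    mean: np.ndarray  # (3p,)
    specimen_ids: list[str] | None = None


def shape_pca(data: GPAResult | LandmarkTable | np.ndarray) -> ShapeSpace:
    """PCA of flattened aligned coordinates about their mean."""
    ids = None
    if isinstance(data, GPAResult):
        coords, ids = data.aligned, data.specimen_ids
    elif isinstance(data, LandmarkTable):
        coords, ids = data.coords, data.specimen_ids
    else:
        coords = np.asarray(data, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 configurations for PCA")
    flat = coords.reshape(n, -1)
    mean = flat.mean(axis=0)
    x = flat - mean
    cov = x.T @ x / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.where(np.abs(evals) < 1e-15, np.abs(evals), evals)
    total = evals.sum()
    pct = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    return ShapeSpace(scores=x @ evecs, loadings=evecs, eigenvalues=evals,
                      pct_variance=pct, mean=mean, specimen_ids=ids)


def protest(scores_a: np.ndarray, scores_b: np.ndarray, nperm: int = 999,
            seed: int | None = None, rng: np.random.Generator | None = None):
    """Procrustean test of concordance between two matched ordinations.

    Both matrices are centred and scaled to unit total sum of squares; after
    optimal orthogonal superimposition (reflection allowed) of ``b`` onto
    ``a`` the statistic is ``t = sqrt(1 - m2)`` with ``m2`` the residual sum
    of squares.  p is estimated from ``nperm`` row permutations of ``b``:
    ``p = (1 + #{t_perm >= t_obs}) / (nperm + 1)``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("row counts differ")
    if a.shape[0] < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng(seed) if rng is None else rng

    def normalize(x):
        x = x - x.mean(axis=0)
        ss = (x**2).sum()
        if ss == 0:
            raise ValueError("degenerate (constant) score matrix")
        return x / np.sqrt(ss)

    a = normalize(a)
    b = normalize(b)

    def stat(bmat):
        # optimal rotation (reflection ok) and scale of bmat onto a
        s = np.linalg.svd(a.T @ bmat, compute_uv=False)
        t2 = min(s.sum() ** 2, 1.0)
        return np.sqrt(t2)

    t_obs = stat(b)
    n = a.shape[0]
    count = 1  # observed counts as one permutation
    for _ in range(nperm):
        if stat(b[rng.permutation(n)]) >= t_obs - 1e-12:
            count += 1
    return {"correlation": float(t_obs), "p": count / (nperm + 1), "nperm": nperm}
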