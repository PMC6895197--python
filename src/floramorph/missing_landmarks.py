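"""Missing-landmark estimation (TPS / mean substitution / regression) and validation.

Damaged specimens (a broken petal tip, a chewed-up stamen) lack a few of the
homologous landmarks, but Procrustes-based analyses need complete
configurations.  Three estimators are provided, all driven by a reference
set of complete specimens:

``TPS``
    The Procrustes mean of the reference set is similarity-aligned to the
    damaged specimen on the shared landmarks, a 3D thin-plate spline
    (biharmonic kernel ``U(r) = r`` plus affine term) is fitted mapping the
    aligned reference shared landmarks onto the specimen's shared landmarks,
    and the reference's missing-landmark positions are mapped through the
    warp.
``MS``
    Mean substitution: the aligned reference mean's positions fill the gap.
``REG``
    Per missing landmark, least-squares regression of its coordinates on the
    shared-landmark coordinates across reference specimens, with predictors
    reduced to the leading principal components (at most ``min(n_ref-1, 10)``)
    because reference sets are far smaller than 3p predictors.

``validate_estimation`` replays the remove-and-re-estimate experiment
(remove 1..kmax random landmarks from an intact specimen, estimate, compare
PCA ordinations by PROTEST and landmark positions by Welch-T/F tests), and
``observer_error`` quantifies landmarking precision from replicate
digitizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import LandmarkTable
from .procrustes import (
    apply_procrustes_transform,
    centroid_size,
    gpa,
    ordinary_procrustes,
    protest,
    shape_pca,
)

__all__ = ["ThinPlateSpline3D", "ImputationReport", "estimate_missing",
           "validate_estimation", "observer_error"]

METHODS = ("TPS", "MS", "REG")


class ThinPlateSpline3D:
    """3D thin-plate spline interpolant with kernel U(r) = r and affine term.

    Exactly interpolates the control points; evaluating elsewhere gives the
    smoothest (biharmonic) warp consistent with them.
    """

    def __init__(self, source: np.ndarray, target: np.ndarray):
        source = np.asarray(source, dtype=float)
        target = np.asarray(target, dtype=float)
        if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
            raise ValueError("source and target must be matching (k, 3) arrays")
        k = source.shape[0]
        if k < 4:
            raise ValueError("need at least 4 control points")
        K = np.linalg.norm(source[:, None] - source[None, :], axis=2)
        P = np.hstack([np.ones((k, 1)), source])
        A = np.zeros((k + 4, k + 4))
        A[:k, :k] = K
        A[:k, k:] = P
        A[k:, :k] = P.T
        rhs = np.zeros((k + 4, 3))
        rhs[:k] = target
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e14:
            raise ValueError(f"singular thin-plate spline system (condition {cond:.3g}); "
                             "control points may be coplanar duplicates")
        sol = np.linalg.solve(A, rhs)
        self._source = source
        self._w = sol[:k]
        self._affine = sol[k:]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        U = np.linalg.norm(points[:, None] - self._source[None, :], axis=2)
        return (np.hstack([np.ones((points.shape[0], 1)), points]) @ self._affine
                + U @ self._w)


def _default_reference(table: LandmarkTable, species: str, need: int = 2) -> list[str]:
    complete = table.complete_specimens()
    conspecific = [s for s in complete
                   if table.species_ids[table.specimen_ids.index(s)] == species]
    return conspecific if len(conspecific) >= need else complete


def estimate_missing(table: LandmarkTable, method: str = "TPS",
                     reference_set: list[str] | None = None) -> LandmarkTable:
    """Fill every masked landmark; returns a complete table (mask all False).

    ``reference_set`` names complete specimens to estimate from; by default
    each damaged specimen uses its complete conspecifics when at least two
    exist, otherwise all complete specimens.
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown estimation method {method!r}; pick from {METHODS}")
    if not table.has_missing:
        return table
    coords = table.coords.copy()
    mask = table.missing_mask.copy()
    if reference_set is not None:
        ref_idx = [table.specimen_ids.index(s) for s in reference_set]
        if any(mask[i].any() for i in ref_idx):
            bad = [table.specimen_ids[i] for i in ref_idx if mask[i].any()]
            raise ValueError(f"reference specimens must be complete: {bad}")
        if not ref_idx:
            raise ValueError("empty reference set")

    for i in range(table.n_specimens):
        if not mask[i].any():
            continue
        if reference_set is None:
            # regression needs several reference specimens; TPS/MS work from two
            refs = _default_reference(table, table.species_ids[i],
                                      need=4 if method == "REG" else 2)
            refs = [s for s in refs if s != table.specimen_ids[i]]
        else:
            refs = [s for s in reference_set if s != table.specimen_ids[i]]
        if not refs:
            raise ValueError(f"no complete reference specimens for {table.specimen_ids[i]!r}")
        coords[i, mask[i]] = _estimate_one(table, i, refs, method)
        mask[i] = False
    return LandmarkTable(list(table.specimen_ids), list(table.species_ids),
                         list(table.groups), list(table.landmark_labels), coords, mask)


def _estimate_one(table: LandmarkTable, i: int, refs: list[str], method: str) -> np.ndarray:
    shared = np.flatnonzero(~table.missing_mask[i])
    missing = np.flatnonzero(table.missing_mask[i])
    if shared.size < 4:
        raise ValueError(f"specimen {table.specimen_ids[i]!r} shares only "
                         f"{shared.size} landmarks with the reference (need >= 4)")
    spec_shared = table.coords[i, shared]
    ref_idx = [table.specimen_ids.index(s) for s in refs]
    if len(ref_idx) == 1:
        ref_aligned = table.coords[ref_idx].copy()  # (1, p, 3)
        ref_mean = ref_aligned[0]
    else:
        fit = gpa(table.coords[ref_idx])
        ref_aligned, ref_mean = fit.aligned, fit.consensus
    # place the reference mean in the damaged specimen's frame
    _, transform = ordinary_procrustes(ref_mean[shared], spec_shared, scale=True)
    ref_in_spec = apply_procrustes_transform(ref_mean, transform)

    if method == "MS":
        return ref_in_spec[missing]
    if method == "TPS":
        warp = ThinPlateSpline3D(ref_in_spec[shared], spec_shared)
        return warp(ref_in_spec[missing])
    # REG
    refs_in_spec = np.array([apply_procrustes_transform(cfg, transform) for cfg in ref_aligned])
    n_ref = refs_in_spec.shape[0]
    if n_ref < 3:
        raise ValueError("regression estimation needs at least 3 reference specimens")
    X = refs_in_spec[:, shared].reshape(n_ref, -1)
    Y = refs_in_spec[:, missing].reshape(n_ref, -1)
    x_new = spec_shared.reshape(-1)
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    n_pc = min(n_ref - 1, 10)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    comps = vt[:n_pc]
    S = Xc @ comps.T
    beta, *_ = np.linalg.lstsq(np.hstack([np.ones((n_ref, 1)), S]), Y, rcond=None)
    s_new = (x_new - x_mean) @ comps.T
    pred = np.hstack([1.0, s_new]) @ beta
    return pred.reshape(-1, 3)


@dataclass
class ImputationReport:
    """Remove-and-re-estimate validation summary for one method."""

    method: str
    nreps: int
    per_landmark_error: np.ndarray  # mean displacement / centroid size, NaN if never removed
    per_landmark_count: np.ndarray  # times each landmark was removed
    protest_correlations: np.ndarray  # (nreps,)
    protest_p: np.ndarray  # (nreps,)
    t_p: np.ndarray  # per-landmark Welch T p-values (estimated vs intact dispersion)
    f_p: np.ndarray  # per-landmark F-test p-values
    seed: int | None = None

    def as_records(self) -> list[dict]:
        return [{"method": self.method, "landmark": j,
                 "mean_error": float(self.per_landmark_error[j]),
                 "n_removed": int(self.per_landmark_count[j]),
                 "t_p": float(self.t_p[j]), "f_p": float(self.f_p[j])}
                for j in range(len(self.per_landmark_error))]


def validate_estimation(intact: LandmarkTable, methods=METHODS, nreps: int = 50,
                        kmax: int = 10, seed: int | None = None,
                        protest_nperm: int = 199) -> dict[str, ImputationReport]:
    """Remove 1..kmax random landmarks from a random intact specimen, nreps times.

    Per replicate and method: estimate, Procrustes-fit the estimated dataset,
    and PROTEST its first two PC axes against the intact dataset's.  Across
    replicates: per-landmark mean displacement (in units of the specimen's
    centroid size) and Welch-T/F tests comparing per-landmark dispersion
    around the consensus between estimated and intact alignments.
    """
    if intact.has_missing:
        raise ValueError("validation needs an intact (complete) table")
    n, p = intact.n_specimens, intact.n_landmarks
    if n < 3:
        raise ValueError("need at least 3 intact specimens")
    if kmax >= p - 4:
        raise ValueError(f"kmax={kmax} leaves fewer than 4 anchor landmarks (p={p})")
    rng = np.random.default_rng(seed)

    intact_fit = gpa(intact)
    intact_scores = shape_pca(intact_fit).scores[:, :2]
    intact_dist = np.linalg.norm(intact_fit.aligned - intact_fit.consensus, axis=2)  # (n, p)

    methods = [m.upper() for m in methods]
    acc = {m: {"err_sum": np.zeros(p), "count": np.zeros(p), "corr": [], "p": [],
               "dists": []} for m in methods}
    for rep in range(nreps):
        s = int(rng.integers(n))
        k = int(rng.integers(1, kmax + 1))
        gone = rng.choice(p, size=k, replace=False)
        damaged_coords = intact.coords.copy()
        damaged_mask = np.zeros((n, p), dtype=bool)
        damaged_mask[s, gone] = True
        damaged_coords[s, gone] = np.nan
        damaged = LandmarkTable(list(intact.specimen_ids), list(intact.species_ids),
                                list(intact.groups), list(intact.landmark_labels),
                                damaged_coords, damaged_mask)
        truth = intact.coords[s, gone]
        size = centroid_size(intact.coords[s])
        for m in methods:
            est = estimate_missing(damaged, method=m)
            err = np.linalg.norm(est.coords[s, gone] - truth, axis=1) / size
            acc[m]["err_sum"][gone] += err
            acc[m]["count"][gone] += 1
            est_fit = gpa(est)
            pr = protest(shape_pca(est_fit).scores[:, :2], intact_scores,
                         nperm=protest_nperm, rng=rng)
            acc[m]["corr"].append(pr["correlation"])
            acc[m]["p"].append(pr["p"])
            acc[m]["dists"].append(np.linalg.norm(est_fit.aligned - est_fit.consensus, axis=2))

    out = {}
    for m in methods:
        a = acc[m]
        with np.errstate(invalid="ignore"):
            mean_err = np.where(a["count"] > 0, a["err_sum"] / np.maximum(a["count"], 1), np.nan)
        est_d = np.concatenate(a["dists"], axis=0)  # (nreps*n, p)
        t_p = np.empty(p)
        f_p = np.empty(p)
        for j in range(p):
            if est_d[:, j].std() == 0 and intact_dist[:, j].std() == 0:
                t_p[j] = 1.0
            else:
                t_p[j] = stats.ttest_ind(est_d[:, j], intact_dist[:, j], equal_var=False).pvalue
            f_p[j] = _f_test(est_d[:, j], intact_dist[:, j])
        out[m] = ImputationReport(method=m, nreps=nreps, per_landmark_error=mean_err,
                                  per_landmark_count=a["count"],
                                  protest_correlations=np.array(a["corr"]),
                                  protest_p=np.array(a["p"]),
                                  t_p=t_p, f_p=f_p, seed=seed)
    return out


def _f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed F test of equal variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    F = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = stats.f.sf(F, dfa, dfb) if F >= 1 else stats.f.cdf(F, dfa, dfb)
    return float(min(1.0, 2 * p))


def observer_error(replicates: LandmarkTable, independents: LandmarkTable) -> dict:
    """Landmarking precision: replicate digitizations vs independent specimens.

    Each set is Procrustes-fitted separately; the error of a landmark is the
    mean distance of its per-configuration position to the set consensus.  In
    a precise landmarking scheme replicate errors are close to zero and at
    least an order of magnitude below the independent-specimen distances;
    Welch-T and F tests compare the two per landmark.
    """
    if list(replicates.landmark_labels) != list(independents.landmark_labels):
        raise ValueError("landmark labels differ between the two sets")
    if replicates.n_specimens < 2 or independents.n_specimens < 2:
        raise ValueError("each set needs at least 2 configurations")
    rep_fit = gpa(replicates)
    ind_fit = gpa(independents)
    rep_d = np.linalg.norm(rep_fit.aligned - rep_fit.consensus, axis=2)  # (n_rep, p)
    ind_d = np.linalg.norm(ind_fit.aligned - ind_fit.consensus, axis=2)
    p = replicates.n_landmarks
    t_p = np.empty(p)
    f_p = np.empty(p)
    for j in range(p):
        if rep_d[:, j].std() == 0 and ind_d[:, j].std() == 0:
            t_p[j] = 1.0
        else:
            t_p[j] = stats.ttest_ind(rep_d[:, j], ind_d[:, j], equal_var=False).pvalue
        f_p[j] = _f_test(rep_d[:, j], ind_d[:, j])
    return {
        "per_landmark_replicate_error": rep_d.mean(axis=0),
        "per_landmark_independent_error": ind_d.mean(axis=0),
        "mean_replicate_error": float(rep_d.mean()),
        "mean_independent_error": float(ind_d.mean()),
        "error_ratio": float(ind_d.mean() / rep_d.mean()) if rep_d.mean() > 0 else np.inf,
        "t_p": t_p,
        "f_p": f_p,
    }
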