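"""Synthetic landmark datasets with known modular structure and phylogeny.

The generator emulates the shape of the study data the downstream analyses
were designed for: ~30 species in 3 pollination-syndrome-like groups on an
ultrametric tree, 37 landmarks per flower, a handful of specimens per
species (many singletons), block-modular within-species covariance, and
1-10 missing landmarks on damaged specimens.  Every stage returns its ground
truth so tests can verify recovery.

Model
-----
* Species mean shapes start from a fixed non-degenerate base configuration
  (points on a sphere plus per-module offsets) and evolve along a pure-birth
  tree, each coordinate independently under Brownian motion with its
  module's rate, or under an Ornstein-Uhlenbeck pull toward group-specific
  optima.
* Specimen deviations are multivariate normal on the 3p coordinates with a
  landmark-level block correlation: coordinates of landmarks in the same
  module correlate at ``rho_w``, across modules at ``rho_b`` (the landmark is
  the unit the CR permutation test permutes, so ground truth is structured
  on landmarks).
* Optional nuisance similarity transforms (rotation, translation, scale)
  exercise everything Procrustes alignment must remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hypotheses import builtin_hypotheses
from .io_formats import LandmarkTable, ModuleHypothesis
from .trees import Tree, simulate_tree

__all__ = ["SimSpec", "simulate_species_means", "simulate_specimens",
           "simulate_dataset", "base_configuration", "block_correlation"]


def _default_hypothesis(p: int) -> ModuleHypothesis:
    if p == 37:
        return builtin_hypotheses()[4]  # 3-module flower partition
    half = p // 2
    labels = [str(k + 1) for k in range(p)]
    assignment = {lab: ("A" if i < half else "B") for i, lab in enumerate(labels)}
    return ModuleHypothesis("sim2mod", assignment, ["A", "B"])


@dataclass
class SimSpec:
    """Parameters of one synthetic study.

    Defaults mirror the study design the analyses target: 37 landmarks under
    a 3-module partition, 30 species in 3 groups, specimen counts uniform on
    1-8 (about four per species, total near 137), nuisance pose/scale applied,
    and roughly half of the specimens damaged with 1-10 missing landmarks.
    """

    p: int = 37
    hypothesis: ModuleHypothesis | None = None
    n_species: int = 30
    specimens_per_species: int | tuple[int, int] = (1, 8)
    rho_w: float = 0.7
    rho_b: float = 0.1
    within_sd: float = 0.05
    sigma2_m: dict[str, float] | float = 0.02
    regime_model: str = "BM"  # "BM" or "OU"
    ou_alpha: float = 2.0
    ou_theta_scale: float = 0.5
    n_groups: int = 3
    missing_fraction: float = 65 / 137
    missing_range: tuple[int, int] = (1, 10)
    nuisance: bool = True
    scatter_directions: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.hypothesis is None:
            self.hypothesis = _default_hypothesis(self.p)
        if not (0 <= self.rho_b <= self.rho_w < 1):
            raise ValueError("need 0 <= rho_b <= rho_w < 1")
        sig = self.sigma2_values()
        if any(s <= 0 for s in sig.values()):
            raise ValueError("module rates must be positive")
        lo, hi = self.missing_range
        if not (1 <= lo <= hi):
            raise ValueError("missing_range must satisfy 1 <= lo <= hi")

    def sigma2_values(self) -> dict[str, float]:
        mods = self.hypothesis.module_names
        if isinstance(self.sigma2_m, dict):
            if set(self.sigma2_m) != set(mods):
                raise ValueError("sigma2_m keys must match module names")
            return {m: float(self.sigma2_m[m]) for m in mods}
        return {m: float(self.sigma2_m) for m in mods}

    @property
    def landmark_labels(self) -> list[str]:
        return sorted(self.hypothesis.assignment,
                      key=lambda s: (0, int(s)) if s.isdigit() else (1, s))

    def with_(self, **kw) -> "SimSpec":
        return replace(self, **kw)


def base_configuration(spec: SimSpec) -> np.ndarray:
    """Deterministic non-degenerate base shape: Fibonacci sphere + module offsets."""
    p = spec.p
    k = np.arange(p, dtype=float)
    phi = np.arccos(1 - 2 * (k + 0.5) / p)
    theta = np.pi * (1 + 5**0.5) * k
    pts = np.stack([np.sin(phi) * np.cos(theta),
                    np.sin(phi) * np.sin(theta),
                    np.cos(phi)], axis=1)
    labels = spec.landmark_labels
    for m, module in enumerate(spec.hypothesis.module_names):
        ang = 2 * np.pi * m / max(spec.hypothesis.n_modules, 1)
        offset = 0.25 * np.array([np.cos(ang), np.sin(ang), (-1.0) ** m * 0.5])
        idx = [i for i, lab in enumerate(labels) if spec.hypothesis.assignment[lab] == module]
        pts[idx] += offset
    return pts


def block_correlation(spec: SimSpec) -> np.ndarray:
    """The 3p x 3p specimen-level correlation matrix implied by the module map."""
    labels = spec.landmark_labels
    module_of = np.array([spec.hypothesis.module_names.index(spec.hypothesis.assignment[lab])
                          for lab in labels])
    g = np.repeat(module_of, 3)
    same = g[:, None] == g[None, :]
    R = np.where(same, spec.rho_w, spec.rho_b)
    np.fill_diagonal(R, 1.0)
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise ValueError("implied block correlation matrix is not positive definite")
    return R


def landmark_frames(spec: SimSpec) -> np.ndarray:
    """Fixed per-landmark rotation frames for deviation directions.

    The correlated deviation draw is expressed in each landmark's own frame.
    Without this, the common factor behind a module's within-correlation is a
    near-uniform translation of that module, which Procrustes centering
    converts into spurious between-module anti-correlation; scattering the
    directions makes modules *deform* coherently instead, as real shape
    variation does.  The CR statistic is invariant to per-landmark rotations
    (it only sees Frobenius norms of between-landmark blocks), so the
    generating block structure is untouched.  Frames are deterministic given
    the seed and shared by the species and specimen levels.
    """
    if not spec.scatter_directions:
        return np.broadcast_to(np.eye(3), (spec.p, 3, 3)).copy()
    rng = np.random.default_rng(spec.seed + 1_000_003)
    frames = np.empty((spec.p, 3, 3))
    for i in range(spec.p):
        frames[i] = _random_rotation(rng)
    return frames


def _apply_frames(dev_flat: np.ndarray, frames: np.ndarray) -> np.ndarray:
    """Rotate each landmark's 3-vector deviation into its own frame."""
    d = dev_flat.reshape(*dev_flat.shape[:-1], frames.shape[0], 3)
    return np.einsum("...ik,ijk->...ij", d, frames).reshape(dev_flat.shape)


def _assign_regimes(tree: Tree, n_groups: int, rng: np.random.Generator) -> dict[str, str]:
    """Paint ``n_groups`` regimes on the tree by clade-based shifts.

    The root regime is group 1; each further group originates on one internal
    branch (clade of 2..n_tips-1 tips), mirroring syndrome shifts.
    """
    tips = tree.tip_labels
    regimes = {t: "g1" for t in tips}
    if n_groups <= 1:
        return regimes
    n = tree.n_tips
    branches = [b for b in tree.branches() if 2 <= len(b["tips"]) <= n - 2]
    rng.shuffle(branches)
    # prefer mid-sized clades so no group ends up with 1-2 species
    lo = max(2, round(n / 8))
    branches.sort(key=lambda b: 0 if lo <= len(b["tips"]) <= n // 2 else 1)
    assigned = 1
    for b in branches:
        if assigned >= n_groups:
            break
        # only shift clades still uniformly in the root regime, keeping groups nested-free
        if all(regimes[t] == "g1" for t in b["tips"]):
            remaining_root = sum(1 for t in tips if regimes[t] == "g1") - len(b["tips"])
            if remaining_root >= 2:
                assigned += 1
                for t in b["tips"]:
                    regimes[t] = f"g{assigned}"
    return regimes


def simulate_species_means(tree: Tree, spec: SimSpec,
                           rng: np.random.Generator | None = None):
    """Evolve species mean shapes along the tree.

    Returns ``(means_table, truth)`` where ``truth`` records the regime of
    every tip and, under OU, the per-group optima.
    """
    if tree.n_tips < 2:
        raise ValueError("tree needs at least 2 tips")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    labels = spec.landmark_labels
    base = base_configuration(spec).reshape(-1)
    sig = spec.sigma2_values()
    module_of = [spec.hypothesis.assignment[lab] for lab in labels]
    sigma2 = np.repeat([sig[m] for m in module_of], 3)
    # evolutionary increments share the landmark-level block correlation, so
    # species means carry the same modular signal the specimen level does
    L_R = np.linalg.cholesky(block_correlation(spec))
    frames = landmark_frames(spec)

    def noise(scale_vec):
        return _apply_frames((L_R @ rng.standard_normal(base.size)) * scale_vec, frames)

    regimes = _assign_regimes(tree, spec.n_groups, rng)
    edges, n_nodes, tip_index = tree.edges_preorder()
    # regime of an internal branch = regime shared by its descendant tips if unanimous, else root regime
    branch_regime = {}
    tipsets = {b["id"]: b["tips"] for b in tree.branches()}
    for b_id, tips in tipsets.items():
        rs = {regimes[t] for t in tips}
        branch_regime[b_id] = rs.pop() if len(rs) == 1 else "g1"

    thetas = {"g1": base.copy()}
    for g in sorted({r for r in regimes.values()}):
        if g != "g1":
            thetas[g] = base + spec.ou_theta_scale * rng.standard_normal(base.size)

    x = np.empty((n_nodes, base.size))
    x[0] = base
    for parent, child, blen in edges:
        if spec.regime_model.upper() == "BM":
            x[child] = x[parent] + noise(np.sqrt(sigma2 * blen))
        elif spec.regime_model.upper() == "OU":
            a = spec.ou_alpha
            th = thetas[branch_regime[child]]
            decay = np.exp(-a * blen)
            sd = np.sqrt(sigma2 / (2 * a) * (1 - np.exp(-2 * a * blen)))
            x[child] = th + (x[parent] - th) * decay + noise(sd)
        else:
            raise ValueError(f"unknown regime model {spec.regime_model!r}")

    species = tree.tip_labels
    coords = np.array([x[tip_index[s]].reshape(spec.p, 3) for s in species])
    table = LandmarkTable(list(species), list(species), [regimes[s] for s in species],
                          labels, coords, np.zeros((len(species), spec.p), dtype=bool))
    truth = {"regimes": regimes,
             "theta": thetas if spec.regime_model.upper() == "OU" else None,
             "sigma2": sig, "frames": frames}
    return table, truth


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1
    return q


def simulate_specimens(means: LandmarkTable, spec: SimSpec,
                       rng: np.random.Generator | None = None) -> LandmarkTable:
    """Draw specimens around species means with block-correlated noise.

    Deviations are ``within_sd`` times draws from the block correlation of
    :func:`block_correlation`; optional nuisance similarity transforms and
    missing-landmark injection follow.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    lo, hi = ((spec.specimens_per_species,) * 2
              if isinstance(spec.specimens_per_species, int)
              else spec.specimens_per_species)
    if lo < 1:
        raise ValueError("specimens_per_species must be >= 1")
    L = np.linalg.cholesky(block_correlation(spec))
    frames = landmark_frames(spec)

    ids, species, groups, coords = [], [], [], []
    for i, sp in enumerate(means.specimen_ids):
        n_i = int(rng.integers(lo, hi + 1))
        dev = _apply_frames(spec.within_sd * (rng.standard_normal((n_i, 3 * spec.p)) @ L.T),
                            frames)
        block = means.coords[i].reshape(-1) + dev
        for k in range(n_i):
            ids.append(f"{sp}_f{k + 1:02d}")
            species.append(sp)
            groups.append(means.groups[i])
            coords.append(block[k].reshape(spec.p, 3))
    coords = np.array(coords)
    n = coords.shape[0]

    if spec.nuisance:
        for k in range(n):
            rot = _random_rotation(rng)
            scale = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
            shift = rng.uniform(0, 1, size=3)
            coords[k] = coords[k] @ rot * scale + shift

    mask = np.zeros((n, spec.p), dtype=bool)
    if spec.missing_fraction > 0:
        n_damaged = int(round(spec.missing_fraction * n))
        damaged = rng.choice(n, size=n_damaged, replace=False)
        lo_m, hi_m = spec.missing_range
        for k in damaged:
            n_miss = int(rng.integers(lo_m, hi_m + 1))
            gone = rng.choice(spec.p, size=min(n_miss, spec.p - 4), replace=False)
            mask[k, gone] = True
            coords[k, gone] = np.nan
    return LandmarkTable(ids, species, groups, list(means.landmark_labels), coords, mask)


def simulate_modular_sample(spec: SimSpec, n: int,
                            rng: np.random.Generator | None = None) -> LandmarkTable:
    """Specimens drawn straight from the block-modular covariance (no tree).

    The population-level experiment behind the CR power/calibration studies:
    ``n`` configurations around the base shape with landmark-level block
    correlation ``(rho_w, rho_b)`` and scale ``within_sd``.  No nuisance
    transforms or missingness are applied.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if n < 2:
        raise ValueError("need n >= 2 specimens")
    L = np.linalg.cholesky(block_correlation(spec))
    frames = landmark_frames(spec)
    dev = _apply_frames(spec.within_sd * (rng.standard_normal((n, 3 * spec.p)) @ L.T),
                        frames)
    base = base_configuration(spec).reshape(-1)
    coords = (base + dev).reshape(n, spec.p, 3)
    ids = [f"s{k + 1:04d}" for k in range(n)]
    return LandmarkTable(ids, ids, [""] * n, spec.landmark_labels, coords,
                         np.zeros((n, spec.p), dtype=bool))


def simulate_dataset(spec: SimSpec, tree: Tree | None = None):
    """Full study simulation: tree, species means, specimens, ground truth."""
    rng = np.random.default_rng(spec.seed)
    if tree is None:
        tree = simulate_tree(spec.n_species, rng=rng)
    means, truth = simulate_species_means(tree, spec, rng=rng)
    table = simulate_specimens(means, spec, rng=rng)
    truth = dict(truth, tree=tree, species_means=means, spec=spec)
    return table, tree, means, truth
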