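"""Congruence-coefficient matrices and likelihood selection of modularity models.

Each landmark's deviation from the consensus across specimens is a vector
field; the congruence coefficient between two landmarks is the cosine-type
correlation of those fields.  A modularity hypothesis induces candidate
models that pool cells of the resulting p x p correlation matrix into
parameter classes (one correlation per class); models are scored by maximum
likelihood on Fisher-transformed correlations with sampling variance
``1/(N - 3)`` and compared by finite-sample corrected AICc and Akaike
weights.

The model grammar crosses {single within-module rho | one rho per module}
with {single between-module rho | one rho per module pair}; duplicate cell
partitions are removed (for two modules the between variants coincide), and
a no-modularity null (one rho for every cell) is appended.  The flower
hypotheses H1-H5 (module counts 4, 2, 2, 2, 3) yield 15 distinct models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import LandmarkTable, ModuleHypothesis

__all__ = ["CorrelationMatrix", "CorrModel", "EMMLiTable", "congruence_matrix",
           "build_model_set", "emmli_fit"]

#: correlations are clamped to +-(1 - CLAMP) before the Fisher transform
CLAMP = 1e-9


@dataclass
class CorrelationMatrix:
    """p x p landmark congruence coefficients plus the specimen count behind them."""

    matrix: np.ndarray
    n_specimens: int
    landmark_labels: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        p = len(self.landmark_labels)
        if self.matrix.shape != (p, p):
            raise ValueError("matrix shape does not match landmark labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(self.matrix)) > 1 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")


def congruence_matrix(coords, landmark_labels: list[str] | None = None,
                      consensus: np.ndarray | None = None) -> CorrelationMatrix:
    """Vector congruence coefficients between landmark deviation fields.

    ``entry(i, j) = sum_s d_si . d_sj / sqrt(sum_s |d_si|^2 sum_s |d_sj|^2)``
    with ``d_si`` the 3-vector deviation of landmark i in specimen s from the
    consensus (by default the mean configuration of ``coords``).
    """
    if isinstance(coords, LandmarkTable):
        landmark_labels = list(coords.landmark_labels)
        coords = coords.coords
    coords = np.asarray(coords, dtype=float)
    n, p, _ = coords.shape
    if n < 4:
        raise ValueError("need at least 4 specimens")
    if landmark_labels is None:
        landmark_labels = [str(k + 1) for k in range(p)]
    mean = coords.mean(axis=0) if consensus is None else np.asarray(consensus)
    d = coords - mean  # (n, p, 3)
    cross = np.einsum("sik,sjk->ij", d, d)
    norms = np.sqrt(np.diag(cross))
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"landmark {landmark_labels[zero[0]]} has zero total deviation")
    corr = cross / np.outer(norms, norms)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(corr, n, landmark_labels)


@dataclass
class CorrModel:
    """A labelled partition of the upper-triangle correlation cells."""

    name: str
    hypothesis: str  # source hypothesis name, "" for the null
    cell_class: dict[tuple[str, str], str]  # (label_i, label_j) i<j -> class name

    @property
    def n_classes(self) -> int:
        return len(set(self.cell_class.values()))

    def signature(self) -> frozenset:
        groups: dict[str, set] = {}
        for cell, cls in self.cell_class.items():
            groups.setdefault(cls, set()).add(cell)
        return frozenset(frozenset(v) for v in groups.values())


def _cells(labels: list[str]):
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            yield labels[i], labels[j]


def build_model_set(hypotheses: list[ModuleHypothesis],
                    landmark_labels: list[str] | None = None) -> list[CorrModel]:
    """Generate the deduplicated model set for a list of modularity hypotheses.

    Landmark labels default to the union over hypotheses (which must agree).
    """
    if not hypotheses:
        raise ValueError("need at least one hypothesis")
    if landmark_labels is None:
        landmark_labels = sorted(hypotheses[0].assignment,
                                 key=lambda s: (0, int(s)) if s.isdigit() else (1, s))
    for h in hypotheses:
        h.validate_against(landmark_labels)
        if h.n_modules < 2:
            raise ValueError(f"hypothesis {h.name!r} has fewer than 2 modules")

    models: list[CorrModel] = []
    seen: set[frozenset] = set()

    def add(model: CorrModel):
        sig = model.signature()
        if sig not in seen:
            seen.add(sig)
            models.append(model)

    for h in hypotheses:
        mod_of = h.assignment
        for within_per_module in (False, True):
            for between_per_pair in (False, True):
                cc = {}
                for a, b in _cells(landmark_labels):
                    ma, mb = mod_of[a], mod_of[b]
                    if ma == mb:
                        cc[(a, b)] = f"within.{ma}" if within_per_module else "within"
                    else:
                        pair = ".".join(sorted((ma, mb)))
                        cc[(a, b)] = f"between.{pair}" if between_per_pair else "between"
                wtag = "sep" if within_per_module else "same"
                btag = "sep" if between_per_pair else "same"
                add(CorrModel(f"{h.name}.w_{wtag}.b_{btag}", h.name, cc))
    null = CorrModel("null", "", {cell: "all" for cell in _cells(landmark_labels)})
    add(null)
    return models


@dataclass
class EMMLiTable:
    """Per-model fit summary; rows sorted by AICc, weights sum to 1."""

    rows: list[dict] = field(default_factory=list)

    @property
    def best(self) -> dict:
        return self.rows[0]

    def as_records(self) -> list[dict]:
        return list(self.rows)


def emmli_fit(corr: CorrelationMatrix, models: list[CorrModel]) -> EMMLiTable:
    """Maximum-likelihood fit and AICc comparison of correlation models.

    Each cell's Fisher z is modelled as normal around its class mean with
    variance ``1/(N - 3)``; the MLE per class is the mean z (back-transformed
    to a rho per class).  ``K`` counts the rho parameters; ``AICc`` uses the
    number of upper-triangle cells as the sample size.
    """
    if corr.n_specimens < 5:
        raise ValueError("need at least 5 specimens behind the correlation matrix")
    labels = corr.landmark_labels
    pos = {lab: i for i, lab in enumerate(labels)}
    cells = list(_cells(labels))
    n_r = len(cells)
    r = np.array([corr.matrix[pos[a], pos[b]] for a, b in cells])
    z = np.arctanh(np.clip(r, -1 + CLAMP, 1 - CLAMP))
    var = 1.0 / (corr.n_specimens - 3)

    rows = []
    for model in models:
        classes: dict[str, list[int]] = {}
        for k, cell in enumerate(cells):
            if cell not in model.cell_class:
                raise ValueError(f"model {model.name!r} does not cover cell {cell}")
            classes.setdefault(model.cell_class[cell], []).append(k)
        K = len(classes)
        if n_r - K - 1 <= 0:
            raise ValueError(f"model {model.name!r} too rich: K={K} for {n_r} cells")
        logL = 0.0
        rho_hat = {}
        for cls, idx in classes.items():
            zc = z[idx]
            zhat = zc.mean()
            rho_hat[cls] = float(np.tanh(zhat))
            logL += float(-0.5 * len(idx) * np.log(2 * np.pi * var)
                          - 0.5 * ((zc - zhat) ** 2).sum() / var)
        aicc = -2 * logL + 2 * K + 2 * K * (K + 1) / (n_r - K - 1)
        rows.append({"model": model.name, "hypothesis": model.hypothesis, "K": K,
                     "logL": logL, "AICc": aicc, "rho": rho_hat})
    best = min(row["AICc"] for row in rows)
    for row in rows:
        row["dAICc"] = row["AICc"] - best
    rel = np.array([np.exp(-0.5 * row["dAICc"]) for row in rows])
    weights = rel / rel.sum()
    for row, w in zip(rows, weights):
        row["weight"] = float(w)
    rows.sort(key=lambda row: row["AICc"])
    return EMMLiTable(rows=rows)
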