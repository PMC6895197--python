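"""GPA invariances, mean shapes, PCA conservation, and PROTEST behaviour."""

import numpy as np
import pytest
from scipy import optimize, stats

from floramorph.procrustes import (
    centroid_size,
    gpa,
    optimal_rotation,
    protest,
    shape_pca,
    species_means,
)

from conftest import make_table


def random_similarity(rng, config):
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1
    s = float(np.exp(rng.uniform(-0.7, 0.7)))
    t = rng.uniform(-2, 2, size=3)
    return config @ q * s + t


def test_gpa_invariance_to_similarity_transforms(rng):
    base = rng.standard_normal((8, 3))
    coords = np.array([random_similarity(rng, base) for _ in range(10)])
    fit = gpa(coords)
    assert fit.converged
    for i in range(10):
        assert np.abs(fit.aligned[i] - fit.aligned[0]).max() < 1e-8
    # consensus equals the (normalized) shape up to rotation
    ref = base - base.mean(0)
    ref /= np.linalg.norm(ref)
    rot = optimal_rotation(ref, fit.consensus)
    assert np.abs(ref @ rot - fit.consensus).max() < 1e-8


def test_gpa_postconditions(rng):
    coords = rng.standard_normal((6, 7, 3))
    fit = gpa(coords)
    # centering and unit centroid size of every aligned configuration
    assert np.abs(fit.aligned.mean(axis=1)).max() < 1e-10
    sizes = np.sqrt((fit.aligned**2).sum(axis=(1, 2)))
    assert np.abs(sizes - 1).max() < 1e-10
    assert np.allclose(fit.consensus, fit.aligned.mean(axis=0))
    assert (fit.centroid_sizes > 0).all()


def test_gpa_residual_sum_is_minimized_against_oracle(rng):
    """Consensus must minimize sum ||x_i R_i - mu||^2 (direct-minimization oracle)."""
    base = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    configs = np.array([base + 0.25 * rng.standard_normal((4, 3)) for _ in range(3)])
    fit = gpa(configs)

    scaled = []
    for c in configs:
        cc = c - c.mean(0)
        scaled.append(cc / np.linalg.norm(cc))

    def objective(flat):
        mu = flat.reshape(4, 3)
        total = 0.0
        for x in scaled:
            r = optimal_rotation(x, mu)
            total += ((x @ r - mu) ** 2).sum()
        return total

    res = optimize.minimize(objective, fit.consensus.ravel(), method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000,
                                     "maxfev": 20000})
    assert res.fun >= objective(fit.consensus.ravel()) - 1e-8


def test_gpa_consensus_matches_full_procrustes_mean_at_low_dispersion(rng):
    """SVD-based full-Procrustes-mean oracle; agrees in the low-dispersion regime."""
    base = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    configs = [base + 0.003 * rng.standard_normal((4, 3)) for _ in range(3)]
    fit = gpa(np.array(configs))
    X = []
    for c in configs:
        cc = c - c.mean(0)
        X.append(cc / np.linalg.norm(cc))
    mu = X[0].copy()
    for _ in range(5000):
        aligned = []
        for x in X:
            r = optimal_rotation(x, mu)
            beta = float(np.trace(mu.T @ (x @ r)))  # full-Procrustes scale
            aligned.append(beta * (x @ r))
        new = np.mean(aligned, axis=0)
        new /= np.linalg.norm(new)
        if np.linalg.norm(new - mu) < 1e-16:
            mu = new
            break
        mu = new
    cons = fit.consensus / np.linalg.norm(fit.consensus)
    rot = optimal_rotation(mu, cons)
    assert np.abs(mu @ rot - cons).max() < 1e-8


def test_gpa_rejects_degenerate_and_missing(rng):
    line = np.stack([np.linspace(0, 1, 5), np.zeros(5), np.zeros(5)], axis=1)
    with pytest.raises(ValueError, match="degenerate|collinear"):
        gpa(np.array([line, line]))
    coords = rng.standard_normal((3, 5, 3))
    mask = np.zeros((3, 5), dtype=bool)
    mask[0, 0] = True
    coords[0, 0] = np.nan
    table = make_table(coords, mask=mask)
    with pytest.raises(ValueError, match="missing"):
        gpa(table)


def test_species_means_averages_and_passes_singletons(rng):
    base = rng.standard_normal((7, 3))
    d = 0.01 * rng.standard_normal((7, 3))
    coords = np.array([base + d, base - d, base * 1.0])
    table = make_table(coords, species=["spA", "spA", "spB"])
    fit = gpa(table)
    means = species_means(fit)
    assert means.specimen_ids == ["spA", "spB"]
    # symmetric deviations average back to the central shape
    assert np.allclose(means.coords[0], (fit.aligned[0] + fit.aligned[1]) / 2)
    # singleton passes through unchanged
    assert np.allclose(means.coords[1], fit.aligned[2])
    with pytest.raises(ValueError):
        species_means(fit, species_ids=["spA"])


def test_shape_pca_variance_accounting(rng):
    coords = rng.standard_normal((10, 5, 3))
    fit = gpa(coords)
    space = shape_pca(fit)
    assert np.all(np.diff(space.eigenvalues) <= 1e-12)
    assert space.pct_variance.sum() == pytest.approx(100.0)
    # total variance conservation
    flat = fit.aligned.reshape(10, -1)
    total = np.var(flat, axis=0, ddof=1).sum()
    assert space.eigenvalues.sum() == pytest.approx(total, rel=1e-10)
    # reconstruction from all PCs reproduces the data
    rec = space.mean + space.scores @ space.loadings.T
    assert np.abs(rec - flat).max() < 1e-10


def test_shape_pca_one_direction(rng):
    direction = rng.standard_normal(15)
    coords = (np.linspace(-1, 1, 6)[:, None] * direction).reshape(6, 5, 3)
    coords += rng.standard_normal((1, 5, 3))  # common offset only
    space = shape_pca(coords)
    assert space.pct_variance[0] == pytest.approx(100.0, abs=1e-8)
    with pytest.raises(ValueError):
        shape_pca(coords[:2])


def test_protest_similarity_and_reflection_give_t_one(rng):
    a = rng.standard_normal((15, 2))
    th = 0.9
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    b = a @ rot * 3.0 + 7.0
    res = protest(a, b, nperm=99, seed=1)
    assert res["correlation"] == pytest.approx(1.0, abs=1e-10)
    assert res["p"] == pytest.approx(1 / 100)
    refl = b @ np.array([[1.0, 0.0], [0.0, -1.0]])
    res2 = protest(a, refl, nperm=99, seed=1)
    assert res2["correlation"] == pytest.approx(1.0, abs=1e-10)


def test_protest_null_p_is_uniform(rng):
    """Independent scores: PROTEST p approximately uniform over replicates."""
    pvals = []
    for _ in range(300):
        a = rng.standard_normal((20, 2))
        b = rng.standard_normal((20, 2))
        pvals.append(protest(a, b, nperm=99, rng=rng)["p"])
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_centroid_size():
    square = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0.0]])
    assert centroid_size(square) == pytest.approx(np.sqrt(8.0))
    assert centroid_size(square + 5.0) == pytest.approx(np.sqrt(8.0))
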