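"""CR statistic values, permutation test behaviour, and group comparisons."""

import itertools

import numpy as np
import pytest

from floramorph.io_formats import ModuleHypothesis
from floramorph.modularity import (
    compare_modularity,
    cr_coefficient,
    modularity_test,
    phylo_modularity,
)
from floramorph.synthetic_data import SimSpec, simulate_modular_sample
from floramorph.trees import Tree

from conftest import make_table


def data_with_exact_cov(S, n, rng):
    """n samples whose *sample* covariance equals S exactly."""
    q = S.shape[0]
    assert n - 1 >= q
    Z = rng.standard_normal((n, q))
    Z -= Z.mean(axis=0)
    Q, _ = np.linalg.qr(Z)
    L = np.linalg.cholesky(S)
    return np.sqrt(n - 1) * Q @ L.T


def hyp_2mod(p, split=None):
    split = split if split is not None else p // 2
    labels = [str(k + 1) for k in range(p)]
    return ModuleHypothesis("h", {l: ("A" if int(l) <= split else "B") for l in labels})


def test_cr_zero_when_between_block_covariance_vanishes(rng):
    p = 6
    S = np.kron(np.eye(2), 0.5 * np.ones((9, 9)) + 0.5 * np.eye(9))
    X = data_with_exact_cov(S, 40, rng)
    res = cr_coefficient(X.reshape(40, p, 3), hyp_2mod(p))
    assert res["cr"] == pytest.approx(0.0, abs=1e-10)


def test_cr_for_exchangeable_covariance_matches_closed_form(rng):
    """All between-landmark covariances equal: CR has a hand-derived value.

    With q_A, q_B landmarks per module and every between-landmark cell equal,
    CR = sqrt(q_A q_B / sqrt(q_A (q_A - 1) q_B (q_B - 1))) -> 1 as modules
    grow (the count asymmetry between the q_A q_B between-cells and the
    q (q - 1) within-cells vanishes).
    """
    for p in (6, 12):
        S = np.full((3 * p, 3 * p), 0.4)
        np.fill_diagonal(S, 1.0)
        X = data_with_exact_cov(S, 3 * p + 5, rng)
        res = cr_coefficient(X.reshape(-1, p, 3), hyp_2mod(p))
        q = p // 2
        expected = np.sqrt(q * q / np.sqrt(q * (q - 1) * q * (q - 1)))
        assert res["cr"] == pytest.approx(expected, abs=1e-10)
    # and the large-module limit approaches 1
    assert abs(np.sqrt(6 * 6 / np.sqrt(6 * 5 * 6 * 5)) - 1) < abs(
        np.sqrt(3 * 3 / np.sqrt(3 * 2 * 3 * 2)) - 1)


def test_cr_matches_brute_force_oracle(rng):
    """Direct evaluation of the CR formula from the covariance, cell by cell."""
    coords = rng.standard_normal((5, 6, 3))
    hyp = hyp_2mod(6, split=2)
    res = cr_coefficient(coords, hyp)

    Y = coords.reshape(5, -1)
    Yc = Y - Y.mean(axis=0)
    S = Yc.T @ Yc / 4
    a = [i for l in (0, 1) for i in range(3 * l, 3 * l + 3)]
    b = [i for l in (2, 3, 4, 5) for i in range(3 * l, 3 * l + 3)]
    Sab = S[np.ix_(a, b)]
    Saa = S[np.ix_(a, a)].copy()
    Sbb = S[np.ix_(b, b)].copy()
    for blk in (Saa, Sbb):  # exclude whole within-landmark 3x3 blocks
        for l in range(blk.shape[0] // 3):
            blk[3 * l:3 * l + 3, 3 * l:3 * l + 3] = 0.0
    cr_oracle = np.sqrt(
        np.trace(Sab @ Sab.T)
        / np.sqrt(np.trace(Saa @ Saa.T) * np.trace(Sbb @ Sbb.T))
    )
    assert res["cr"] == pytest.approx(cr_oracle, rel=1e-12)


def test_cr_multi_module_is_mean_of_pairs(rng):
    labels = [str(k + 1) for k in range(9)]
    hyp = ModuleHypothesis("h3", {l: "ABC"[(int(l) - 1) // 3] for l in labels})
    coords = rng.standard_normal((12, 9, 3))
    res = cr_coefficient(coords, hyp)
    iu = np.triu_indices(3, k=1)
    assert res["cr"] == pytest.approx(res["pairwise_cr"][iu].mean(), rel=1e-12)


def test_cr_invariance_to_rotation_and_within_module_order(rng):
    spec = SimSpec(p=8, missing_fraction=0, nuisance=False, seed=1)
    tab = simulate_modular_sample(spec, 20, rng=rng)
    hyp = spec.hypothesis
    base = cr_coefficient(tab.coords, hyp, tab.landmark_labels)["cr"]
    # global rotation of all specimens
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    rotated = tab.coords @ q
    assert cr_coefficient(rotated, hyp, tab.landmark_labels)["cr"] == pytest.approx(
        base, abs=1e-10)
    # permuting landmark order within modules
    idx_a = [0, 1, 2, 3]
    idx_b = [4, 5, 6, 7]
    rng.shuffle(idx_a)
    rng.shuffle(idx_b)
    perm = idx_a + idx_b
    labels_perm = [tab.landmark_labels[i] for i in perm]
    assert cr_coefficient(tab.coords[:, perm], hyp, labels_perm)["cr"] == pytest.approx(
        base, abs=1e-10)


def test_permutation_p_matches_exhaustive_enumeration(rng):
    """6 landmarks in 3+3 modules: the null has C(6,3)=20 labelled assignments."""
    spec = SimSpec(p=6, rho_w=0.6, rho_b=0.2, missing_fraction=0, nuisance=False,
                   seed=5, hypothesis=hyp_2mod(6, split=3))
    tab = simulate_modular_sample(spec, 25, rng=rng)
    hyp = spec.hypothesis
    crs = {}
    for combo in itertools.combinations(range(6), 3):
        assign = {str(k + 1): ("A" if k in combo else "B") for k in range(6)}
        h = ModuleHypothesis("e", assign, ["A", "B"])
        crs[combo] = cr_coefficient(tab.coords, h, tab.landmark_labels)["cr"]
    obs = crs[(0, 1, 2)]
    p_exact = sum(v <= obs + 1e-12 for v in crs.values()) / len(crs)
    res = modularity_test(tab.coords, hyp, nperm=4000, seed=3,
                          landmark_labels=tab.landmark_labels)
    assert abs(res.p - p_exact) <= 0.02


def test_modularity_test_p_floor_and_z_sign(modular_table, modular_spec):
    res = modularity_test(modular_table, modular_spec.hypothesis, nperm=500, seed=2)
    assert res.p >= 1 / 500
    assert res.p <= 0.05  # strongly modular data
    assert res.z > 0  # positive z = stronger modularity
    assert len(res.perm_values) == 500
    assert res.perm_values[0] == pytest.approx(res.cr_obs)


def test_modularity_test_reproducible(modular_table, modular_spec):
    a = modularity_test(modular_table, modular_spec.hypothesis, nperm=300, seed=9)
    b = modularity_test(modular_table, modular_spec.hypothesis, nperm=300, seed=9)
    assert a.p == b.p and a.z == b.z
    assert np.array_equal(a.perm_values, b.perm_values)


def test_z_increases_as_between_correlation_drops(rng):
    medians = []
    for rho_b in (0.5, 0.3, 0.1):
        zs = []
        for _ in range(40):
            spec = SimSpec(p=10, rho_w=0.6, rho_b=rho_b, missing_fraction=0,
                           nuisance=False, seed=0)
            tab = simulate_modular_sample(spec, 30, rng=rng)
            zs.append(modularity_test(tab.coords, spec.hypothesis, nperm=120,
                                      seed=int(rng.integers(2**31)),
                                      landmark_labels=tab.landmark_labels).z)
        medians.append(np.median(zs))
    assert medians[0] < medians[1] < medians[2]


def test_degenerate_module_and_small_sample_rejected(rng):
    labels = [str(k + 1) for k in range(5)]
    hyp = ModuleHypothesis("bad", {"1": "A", "2": "B", "3": "B", "4": "B", "5": "B"})
    # module A's within-block off-diagonals exactly zero -> no denominator mass
    S = np.eye(15)
    S[3:, 3:] = 0.5 * np.ones((12, 12)) + 0.5 * np.eye(12)
    X = data_with_exact_cov(S, 30, rng)
    with pytest.raises(ValueError, match="within-module"):
        cr_coefficient(X.reshape(30, 5, 3), hyp, labels)
    coords = rng.standard_normal((2, 5, 3))
    with pytest.raises(ValueError, match="3 specimens"):
        modularity_test(coords, hyp, nperm=100, landmark_labels=labels)


def test_small_nperm_warns(modular_table, modular_spec):
    with pytest.warns(UserWarning, match="small"):
        modularity_test(modular_table, modular_spec.hypothesis, nperm=99, seed=0)


def test_compare_modularity_self_is_null(modular_table, modular_spec):
    res = modularity_test(modular_table, modular_spec.hypothesis, nperm=300, seed=4)
    comp = compare_modularity([res, res], ["a", "b"])
    assert comp.delta_z[0, 1] == pytest.approx(0.0)
    assert comp.p[0, 1] == pytest.approx(1.0)


def test_compare_modularity_detects_strength_difference(rng):
    strong = SimSpec(p=10, rho_w=0.7, rho_b=0.1, missing_fraction=0, nuisance=False, seed=0)
    flat = strong.with_(rho_w=0.4, rho_b=0.4)  # no modular structure at all
    hits = 0
    for _ in range(10):
        ta = simulate_modular_sample(strong, 40, rng=rng)
        tb = simulate_modular_sample(flat, 40, rng=rng)
        ra = modularity_test(ta.coords, strong.hypothesis, nperm=400,
                             seed=int(rng.integers(2**31)), landmark_labels=ta.landmark_labels)
        rb = modularity_test(tb.coords, flat.hypothesis, nperm=400,
                             seed=int(rng.integers(2**31)), landmark_labels=tb.landmark_labels)
        comp = compare_modularity([ra, rb], ["strong", "weak"])
        hits += (comp.table[0]["p"] < 0.05) and (ra.z > rb.z)
    assert hits >= 7


def test_phylo_modularity_star_tree_reduces_to_plain_test(rng):
    n = 10
    newick = "(" + ",".join(f"s{i}:1" for i in range(n)) + ");"
    star = Tree.from_newick(newick)
    spec = SimSpec(p=8, missing_fraction=0, nuisance=False, seed=2)
    tab = simulate_modular_sample(spec, n, rng=rng)
    table = make_table(tab.coords, labels=tab.landmark_labels)
    table.specimen_ids[:] = [f"s{i}" for i in range(n)]
    table.species_ids[:] = [f"s{i}" for i in range(n)]
    r_star = phylo_modularity(table, star, spec.hypothesis, nperm=200, seed=6)
    r_plain = modularity_test(table, spec.hypothesis, nperm=200, seed=6)
    assert r_star.cr_obs == pytest.approx(r_plain.cr_obs, abs=1e-10)
    assert r_star.p == r_plain.p
    assert r_star.z == pytest.approx(r_plain.z, abs=1e-8)


def test_phylo_modularity_errors(rng):
    star = Tree.from_newick("(a:1,b:1,c:1,d:1);")
    coords = rng.standard_normal((3, 6, 3))
    with pytest.raises(ValueError, match="4 species"):
        phylo_modularity(coords, star, hyp_2mod(6), nperm=100)
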