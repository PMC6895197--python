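"""Phylogenetic signal, rates, ancestral states, trait models, shift search."""

import numpy as np
import pytest
from scipy import stats

from floramorph.io_formats import ModuleHypothesis
from floramorph.phylocomp import (
    PhyloContext,
    asr_discrete,
    detect_shifts,
    fit_trait_models,
    kmult,
    module_rates,
)
from floramorph.synthetic_data import SimSpec, simulate_species_means
from floramorph.trees import Tree, simulate_tree


def bm_data(tree, q, rng, scale=1.0):
    L = np.linalg.cholesky(tree.cov_matrix())
    return scale * (L @ rng.standard_normal((tree.n_tips, q)))


def ou_data(tree, alpha, rng, mean=None):
    C = tree.cov_matrix()
    T = tree.depth
    W = np.exp(-2 * alpha * (T - C)) * (1 - np.exp(-2 * alpha * C)) / (2 * alpha)
    y = np.linalg.cholesky(W) @ rng.standard_normal(tree.n_tips)
    return y if mean is None else y + mean


def test_kmult_scale_invariant_and_near_one_under_bm(rng):
    tree = simulate_tree(30, rng=rng)
    Y = bm_data(tree, 9, rng)
    r1 = kmult(Y, tree, nperm=9, seed=0)
    r2 = kmult(Y, tree.scaled(3.7), nperm=9, seed=0)
    assert r1.k_mult == pytest.approx(r2.k_mult, abs=1e-10)

    ks = []
    for _ in range(40):
        t = simulate_tree(30, rng=rng)
        ks.append(kmult(bm_data(t, 9, rng), t, nperm=9, seed=0).k_mult)
    assert 0.85 < np.mean(ks) < 1.15


def test_kmult_detects_signal_with_permutation_p(rng):
    tree = simulate_tree(25, rng=rng)
    Y = bm_data(tree, 12, rng)
    res = kmult(Y, tree, nperm=199, seed=1)
    assert res.p <= 0.05
    # destroying the tip order destroys the signal most of the time
    Yshuf = Y[rng.permutation(25)]
    res2 = kmult(Yshuf, tree, nperm=199, seed=1)
    assert res2.k_mult < res.k_mult


def test_gls_root_equals_mean_on_star_tree(rng):
    n = 8
    star = Tree.from_newick("(" + ",".join(f"s{i}:1" for i in range(n)) + ");")
    Y = rng.standard_normal((n, 5))
    ctx = PhyloContext.build(star, Y, star.tip_labels)
    assert np.allclose(ctx.C, np.eye(n))
    assert np.allclose(ctx.a_hat, Y.mean(axis=0), atol=1e-10)


def test_module_rates_recover_ratio_and_calibrate_null(rng):
    labels = [str(k) for k in range(1, 9)]
    hyp = ModuleHypothesis("h", {l: ("A" if int(l) <= 4 else "B") for l in labels})
    # 4:1 rates
    sig = 0
    ratios = []
    for _ in range(15):
        tree = simulate_tree(60, rng=rng)
        spec = SimSpec(p=8, hypothesis=hyp, sigma2_m={"A": 0.04, "B": 0.01},
                       n_groups=1, missing_fraction=0, nuisance=False,
                       seed=int(rng.integers(2**31)))
        means, _ = simulate_species_means(tree, spec, rng=rng)
        rr = module_rates(means, tree, hyp, nsim=99, seed=int(rng.integers(2**31)))
        ratios.append(rr.ratio)
        sig += rr.p <= 0.05
        assert rr.sigma2["A"] > rr.sigma2["B"]
    assert sig >= 13
    assert abs(np.median(ratios) - 4) / 4 < 0.35

    # equal rates: p roughly uniform, ratio near 1
    pvals = []
    for _ in range(30):
        tree = simulate_tree(40, rng=rng)
        spec = SimSpec(p=8, hypothesis=hyp, sigma2_m=0.02, n_groups=1,
                       missing_fraction=0, nuisance=False, seed=int(rng.integers(2**31)))
        means, _ = simulate_species_means(tree, spec, rng=rng)
        rr = module_rates(means, tree, hyp, nsim=49, seed=int(rng.integers(2**31)))
        pvals.append(rr.p)
    assert (np.array(pvals) <= 0.05).mean() < 0.2


def test_module_rate_estimates_unbiased_under_bm(rng):
    labels = [str(k) for k in range(1, 7)]
    hyp = ModuleHypothesis("h", {l: ("A" if int(l) <= 3 else "B") for l in labels})
    tree = simulate_tree(40, seed=77)
    ests = []
    for _ in range(150):
        spec = SimSpec(p=6, hypothesis=hyp, sigma2_m=0.03, n_groups=1,
                       missing_fraction=0, nuisance=False, seed=int(rng.integers(2**31)))
        means, _ = simulate_species_means(tree, spec, rng=rng)
        rr = module_rates(means, tree, hyp, nsim=0 + 1, seed=0)
        ests.append(rr.pooled_rate)
    assert np.mean(ests) == pytest.approx(0.03, rel=0.05)


def test_asr_all_tips_one_state(rng):
    tree = simulate_tree(10, rng=rng)
    states = {t: "bee" for t in tree.tip_labels}
    res = asr_discrete(tree, states, model="ER", states=["bee", "bird"])
    assert res["root"][res["states"].index("bee")] >= 0.999
    assert res["rates"][0] < 1e-3  # rate driven to the lower bound


def test_asr_two_tip_closed_form():
    """ER likelihood on a 2-tip tree equals the 2-state transition formula."""
    tree = Tree.from_newick("(A:0.6,B:0.4);")
    res = asr_discrete(tree, {"A": "x", "B": "y"}, model="ER")
    r = res["rates"][0]

    def p_same(t):
        return 0.5 * (1 + np.exp(-2 * r * t))

    def p_diff(t):
        return 0.5 * (1 - np.exp(-2 * r * t))

    # flat root prior over the two states, tips in different states
    lik = 0.5 * (p_same(0.6) * p_diff(0.4) + p_diff(0.6) * p_same(0.4))
    assert res["logL"] == pytest.approx(np.log(lik), abs=1e-6)


def test_asr_er_preferred_for_symmetric_character(rng):
    tree = simulate_tree(24, rng=rng)
    tips = tree.tip_labels
    states = {t: ("A" if i % 2 else "B") for i, t in enumerate(tips)}
    er = asr_discrete(tree, states, model="ER")
    ard = asr_discrete(tree, states, model="ARD")
    assert er["n_params"] == 1 and ard["n_params"] == 2
    assert ard["logL"] >= er["logL"] - 1e-6  # nesting
    assert er["AIC"] < ard["AIC"]  # symmetric data: extra rates not worth it
    with pytest.raises(ValueError, match="missing"):
        asr_discrete(tree, states, model="ER", states=["A"])


def test_trait_models_nesting_and_identification(rng):
    bm_wins = 0
    for _ in range(10):
        tree = simulate_tree(60, rng=rng)
        y = bm_data(tree, 1, rng).ravel()
        fits = {f.model: f for f in fit_trait_models(tree, y)}
        assert set(fits) == {"BM", "lambda", "EB", "OU"}
        # lambda and EB nest BM: their ML can only be better
        assert fits["lambda"].logL >= fits["BM"].logL - 1e-6
        assert fits["EB"].logL >= fits["BM"].logL - 1e-6
        bm_wins += fits["BM"].AICc <= min(f.AICc for f in fits.values()) + 1e-9
    # parsimony favours the generating model most of the time
    assert bm_wins >= 6


def test_trait_models_recover_ou_attraction(rng):
    hits = 0
    beats = 0
    for _ in range(15):
        tree = simulate_tree(100, rng=rng)
        y = ou_data(tree, alpha=2.0, rng=rng)
        fits = {f.model: f for f in fit_trait_models(tree, y)}
        a = fits["OU"].params["alpha"]
        hits += 1.0 <= a <= 4.0
        beats += fits["OU"].AICc < fits["BM"].AICc
    assert hits >= 12
    assert beats >= 13


def test_trait_models_require_ultrametric():
    tree = Tree.from_newick("(((A:1,B:2):1,(C:1,D:1):2):1,(E:1,F:3):2);")
    trait = {t: float(i) for i, t in enumerate("ABCDEF")}
    with pytest.raises(ValueError, match="ultrametric"):
        fit_trait_models(tree, trait, models=("OU",))


def test_detect_shifts_null_and_recovery(rng):
    # no-shift BM data: nothing selected, and selected BIC never above null
    zero = 0
    for _ in range(8):
        tree = simulate_tree(28, rng=rng)
        y = bm_data(tree, 1, rng).ravel()
        cfg = detect_shifts(tree, y, max_shifts=5)
        assert cfg.bic <= cfg.null_bic + 1e-9
        zero += len(cfg.shift_branches) == 0
    assert zero >= 6

    # one large optimum shift is found at (or next to) the true branch
    hits = 0
    for _ in range(8):
        tree = simulate_tree(28, rng=rng)
        T = tree.depth
        alpha = 3.0
        cands = [b for b in tree.branches()
                 if 4 <= len(b["tips"]) <= 9 and b["start"] <= 0.5]
        if not cands:
            hits += 1
            continue
        b = cands[int(rng.integers(len(cands)))]
        dtheta = 5 * np.sqrt(1 / (2 * alpha))
        shift = np.array([dtheta * (1 - np.exp(-alpha * (T - b["start"])))
                          if s in b["tips"] else 0.0 for s in tree.tip_labels])
        y = ou_data(tree, alpha, rng, mean=shift)
        cfg = detect_shifts(tree, y, max_shifts=5)
        truth = frozenset(b["tips"])
        every = frozenset(tree.tip_labels)
        ok = False
        for sb in cfg.shift_branches:
            sel = frozenset(sb["tips"])
            if (sel == truth or sel == every - truth
                    or (sel < truth and len(truth - sel) <= 2)
                    or (truth < sel and len(sel - truth) <= 2)):
                ok = True
        hits += ok
    assert hits >= 6


def _balanced_tree(depth=5):
    def rec(d, prefix):
        if d == 0:
            return prefix
        bl = 1.0 / depth
        return f"({rec(d - 1, prefix + '0')}:{bl},{rec(d - 1, prefix + '1')}:{bl})"
    return Tree.from_newick(rec(depth, "t") + ";")


def test_detect_shifts_convergent_regimes_merged(rng):
    """Two distant clades shifted to one shared optimum: both shifts are
    usually found and their optima merged into a convergent regime."""
    tree = _balanced_tree(5)
    T = tree.depth
    alpha = 2.0
    picks = [b for b in tree.branches()
             if len(b["tips"]) == 4 and (all(t.startswith("t000") for t in b["tips"])
                                         or all(t.startswith("t111") for t in b["tips"]))]
    assert len(picks) == 2
    dtheta = 8 * np.sqrt(1 / (2 * alpha))
    mean = np.zeros(tree.n_tips)
    for b in picks:
        w = dtheta * (1 - np.exp(-alpha * (T - b["start"])))
        for i, s in enumerate(tree.tip_labels):
            if s in b["tips"]:
                mean[i] = w
    both = merged = 0
    for _ in range(12):
        y = ou_data(tree, alpha, rng, mean=mean)
        cfg = detect_shifts(tree, y, max_shifts=5)
        assert cfg.bic <= cfg.null_bic + 1e-9
        both += len(cfg.shift_branches) >= 2
        merged += (len(cfg.shift_branches) >= 2 and len(cfg.convergent_regimes) >= 1)
    assert both >= 6
    assert merged >= 4


def test_detect_shifts_guards():
    tree = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    with pytest.raises(ValueError, match="max_shifts"):
        detect_shifts(tree, {"A": 0, "B": 0, "C": 1, "D": 1.0}, max_shifts=10)
    bad = Tree.from_newick("((A:1,B:2):1,(C:1,D:1):2);")
    with pytest.raises(ValueError, match="ultrametric"):
        detect_shifts(bad, {"A": 0, "B": 0, "C": 1, "D": 1.0}, max_shifts=2)
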