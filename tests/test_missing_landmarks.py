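"""TPS / MS / REG imputation, validation harness, and observer error."""

import numpy as np
import pytest

from floramorph.io_formats import LandmarkTable
from floramorph.missing_landmarks import (
    ThinPlateSpline3D,
    estimate_missing,
    observer_error,
    validate_estimation,
)
from floramorph.synthetic_data import SimSpec, simulate_modular_sample

from conftest import make_table


def damage(table, spec_idx, landmark_idx):
    coords = table.coords.copy()
    mask = table.missing_mask.copy()
    coords[spec_idx, landmark_idx] = np.nan
    mask[spec_idx, landmark_idx] = True
    return LandmarkTable(list(table.specimen_ids), list(table.species_ids),
                         list(table.groups), list(table.landmark_labels), coords, mask)


def affine_family(rng, n, p=14, eps=0.12):
    """Specimens that are random affine images of one base shape."""
    base = rng.standard_normal((p, 3))
    coords = np.array([base @ (np.eye(3) + eps * rng.standard_normal((3, 3)))
                       + rng.uniform(-1, 1, 3) for _ in range(n)])
    return make_table(coords)


def test_tps_is_exact_interpolant(rng):
    src = rng.standard_normal((12, 3))
    tgt = src + 0.2 * rng.standard_normal((12, 3))
    warp = ThinPlateSpline3D(src, tgt)
    assert np.abs(warp(src) - tgt).max() < 1e-8
    # affine maps are reproduced exactly everywhere, not just at control points
    A = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
    warp2 = ThinPlateSpline3D(src, src @ A + 1.5)
    probe = rng.standard_normal((30, 3))
    assert np.abs(warp2(probe) - (probe @ A + 1.5)).max() < 1e-8


def test_tps_rejects_degenerate_control_points():
    src = np.zeros((5, 3))
    with pytest.raises(ValueError):
        ThinPlateSpline3D(src, src)


def test_complete_table_returned_unchanged(rng):
    tab = affine_family(rng, 5)
    assert estimate_missing(tab, "TPS") is tab


@pytest.mark.parametrize("method", ["TPS", "MS", "REG"])
def test_affine_specimens_recovered_exactly_by_tps(rng, method):
    tab = affine_family(rng, 6)
    dam = damage(tab, 0, [2, 5, 9])
    est = estimate_missing(dam, method=method)
    assert not est.has_missing
    err = np.abs(est.coords[0, [2, 5, 9]] - tab.coords[0, [2, 5, 9]]).max()
    if method == "TPS":
        assert err < 1e-8  # the warp is affine and TPS reproduces it exactly
    else:
        assert err < 0.5  # MS/REG land in the right neighbourhood only
    # untouched specimens identical
    assert np.array_equal(est.coords[1:], tab.coords[1:])


def test_tps_beats_mean_substitution_on_structured_data(rng):
    wins = 0
    for rep in range(15):
        tab = affine_family(rng, 8, eps=0.15)
        gone = rng.choice(14, size=5, replace=False)
        dam = damage(tab, 0, gone)
        e_tps = estimate_missing(dam, "TPS")
        e_ms = estimate_missing(dam, "MS")
        err_tps = np.linalg.norm(e_tps.coords[0, gone] - tab.coords[0, gone])
        err_ms = np.linalg.norm(e_ms.coords[0, gone] - tab.coords[0, gone])
        wins += err_tps < err_ms
    assert wins >= 12


def test_too_few_anchor_landmarks_rejected(rng):
    tab = affine_family(rng, 5, p=8)
    dam = damage(tab, 0, [0, 1, 2, 3, 4])  # only 3 shared left
    with pytest.raises(ValueError, match="4"):
        estimate_missing(dam, "TPS")


def test_estimation_error_monotone_in_noise(rng):
    base_spec = SimSpec(p=12, missing_fraction=0, nuisance=False, seed=8)
    errors = []
    for sd in (0.01, 0.05, 0.2):
        spec = base_spec.with_(within_sd=sd)
        errs = []
        for rep in range(10):
            tab = simulate_modular_sample(spec, 8, rng=rng)
            gone = rng.choice(12, size=3, replace=False)
            dam = damage(tab, 0, gone)
            est = estimate_missing(dam, "TPS")
            errs.append(np.linalg.norm(est.coords[0, gone] - tab.coords[0, gone]))
        errors.append(np.mean(errs))
    assert errors[0] < errors[1] < errors[2]


def test_validate_estimation_bookkeeping_and_reproducibility(rng):
    spec = SimSpec(p=12, within_sd=0.03, missing_fraction=0, nuisance=False, seed=4)
    tab = simulate_modular_sample(spec, 8, rng=rng)
    rep1 = validate_estimation(tab, methods=("TPS", "MS"), nreps=6, kmax=4,
                               seed=3, protest_nperm=49)
    assert set(rep1) == {"TPS", "MS"}
    for r in rep1.values():
        assert len(r.protest_correlations) == 6
        assert len(r.protest_p) == 6
        assert r.per_landmark_error.shape == (12,)
        assert np.all((r.t_p >= 0) & (r.t_p <= 1))
        assert np.all((r.f_p >= 0) & (r.f_p <= 1))
        counted = r.per_landmark_count > 0
        assert np.all(r.per_landmark_error[counted] >= 0)
    rep2 = validate_estimation(tab, methods=("TPS", "MS"), nreps=6, kmax=4,
                               seed=3, protest_nperm=49)
    assert np.array_equal(rep1["TPS"].protest_correlations,
                          rep2["TPS"].protest_correlations)
    assert np.array_equal(rep1["TPS"].per_landmark_error,
                          rep2["TPS"].per_landmark_error, equal_nan=True)


def test_validate_estimation_significant_protest_on_realistic_data(rng):
    spec = SimSpec(p=14, within_sd=0.04, missing_fraction=0, nuisance=False, seed=9)
    tab = simulate_modular_sample(spec, 10, rng=rng)
    reports = validate_estimation(tab, methods=("TPS",), nreps=10, kmax=6,
                                  seed=5, protest_nperm=199)
    assert (reports["TPS"].protest_p <= 0.05).all()


def test_validate_estimation_guard_rails(rng):
    spec = SimSpec(p=8, missing_fraction=0, nuisance=False, seed=2)
    tab = simulate_modular_sample(spec, 6, rng=rng)
    with pytest.raises(ValueError, match="kmax"):
        validate_estimation(tab, nreps=2, kmax=5)
    dam = damage(tab, 0, [0])
    with pytest.raises(ValueError, match="intact"):
        validate_estimation(dam, nreps=2, kmax=2)


def test_observer_error_identical_replicates_zero(rng):
    base = rng.standard_normal((10, 3))
    reps = make_table(np.array([base] * 4))
    ind = make_table(np.array([base + 0.1 * rng.standard_normal((10, 3))
                               for _ in range(5)]))
    out = observer_error(reps, ind)
    assert out["mean_replicate_error"] == pytest.approx(0.0, abs=1e-9)
    assert out["mean_independent_error"] > 1e-3


def test_observer_error_detects_precision_gap(rng):
    """Replicates 20x tighter than independents: F tests fire, errors more than
    an order of magnitude apart."""
    spec = SimSpec(p=10, missing_fraction=0, nuisance=False, seed=1)
    sig = 0
    ratios = []
    for run in range(10):
        reps = simulate_modular_sample(spec.with_(within_sd=0.002), 10, rng=rng)
        ind = simulate_modular_sample(spec.with_(within_sd=0.04), 10, rng=rng)
        out = observer_error(reps, ind)
        sig += (out["f_p"] < 0.05).all()
        ratios.append(out["error_ratio"])
    assert sig >= 9
    assert np.median(ratios) >= 10


def test_observer_error_label_mismatch(rng):
    a = make_table(rng.standard_normal((3, 5, 3)))
    b = make_table(rng.standard_normal((3, 5, 3)), labels=["9", "8", "7", "6", "5"])
    with pytest.raises(ValueError, match="labels"):
        observer_error(a, b)
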