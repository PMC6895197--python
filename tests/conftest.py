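import numpy as np
import pytest

from floramorph.io_formats import LandmarkTable, ModuleHypothesis
from floramorph.synthetic_data import SimSpec, simulate_modular_sample


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_module_hypothesis():
    labels = [str(k) for k in range(1, 13)]
    return ModuleHypothesis(
        "H2mod", {lab: ("A" if int(lab) <= 6 else "B") for lab in labels}, ["A", "B"]
    )


@pytest.fixture
def modular_spec(two_module_hypothesis):
    return SimSpec(p=12, hypothesis=two_module_hypothesis, rho_w=0.7, rho_b=0.1,
                   within_sd=0.05, missing_fraction=0.0, nuisance=False, seed=11)


@pytest.fixture
def modular_table(modular_spec):
    return simulate_modular_sample(modular_spec, 30)


def make_table(coords, species=None, groups=None, mask=None, labels=None):
    coords = np.asarray(coords, dtype=float)
    n, p, _ = coords.shape
    ids = [f"s{i}" for i in range(n)]
    return LandmarkTable(
        ids,
        species if species is not None else ids,
        groups if groups is not None else [""] * n,
        labels if labels is not None else [str(k + 1) for k in range(p)],
        coords,
        mask if mask is not None else np.zeros((n, p), dtype=bool),
    )
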