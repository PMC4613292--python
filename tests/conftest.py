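import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from barcodegap.distance import DistanceMatrix
from barcodegap.simulate import GenusSimConfig, simulate_genus

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_dm(ids, values):
    arr = np.asarray(values, dtype=float)
    sites = np.full(arr.shape, 100, dtype=np.int64)
    return DistanceMatrix(list(ids), arr, sites)


@pytest.fixture
def worked_example():
    """Species A={a1,a2}, d(a1,a2)=0.01; B={b1}, d(a1,b1)=0.20, d(a2,b1)=0.22.

    Hand enumeration: all_intra=0.01, theta=0.01, coalescent_depth=0.01,
    all_inter=0.21, theta_prime=0.21 (A:0.21, B:0.21), min_inter=0.20.
    """
    dm = make_dm(
        ["a1", "a2", "b1"],
        [[0.0, 0.01, 0.20], [0.01, 0.0, 0.22], [0.20, 0.22, 0.0]],
    )
    labels = {"a1": "A", "a2": "A", "b1": "B"}
    return dm, labels


@pytest.fixture(scope="session")
def small_genus():
    """8 species x 4 samples at default divergences, fixed seed."""
    cfg = GenusSimConfig(n_species=8, samples_per_species=4, seed=42)
    return simulate_genus(cfg) + (cfg,)


@pytest.fixture(scope="session")
def planted_genus():
    """10 species x 4 samples with 2 planted identical species pairs."""
    cfg = GenusSimConfig(n_species=10, samples_per_species=4,
                         n_identical_pairs=2, seed=42)
    return simulate_genus(cfg) + (cfg,)
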