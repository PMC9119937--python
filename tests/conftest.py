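import numpy as np
import pytest

from tiffms.simulate import DriftParams, SimConfig, simulate_library, simulate_run


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured study: 4 CVs, mixed species, unknowns."""
    return SimConfig(n_target_peptides=150, n_entrap_peptides=60,
                     n_unknown_features=200, seed=7)


@pytest.fixture(scope="session")
def small_library(small_config):
    return simulate_library(small_config)


@pytest.fixture(scope="session")
def small_run(small_library):
    library, truth = small_library
    features, links = simulate_run(truth, run_seed=1)
    return features, links


@pytest.fixture(scope="session")
def noise_free_config():
    """Perfect-information limit: no mass/RT error, no dropout, no unknowns."""
    return SimConfig(n_target_peptides=120, n_entrap_peptides=50,
                     n_unknown_features=0, dropout=0.0, ppm_sd=0.0,
                     rt_noise_sd=0.0, drift=DriftParams(), seed=11)


def align_with_truth(features, truth):
    """Set rt_aligned from the true warp (bypasses anchor fitting)."""
    for f in features:
        f.rt_aligned = float(truth.warp(f.rt_apex))
    return features


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
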