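import numpy as np
import pytest

from nmrstress import (
    SimConfig,
    default_effects,
    default_library,
    preprocess_cohort,
    simulate_cohort,
)

#: point count used for cohort fixtures and replicate studies; bins stay far
#: wider than the linewidth and far narrower than any exclusion window, so
#: the pipeline behaves as at full resolution at a fraction of the cost
STUDY_POINTS = 8192


@pytest.fixture(scope="session")
def lib():
    return default_library()


@pytest.fixture(scope="session")
def effect_cohort(lib):
    """A 32-sample crossover cohort carrying the study fold changes."""
    cfg = SimConfig(n_points=STUDY_POINTS, effects=default_effects(), seed=1)
    return simulate_cohort(cfg, lib)


@pytest.fixture(scope="session")
def effect_matrix(effect_cohort):
    spectra, design, _ = effect_cohort
    return preprocess_cohort(spectra, design)


@pytest.fixture(scope="session")
def null_cohort(lib):
    """Same design with no treatment effects (permutation-null conditions)."""
    cfg = SimConfig(n_points=STUDY_POINTS, effects={}, seed=7)
    return simulate_cohort(cfg, lib)


@pytest.fixture(scope="session")
def null_matrix(null_cohort):
    spectra, design, _ = null_cohort
    return preprocess_cohort(spectra, design)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
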