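import warnings

import numpy as np
import pytest

from microbiometab.preprocess import (log_then_autoscale, normalize_internal_standard,
                                      rarefy, relative_abundance)
from microbiometab.simulate import SimulationParams, fixture_small, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic tiny cohort used across the suite."""
    return fixture_small()


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    otu, met, labels, truth = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        processed, _ = log_then_autoscale(normalize_internal_standard(met))
        relative = relative_abundance(rarefy(otu, seed=7))
    return processed, relative, labels, truth


@pytest.fixture(scope="session")
def study_scale_cohort():
    """One 17/6/20 cohort at study scale (150 taxa, 224 metabolites)."""
    return simulate_cohort(SimulationParams(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
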