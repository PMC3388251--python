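import numpy as np
import pytest

from cfscreen import (
    AncestryStratum,
    PopulationConfig,
    default_biomarker_model,
    generate_cohort,
)


@pytest.fixture(scope="session")
def model():
    """Shipped biomarker model (calibrated unaffected IRT + defaults)."""
    return default_biomarker_model()


@pytest.fixture(scope="session")
def small_cohort(model):
    """A 5,000-newborn default-strata cohort, fixed seed."""
    return generate_cohort(PopulationConfig(cohort_size=5_000, seed=42), model)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def single_stratum_config():
    """One general-population stratum at carrier frequency 1:30."""
    return PopulationConfig(
        cohort_size=100,
        strata=(AncestryStratum("general", 1.0, 1.0 / 30.0, 0.95),),
        seed=7,
    )
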