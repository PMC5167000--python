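import numpy as np
import pytest

from cortasym import SimulationConfig, generate_cohort

SMALL_REGIONS = (
    "G_insular_short",
    "S_orbital_med-olfact",
    "G_occipital_middle",
    "S_circular_insula_ant",
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_early=60,
        n_late=50,
        regions=SMALL_REGIONS,
        rate_early=-0.06,
        rate_late=-0.02,
        noise_sd=0.15,
        seed=20160101,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(cohort, thickness, truth) for a modest 4-region synthetic cohort."""
    return generate_cohort(small_config)
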