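import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spectramt as sm

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim_config() -> sm.SimConfig:
    """Down-scaled campaign: 6 eggs/variety on a 60-band grid."""
    base = sm.default_egg_sim_config(seed=7)
    return base.replace(
        grid=sm.WavelengthGrid(np.linspace(1000.0, 2500.0, 60)),
        n_eggs_per_variety=9,
    )


@pytest.fixture(scope="session")
def small_table(small_sim_config) -> sm.SpectraTable:
    return sm.simulate_dataset(small_sim_config)


@pytest.fixture(scope="session")
def small_snv_table(small_table) -> sm.SpectraTable:
    return sm.snv_table(small_table)
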