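import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from swanstage import (ModelParams, SluiceModel, WaterLevelSeries,
                       simulate_lake_level, study_forcing, synth_patches,
                       year_schedule, year_window)

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def patches_2005():
    """Four-patch landscape at the 2005 measured mean densities."""
    return synth_patches(2005, se_scale=0.0)


@pytest.fixture(scope="session")
def forcing_2005():
    """Canonical synthetic sea-side forcing for the 2005 window."""
    return study_forcing(2005)


@pytest.fixture(scope="session")
def lake_2005(forcing_2005):
    """Managed lake levels under the current target (-0.93 m NAP)."""
    return simulate_lake_level(forcing_2005, SluiceModel())


@pytest.fixture(scope="session")
def schedule_2005():
    return year_schedule(2005, 4500)


@pytest.fixture()
def flat_lake_10d():
    """Ten days of lake level held exactly at the reference target."""
    return WaterLevelSeries(start=pd.Timestamp("2005-10-01"),
                            levels=np.full(240, -0.93))
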