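import numpy as np
import pytest

from marinecast import (
    ForecastSkillProfile,
    HeatwaveSpec,
    make_grid,
    simulate_forecasts,
    simulate_observed_sst,
)


@pytest.fixture(scope="session")
def cce_grid():
    """Coarse grid over the full West Coast study domain (all ocean)."""
    return make_grid(resolution_deg=1.0)


@pytest.fixture(scope="session")
def small_grid():
    """Compact coastal domain covering both index regions, cheap to simulate."""
    return make_grid(lat_range=(30.0, 42.0), lon_range=(-126.0, -115.5), resolution_deg=1.0)


@pytest.fixture(scope="session")
def observed_world(small_grid):
    """32-year observed world with a 2005-2006 warm extreme."""
    return simulate_observed_sst(
        small_grid,
        year_range=(1981, 2012),
        seed=101,
        heatwaves=[HeatwaveSpec("2005-03", "2006-12", 2.0)],
    )


@pytest.fixture(scope="session")
def small_forecasts(observed_world):
    """5-member monthly-initialized retrospective ensemble."""
    return simulate_forecasts(
        observed_world,
        ForecastSkillProfile(rho0=0.9, decay=0.97, drift_bias=0.1),
        n_members=5,
        seed=202,
        clim_years=(1981, 2010),
    )
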