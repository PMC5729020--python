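import numpy as np
import pandas as pd
import pytest

import tempmort as tm
from tempmort.synth import generate_location


@pytest.fixture(scope="session")
def quad_surface():
    return tm.quadratic_risk_surface()


@pytest.fixture(scope="session")
def obs_series(quad_surface):
    """One location, 8 years, moderate overdispersion."""
    spec = tm.SyntheticLocationSpec(n_years=8, seed=42, overdispersion=1.3)
    return spec, generate_location(spec, quad_surface)


@pytest.fixture(scope="session")
def fitted_curve(obs_series):
    _, series = obs_series
    return tm.fit_location(series)


@pytest.fixture(scope="session")
def small_ensemble():
    """12 locations on the shared basis, known GDP effect and heterogeneity."""
    return tm.make_multilocation_ensemble(
        12, heterogeneity_sd=0.02, seed=7, n_years=6
    )


def linear_curve(theta0: float = 1.0, center: float = 10.0) -> tm.ReducedCurve:
    """Curve on the 1-column (linear) basis: log-RR = theta0 * (x - c) / span."""
    return tm.ReducedCurve(
        location_id="lin",
        theta=np.array([theta0]),
        V=np.zeros((1, 1)),
        var_knots=np.array([]),
        var_boundary=(0.0, 30.0),
        centering_value=center,
        temp_percentiles={1.0: 2.0, 50.0: 15.0, 99.0: 28.0},
    )


def constant_inputs(
    n_days: int = 400,
    temp: float = 20.0,
    deaths: float = 30.0,
    start: str = "2010-01-01",
) -> tm.ProjectionInputs:
    dates = pd.date_range(start, periods=n_days, freq="D")
    return tm.ProjectionInputs(
        location_id="loc",
        gcm_id="GCM1",
        rcp_id="RCP8.5",
        dates=dates,
        tmean=np.full(n_days, temp),
        expected_deaths=np.full(n_days, deaths),
    )
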