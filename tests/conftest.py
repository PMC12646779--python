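import numpy as np
import pandas as pd
import pytest

from movestrat.occurrence import GridSpec, OccurrenceDistribution
from movestrat.simulate import default_strategy_params, simulate_trajectory


def make_od(mass, cell_size=150.0, x0=0.0, y0=0.0, window_id="w"):
    """OD from a raw nonnegative array (normalized here for convenience)."""
    mass = np.asarray(mass, float)
    grid = GridSpec(x0=x0, y0=y0, cell_size=cell_size,
                    n_cols=mass.shape[1], n_rows=mass.shape[0])
    return OccurrenceDistribution(grid=grid, mass=mass / mass.sum(),
                                  window_id=window_id)


@pytest.fixture(scope="session")
def resident_track():
    return simulate_trajectory(default_strategy_params("resident"), seed=11)


@pytest.fixture(scope="session")
def dual_track():
    return simulate_trajectory(default_strategy_params("dual_range"), seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def brownian_track(sigma2_m, n_fixes, dt_h=1.0, seed=0, loc_error_sd=0.0):
    """Pure Brownian motion fixes at a regular interval (no mean reversion)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(sigma2_m * dt_h), size=(n_fixes - 1, 2))
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    if loc_error_sd > 0:
        xy = xy + rng.normal(0.0, loc_error_sd, size=xy.shape)
    ts = pd.date_range("2020-01-01", periods=n_fixes,
                       freq=pd.Timedelta(hours=dt_h), tz="UTC")
    return pd.DataFrame({"timestamp": ts, "x": xy[:, 0], "y": xy[:, 1],
                         "loc_error_sd": loc_error_sd})
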