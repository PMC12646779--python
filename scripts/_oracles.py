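"""Independent oracles and synthetic inputs used by the acceptance script."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import beta as beta_dist

from movestrat.betareg import compress_boundary
from movestrat.occurrence import GridSpec, OccurrenceDistribution

STRATS = ("resident", "dual_range_migrant", "multi_range_migrant")


def make_od(mass, cell_size=150.0, x0=0.0, y0=0.0, window_id="w"):
    mass = np.asarray(mass, float)
    grid = GridSpec(x0=x0, y0=y0, cell_size=cell_size,
                    n_cols=mass.shape[1], n_rows=mass.shape[0])
    return OccurrenceDistribution(grid=grid, mass=mass / mass.sum(),
                                  window_id=window_id)


def brownian_track(sigma2_m, n_fixes, dt_h=1.0, seed=0, loc_error_sd=0.0):
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(sigma2_m * dt_h), size=(n_fixes - 1, 2))
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    if loc_error_sd > 0:
        xy = xy + rng.normal(0.0, loc_error_sd, size=xy.shape)
    ts = pd.date_range("2020-01-01", periods=n_fixes,
                       freq=pd.Timedelta(hours=dt_h), tz="UTC")
    return pd.DataFrame({"timestamp": ts, "x": xy[:, 0], "y": xy[:, 1],
                         "loc_error_sd": loc_error_sd})


def grid_search_intercept_mu(y):
    """Profile the intercept-only Beta likelihood over mu on a fine grid."""
    yc = compress_boundary(np.asarray(y, float))

    def nll_at(mu):
        def inner(log_phi):
            phi = np.exp(log_phi)
            return -beta_dist.logpdf(yc, mu * phi, (1 - mu) * phi).sum()
        return minimize_scalar(inner, bounds=(-3, 12), method="bounded").fun

    mus = np.linspace(0.01, 0.99, 981)
    coarse = mus[np.argmin([nll_at(m) for m in mus])]
    fine = np.linspace(coarse - 2e-3, coarse + 2e-3, 401)
    return float(fine[np.argmin([nll_at(m) for m in fine])])


def synthetic_tables(n_per_strategy, seed, yty_effect=0.0, phi=15.0):
    """Cohort tables whose overlap responses are Beta draws; the logit-mean
    responds to the two year-to-year predictors with slope ``yty_effect``."""
    rng = np.random.default_rng(seed)
    n = 3 * n_per_strategy
    ids = [f"A{i:03d}" for i in range(n)]
    yty_sl = rng.normal(size=n)
    yty_bm = rng.normal(size=n)
    spatial = 0.3 * yty_sl + rng.normal(size=n)
    driver = yty_effect * (0.8 * yty_sl + 0.5 * yty_bm)

    def draw(eta):
        mu = expit(eta)
        return rng.beta(mu * phi, (1 - mu) * phi)

    metrics = pd.DataFrame({
        "animal_id": ids,
        "seasonal_overlap": draw(-0.3 + driver),
        "winter_overlap": draw(0.2 + driver),
        "annual_overlap": draw(-0.1 + driver),
        "summer_overlap": draw(1.0 + 0 * driver),
        "complete": True,
    })
    assignments = pd.DataFrame({
        "animal_id": ids,
        "strategy": np.repeat(STRATS, n_per_strategy),
    })
    variation = pd.DataFrame({
        "animal_id": ids,
        "spatial_variation_score": spatial,
        "yty_spring_length_sd": yty_sl,
        "yty_biomass_sd": yty_bm,
        "winter_conditions": rng.normal(30, 5, n),
        "winter_severity": rng.normal(size=n),
        "pct_agriculture": rng.uniform(0, 0.5, n),
        "dist_roads": rng.uniform(500, 9000, n),
    })
    return metrics, assignments, variation
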