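"""Synthetic trajectories and landscapes with known ground truth.

Every downstream stage of the pipeline (occurrence estimation, overlap
metrics, strategy classification, resource-variation summaries, model
selection) is verified against cohorts produced here, because the generating
movement strategy and the generating landscape variances are known exactly.

Trajectories follow a discrete-time Ornstein--Uhlenbeck (OU) process whose
attraction centre moves on a seasonal schedule:

    x_{t+dt} = x_t + a * (mu(t) - x_t) * dt + step_sd * sqrt(dt) * eps,

with ``a`` the mean-reversion rate (1/h), ``step_sd`` the diffusive scale
(m / sqrt(h)) and ``eps`` standard bivariate normal.  The centre ``mu(t)``
sits on the summer centre during June--August, on the winter centre during
December--February, and moves linearly between them during the shoulder
seasons.  Three strategies are generated:

* ``resident`` -- winter centre equals summer centre;
* ``dual_range`` -- a fixed winter centre ``winter_centre_distance`` metres
  from the summer centre, reused every year;
* ``multi_range`` -- a fresh winter centre drawn uniformly on the circle of
  radius ``winter_centre_distance`` each winter.

Landscapes are stacks of Gaussian random fields (smoothed white noise) per
covariate and year.  Annual covariates receive an additive year effect drawn
``Normal(0, yty_sd**2)``, so the SD of annual field means is controlled
directly; static covariates (elevation, percent agriculture, distance to
roads) have no year effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .occurrence import GridSpec

STRATEGIES = ("resident", "dual_range", "multi_range")

#: covariates every landscape must carry
REQUIRED_COVARIATES = (
    "spring_length",
    "biomass",
    "snow_depth",
    "elevation",
    "pct_agriculture",
    "dist_roads",
)

STATIC_COVARIATES = frozenset({"elevation", "pct_agriculture", "dist_roads"})

#: reference correlation length (m) at which ``spatial_sd`` is attained
REFERENCE_CORR_LENGTH = 1500.0

#: per-covariate (mean, spatial SD at reference corr_length, lower clip, upper clip)
COVARIATE_FIELDS: Mapping[str, tuple[float, float, float, float]] = {
    "spring_length": (75.0, 10.0, 0.0, np.inf),     # days
    "biomass": (900.0, 200.0, 0.0, np.inf),         # lbs / acre
    "snow_depth": (40.0, 12.0, 0.0, np.inf),        # cm, winter mean
    "elevation": (2000.0, 300.0, 0.0, np.inf),      # m
    "pct_agriculture": (0.3, 0.1, 0.0, 1.0),        # proportion
    "dist_roads": (5000.0, 2000.0, 0.0, np.inf),    # m
}

#: default year-to-year SD of annual field means, per annual covariate
DEFAULT_YTY_SD: Mapping[str, float] = {
    "spring_length": 6.0,   # days
    "biomass": 120.0,       # lbs / acre
    "snow_depth": 8.0,      # cm
}


@dataclass
class StrategyParams:
    """Generating parameters for one animal's movement strategy."""

    strategy: str = "resident"
    summer_centre: tuple[float, float] = (0.0, 0.0)
    winter_centre_distance: float = 0.0
    winter_redraw: bool = False
    attraction: float = 0.05          # 1/h
    step_sd: float = 300.0            # m / sqrt(h)
    fix_interval: float = 2.0         # h
    start_date: str = "2018-05-01"
    n_months: int = 22

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for name in ("attraction", "step_sd", "fix_interval",
                     "winter_centre_distance"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.attraction <= 0:
            raise ValueError("attraction must be > 0")
        if self.step_sd < 0:
            raise ValueError("step_sd must be >= 0")
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be > 0")
        if not 21 <= self.n_months <= 23:
            raise ValueError("n_months must lie in [21, 23]")
        if self.strategy == "resident" and self.winter_centre_distance != 0:
            raise ValueError("resident implies winter_centre_distance == 0")
        if not all(np.isfinite(self.summer_centre)):
            raise ValueError("summer_centre must be finite")

    @property
    def stationary_sd(self) -> float:
        """Stationary OU positional SD per axis: step_sd / sqrt(2 * attraction)."""
        return self.step_sd / np.sqrt(2.0 * self.attraction)


def default_strategy_params(strategy: str, **overrides) -> StrategyParams:
    """Study-condition defaults for each strategy (30 km seasonal displacement)."""
    base = dict(strategy=strategy)
    if strategy != "resident":
        base["winter_centre_distance"] = 30_000.0
    if strategy == "multi_range":
        base["winter_redraw"] = True
    base.update(overrides)
    return StrategyParams(**base)


@dataclass
class LandscapeParams:
    """Generating parameters for a covariate raster stack."""

    grid_extent: float = 150_000.0    # m (square landscape)
    cell_size: float = 150.0          # m
    corr_length: float = 1500.0       # m, spatial autocorrelation scale
    n_years: int = 3
    start_year: int = 2018
    yty_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_YTY_SD))
    covariate_names: Sequence[str] = REQUIRED_COVARIATES

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.corr_length < self.cell_size:
            raise ValueError("corr_length must be >= cell_size")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        missing = set(REQUIRED_COVARIATES) - set(self.covariate_names)
        if missing:
            raise ValueError(f"covariate_names missing {sorted(missing)}")
        if any(v < 0 for v in self.yty_sd.values()):
            raise ValueError("yty_sd entries must be >= 0")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))


@dataclass
class CovariateStack:
    """Per-covariate, per-year raster layers on a common grid.

    ``layers[name]`` has shape (n_years, n_rows, n_cols) for annual covariates
    and (n_rows, n_cols) for static ones.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    years: list[int]

    def is_static(self, name: str) -> bool:
        return self.layers[name].ndim == 2

    @property
    def covariates(self) -> list[str]:
        return list(self.layers)

    def annual(self, name: str) -> np.ndarray:
        """Layers of ``name`` as (n_years, n_rows, n_cols), tiling static ones."""
        arr = self.layers[name]
        if arr.ndim == 2:
            return np.broadcast_to(arr, (len(self.years),) + arr.shape)
        return arr

    def mean_over_years(self, name: str) -> np.ndarray:
        arr = self.layers[name]
        return arr if arr.ndim == 2 else arr.mean(axis=0)


# ---------------------------------------------------------------------------
# seasonal centre schedule
# ---------------------------------------------------------------------------

def _season_weights(ts: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray]:
    """Return (w, winter_year): w=0 on the summer centre, w=1 on the winter centre.

    Winter of year t spans Dec(t)--Feb(t+1); the shoulder seasons interpolate
    linearly in time.
    """
    year = ts.year.to_numpy()
    month = ts.month.to_numpy()
    w = np.zeros(len(ts))
    winter_year = year.copy()

    autumn = (month >= 9) & (month <= 11)
    if autumn.any():
        t0 = pd.to_datetime({"year": year[autumn], "month": 9, "day": 1}, utc=True)
        t1 = pd.to_datetime({"year": year[autumn], "month": 12, "day": 1}, utc=True)
        frac = (ts[autumn].tz_convert("UTC") - pd.DatetimeIndex(t0)) / (
            pd.DatetimeIndex(t1) - pd.DatetimeIndex(t0))
        w[autumn] = frac
    winter = (month == 12) | (month <= 2)
    w[winter] = 1.0
    winter_year[month <= 2] -= 1
    spring = (month >= 3) & (month <= 5)
    if spring.any():
        t0 = pd.to_datetime({"year": year[spring], "month": 3, "day": 1}, utc=True)
        t1 = pd.to_datetime({"year": year[spring], "month": 6, "day": 1}, utc=True)
        frac = (ts[spring].tz_convert("UTC") - pd.DatetimeIndex(t0)) / (
            pd.DatetimeIndex(t1) - pd.DatetimeIndex(t0))
        w[spring] = 1.0 - frac
        winter_year[spring] -= 1
    return w, winter_year


def simulate_trajectory(params: StrategyParams, seed: int,
                        loc_error_sd: float = 20.0) -> pd.DataFrame:
    """Simulate one animal's OU track; columns timestamp, x, y, loc_error_sd.

    Reproducible for fixed (params, seed).  The returned positions are the true
    OU states; ``loc_error_sd`` is recorded as the nominal GPS error for
    downstream occurrence estimation (it is metadata, not added noise, so that
    generator truth stays exact).
    """
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(params.start_date, tz="UTC")
    end = start + pd.DateOffset(months=params.n_months)
    ts = pd.date_range(start, end, freq=pd.Timedelta(hours=params.fix_interval),
                       inclusive="left")
    n = len(ts)

    sx, sy = params.summer_centre
    w, winter_year = _season_weights(ts)

    # winter centre per winter-year
    wyears = np.unique(winter_year)
    centres: dict[int, tuple[float, float]] = {}
    fixed_angle = rng.uniform(0, 2 * np.pi)
    for wy in wyears:
        if params.strategy == "resident" or params.winter_centre_distance == 0:
            centres[wy] = (sx, sy)
        elif params.winter_redraw:
            ang = rng.uniform(0, 2 * np.pi)
            centres[wy] = (sx + params.winter_centre_distance * np.cos(ang),
                           sy + params.winter_centre_distance * np.sin(ang))
        else:
            centres[wy] = (sx + params.winter_centre_distance * np.cos(fixed_angle),
                           sy + params.winter_centre_distance * np.sin(fixed_angle))
    wx = np.array([centres[wy][0] for wy in winter_year])
    wy_ = np.array([centres[wy][1] for wy in winter_year])
    mu_x = sx + w * (wx - sx)
    mu_y = sy + w * (wy_ - sy)

    dt = params.fix_interval
    a = params.attraction
    noise = params.step_sd * np.sqrt(dt) * rng.standard_normal((n, 2))
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = mu_x[0], mu_y[0]
    adt = a * dt
    for i in range(1, n):
        x[i] = x[i - 1] + adt * (mu_x[i - 1] - x[i - 1]) + noise[i, 0]
        y[i] = y[i - 1] + adt * (mu_y[i - 1] - y[i - 1]) + noise[i, 1]

    return pd.DataFrame({
        "timestamp": ts,
        "x": x,
        "y": y,
        "loc_error_sd": loc_error_sd,
    })


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma_cells: float, amplitude: float) -> np.ndarray:
    """Gaussian random field: white noise convolved with a Gaussian kernel.

    ``amplitude`` is calibrated so the field SD equals the covariate's nominal
    spatial SD when sigma_cells corresponds to REFERENCE_CORR_LENGTH; for a 2-D
    Gaussian kernel the smoothing shrinks white-noise SD by ~1/(2*sigma*sqrt(pi)).
    """
    noise = rng.standard_normal(shape)
    return amplitude * gaussian_filter(noise, sigma=sigma_cells, mode="reflect")


def simulate_landscape(params: LandscapeParams, seed: int) -> CovariateStack:
    """Generate a covariate stack with known spatial and interannual variance."""
    if params.grid_extent < 3 * params.corr_length:
        raise ValueError("grid_extent must be >= 3 * corr_length "
                         "(random field degenerates)")
    rng = np.random.default_rng(seed)
    n = int(round(params.grid_extent / params.cell_size))
    grid = GridSpec(x0=0.0, y0=0.0, cell_size=params.cell_size,
                    n_cols=n, n_rows=n)
    sigma_cells = params.corr_length / params.cell_size
    sigma_ref = REFERENCE_CORR_LENGTH / params.cell_size
    layers: dict[str, np.ndarray] = {}
    for name in params.covariate_names:
        mean, sd_ref, lo, hi = COVARIATE_FIELDS.get(
            name, (0.0, 1.0, -np.inf, np.inf))
        amplitude = sd_ref * 2.0 * sigma_ref * np.sqrt(np.pi)
        base = mean + _smooth_field(rng, (n, n), sigma_cells, amplitude)
        if name in STATIC_COVARIATES:
            layers[name] = np.clip(base, lo, hi)
        else:
            sd_y = float(params.yty_sd.get(name, 0.0))
            year_effects = rng.normal(0.0, sd_y, size=params.n_years) \
                if sd_y > 0 else np.zeros(params.n_years)
            layers[name] = np.clip(
                base[None, :, :] + year_effects[:, None, None], lo, hi)
    return CovariateStack(grid=grid, layers=layers, years=params.years)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def simulate_population(n_per_strategy: int,
                        strategy_params: Mapping[str, StrategyParams] | None = None,
                        landscape_params: LandscapeParams | None = None,
                        seed: int = 0,
                        ) -> tuple[dict[str, pd.DataFrame], CovariateStack, pd.DataFrame]:
    """Labelled cohort of 3 * n_per_strategy animals placed on one landscape.

    Returns (trajectories keyed by animal_id, covariate stack, truth table).
    """
    if n_per_strategy < 1:
        raise ValueError("n_per_strategy must be >= 1")
    if strategy_params is None:
        strategy_params = {s: default_strategy_params(s) for s in STRATEGIES}
    if landscape_params is None:
        landscape_params = LandscapeParams()

    ss = np.random.SeedSequence(seed)
    land_seed, place_seed, *animal_seeds = ss.generate_state(
        2 + 3 * n_per_strategy) >> 1  # keep below 2**31
    stack = simulate_landscape(landscape_params, int(land_seed))
    place_rng = np.random.default_rng(int(place_seed))

    # summer centres in the inner box so 30 km winter excursions stay on-grid
    ext = landscape_params.grid_extent
    lo, hi = 0.27 * ext, 0.73 * ext

    trajectories: dict[str, pd.DataFrame] = {}
    rows = []
    idx = 0
    for strategy in STRATEGIES:
        base = strategy_params[strategy]
        for _ in range(n_per_strategy):
            animal_id = f"A{idx:03d}"
            centre = tuple(place_rng.uniform(lo, hi, size=2))
            p = replace(base, summer_centre=centre)
            aseed = int(animal_seeds[idx])
            trajectories[animal_id] = simulate_trajectory(p, aseed)
            rows.append({
                "animal_id": animal_id,
                "strategy": strategy,
                "summer_x": centre[0],
                "summer_y": centre[1],
                "winter_centre_distance": p.winter_centre_distance,
                "attraction": p.attraction,
                "step_sd": p.step_sd,
                "fix_interval": p.fix_interval,
                "n_months": p.n_months,
                "seed": aseed,
            })
            idx += 1
    truth = pd.DataFrame(rows)
    return trajectories, stack, truth
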