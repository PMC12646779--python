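"""End-to-end orchestration: simulate -> metrics -> classify -> variation ->
model selection, from a single flat key=value configuration.

Every stage is a pure function of (inputs, config, seed): stages communicate
through delimited-text tables and ASCII-grid rasters in the run directory, a
``manifest.json`` records versions, the seed and a config hash, and reruns
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .betareg import BetaRegression  # noqa: F401  (re-export convenience)
from .classify import kmeans_strategies
from .models import coefficient_table, run_model_sets, selection_table
from .occurrence import BBMMParams, estimate_bbmm, estimate_kud, \
    fit_bbmm_variance, make_grid, reference_bandwidth
from .overlap import IncompleteMetricsError, movement_metrics
from .rasters import read_stack, write_stack
from .simulate import LandscapeParams, simulate_population
from .trajio import Trajectory, UnclassifiableError, read_trajectories, \
    split_windows, write_trajectories
from .variation import standardized_domain, variation_table, year_round_range

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Flat run configuration; every key can appear in the config file."""

    seed: int = 0
    n_per_strategy: int = 10
    cell_size: float = 150.0
    min_fixes: int = 30
    isopleth_level: float = 0.95
    loc_error_sd: float = 20.0
    max_lag: float = 8.0
    n_alpha: int = 10
    bbmm_max_fix_interval: float = 4.0   # h; longer gaps switch the window to KUD
    kmeans_n_init: int = 50
    domain_area_km2: float = 1500.0
    min_subset_n: int = 10
    landscape_extent: float = 150_000.0
    landscape_corr_length: float = 1500.0
    landscape_n_years: int = 3

    def validate(self) -> None:
        if not 0 < self.isopleth_level <= 1:
            raise ValueError(
                f"isopleth_level must be in (0, 1], got {self.isopleth_level}")
        if self.n_per_strategy < 1:
            raise ValueError("n_per_strategy must be >= 1")
        if self.domain_area_km2 <= 0:
            raise ValueError("domain_area_km2 must be > 0")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")


def load_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` text file (# comments allowed)."""
    values = {}
    fields = PipelineConfig.__dataclass_fields__
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in fields:
            raise ValueError(f"unknown config key: {key}")
        typ = fields[key].type
        values[key] = int(val) if typ == "int" else float(val)
    cfg = PipelineConfig(**values)
    cfg.validate()
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# stages (file-mediated so CLI subcommands and run_pipeline agree exactly)
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, run_dir: Path) -> None:
    land = LandscapeParams(grid_extent=cfg.landscape_extent,
                           cell_size=cfg.cell_size,
                           corr_length=cfg.landscape_corr_length,
                           n_years=cfg.landscape_n_years)
    trajs, stack, truth = simulate_population(
        cfg.n_per_strategy, landscape_params=land, seed=cfg.seed)
    write_trajectories(trajs, run_dir / "trajectories.csv")
    write_stack(stack, run_dir / "rasters")
    _write_csv(truth, run_dir / "truth.csv")
    logger.info("simulate: %d animals on a %d-cell landscape",
                len(trajs), stack.grid.n_rows * stack.grid.n_cols)


def compute_metrics_one(traj: Trajectory, cfg: PipelineConfig) -> dict:
    """Windows -> ODs -> the four overlap metrics for one animal."""
    split = split_windows(traj, min_fixes=cfg.min_fixes)
    df = traj.fixes
    loc_sd = float(np.nan_to_num(df["loc_error_sd"].median(),
                                 nan=cfg.loc_error_sd))
    sigma2 = fit_bbmm_variance(df, loc_error_sd=loc_sd, max_lag=cfg.max_lag)
    params = BBMMParams(sigma2_m=sigma2, loc_error_sd=loc_sd,
                        max_lag=cfg.max_lag, n_alpha=cfg.n_alpha)
    h_full = reference_bandwidth(df["x"].to_numpy(), df["y"].to_numpy())
    grid = make_grid(df["x"].to_numpy(), df["y"].to_numpy(),
                     cell_size=cfg.cell_size,
                     margin=max(3 * h_full, 10 * cfg.cell_size))

    def od_for(sub: pd.DataFrame, window_id: str):
        gaps = np.diff(pd.DatetimeIndex(sub["timestamp"]).asi8) / 3.6e12
        if gaps.size and gaps.max() <= cfg.bbmm_max_fix_interval:
            return estimate_bbmm(sub, grid, params, window_id=window_id)
        return estimate_kud(sub, grid, window_id=window_id)

    seasonal = {k: od_for(v, k) for k, v in split.seasonal.items()}
    monthly = [od_for(sub, f"month_{i + 1:02d}") if sub is not None else None
               for i, sub in enumerate(split.monthly)]
    m = movement_metrics(seasonal, monthly, level=cfg.isopleth_level)
    return {"animal_id": traj.animal_id,
            "seasonal_overlap": m.seasonal_overlap,
            "summer_overlap": m.summer_overlap,
            "winter_overlap": m.winter_overlap,
            "annual_overlap": m.annual_overlap,
            "n_monthly_pairs": m.n_monthly_pairs,
            "sigma2_m": sigma2,
            "complete": True}


def stage_metrics(cfg: PipelineConfig, run_dir: Path) -> None:
    trajs = read_trajectories(run_dir / "trajectories.csv")
    rows = []
    for traj in trajs:
        try:
            rows.append(compute_metrics_one(traj, cfg))
            logger.info("metrics: %s done", traj.animal_id)
        except (UnclassifiableError, IncompleteMetricsError) as err:
            logger.warning("metrics: %s incomplete (%s)", traj.animal_id, err)
            rows.append({"animal_id": traj.animal_id, "complete": False})
    _write_csv(pd.DataFrame(rows), run_dir / "metrics.csv")


def stage_classify(cfg: PipelineConfig, run_dir: Path) -> None:
    metrics = pd.read_csv(run_dir / "metrics.csv")
    complete = metrics[metrics["complete"] == True]  # noqa: E712
    assignments = kmeans_strategies(complete, n_init=cfg.kmeans_n_init,
                                    seed=cfg.seed)
    _write_csv(assignments, run_dir / "assignments.csv")


def stage_variation(cfg: PipelineConfig, run_dir: Path) -> None:
    trajs = read_trajectories(run_dir / "trajectories.csv")
    stack = read_stack(run_dir / "rasters")
    emp_masks, std_masks = {}, {}
    for traj in trajs:
        emp_masks[traj.animal_id] = year_round_range(
            traj.fixes, stack.grid, level=cfg.isopleth_level)
        std_masks[traj.animal_id] = standardized_domain(
            traj.fixes, cfg.domain_area_km2, stack.grid)
    _write_csv(variation_table(stack, emp_masks, domain="empirical"),
               run_dir / "variation_empirical.csv")
    _write_csv(variation_table(stack, std_masks, domain="standardized"),
               run_dir / "variation_standardized.csv")


def stage_models(cfg: PipelineConfig, run_dir: Path) -> None:
    metrics = pd.read_csv(run_dir / "metrics.csv")
    assignments = pd.read_csv(run_dir / "assignments.csv")
    variation = pd.read_csv(run_dir / "variation_empirical.csv")
    for objective in (2, 3):
        res = run_model_sets(metrics, assignments, variation,
                             objective=objective, min_n=cfg.min_subset_n)
        _write_csv(selection_table(res),
                   run_dir / f"selection_obj{objective}.csv")
        _write_csv(coefficient_table(res),
                   run_dir / f"coefficients_obj{objective}.csv")


STAGES = {
    "simulate": stage_simulate,
    "metrics": stage_metrics,
    "classify": stage_classify,
    "variation": stage_variation,
    "models": stage_models,
}


def run_pipeline(cfg: PipelineConfig, run_dir) -> Path:
    """Run every stage into ``run_dir``; returns the run directory.

    Fails fast with :class:`PipelineStageError` naming the failing stage;
    outputs of completed stages are retained.
    """
    cfg.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES.items():
        logger.info("running stage %s", name)
        try:
            fn(cfg, run_dir)
        except Exception as err:
            raise PipelineStageError(name, err) from err
    manifest = {
        "package": "movestrat",
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": config_hash(cfg),
        "versions": _dependency_versions(),
        "outputs": sorted(p.name for p in run_dir.iterdir()
                          if p.suffix == ".csv"),
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return run_dir


def _dependency_versions() -> dict[str, str]:
    import scipy
    import sklearn
    import statsmodels
    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__, "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__}
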