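"""Reading, validating and windowing GPS relocation tables.

The delimited-text exchange format has columns ``animal_id``,
``timestamp`` (ISO-8601, UTC), ``x``, ``y`` and optional ``loc_error_sd``
(metres).  Seasons follow the northern-hemisphere ungulate convention:
summer is 1 June--31 August, winter is 1 December--28/29 February (winter of
year t spans Dec(t)--Feb(t+1)); monthly windows are calendar months indexed
sequentially from the first month of data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("animal_id", "timestamp", "x", "y")

SUMMER_MONTHS = (6, 7, 8)
WINTER_MONTHS = (12, 1, 2)


@dataclass
class Trajectory:
    """One animal's timestamped projected relocations."""

    animal_id: str
    fixes: pd.DataFrame  # columns timestamp (UTC), x, y, loc_error_sd

    def __post_init__(self) -> None:
        df = self.fixes
        for col in ("timestamp", "x", "y"):
            if col not in df.columns:
                raise ValueError(f"fixes missing column {col!r}")
        if "loc_error_sd" not in df.columns:
            self.fixes = df = df.assign(loc_error_sd=np.nan)
        ts = pd.DatetimeIndex(df["timestamp"])
        if ts.tz is None:
            raise ValueError("timestamps must be timezone-aware UTC")
        if len(df) and not (np.diff(ts.asi8) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if len(df) and not np.isfinite(df[["x", "y"]].to_numpy()).all():
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def span_months(self) -> int:
        """Number of calendar months touched by the record."""
        if len(self.fixes) == 0:
            return 0
        ts = pd.DatetimeIndex(self.fixes["timestamp"])
        first = ts[0].year * 12 + ts[0].month
        last = ts[-1].year * 12 + ts[-1].month
        return last - first + 1


@dataclass
class SeasonWindows:
    """Season boundary convention; months are calendar months, days inclusive."""

    summer_months: tuple[int, ...] = SUMMER_MONTHS
    winter_months: tuple[int, ...] = WINTER_MONTHS


class UnclassifiableError(ValueError):
    """Animal lacks the two usable summers and winters the metrics need."""


@dataclass
class WindowSplit:
    """Sub-trajectories per window for one animal."""

    seasonal: dict[str, pd.DataFrame]       # summer_1, summer_2, winter_1, winter_2
    monthly: list[pd.DataFrame | None]      # sequential calendar months; None = absent
    absent: list[str] = field(default_factory=list)

    @property
    def n_months(self) -> int:
        return len(self.monthly)


def read_trajectories(path, sep: str = ",", min_span_months: int = 21,
                      ) -> list[Trajectory]:
    """Read per-animal trajectories from a delimited-text file.

    Rows are sorted by time within animal; duplicated timestamps are collapsed
    to their first occurrence with a logged warning.  Animals whose records
    fail validation (non-finite coordinates, unparseable timestamps, span
    below ``min_span_months``) are rejected with a logged report rather than
    aborting the read.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")

    out: list[Trajectory] = []
    for animal_id, g in df.groupby("animal_id", sort=True):
        g = g.sort_values("timestamp").reset_index(drop=True)
        try:
            if g["timestamp"].isna().any():
                raise ValueError("unparseable timestamps")
            ndup = g["timestamp"].duplicated().sum()
            if ndup:
                logger.warning("%s: collapsing %d duplicated timestamps "
                               "to first occurrence", animal_id, ndup)
                g = g[~g["timestamp"].duplicated()].reset_index(drop=True)
            cols = ["timestamp", "x", "y"]
            if "loc_error_sd" in g.columns:
                cols.append("loc_error_sd")
            traj = Trajectory(animal_id=str(animal_id), fixes=g[cols])
            if traj.span_months < min_span_months:
                raise ValueError(
                    f"span {traj.span_months} months < {min_span_months}")
            out.append(traj)
        except ValueError as err:
            logger.warning("rejecting animal %s: %s", animal_id, err)
    return out


def write_trajectories(trajectories, path, sep: str = ",") -> None:
    """Write trajectories (Trajectory objects or {id: fixes} mapping) to text."""
    frames = []
    items = trajectories.items() if isinstance(trajectories, dict) else \
        ((t.animal_id, t.fixes) for t in trajectories)
    for animal_id, fixes in items:
        f = fixes.copy()
        f.insert(0, "animal_id", animal_id)
        frames.append(f)
    allf = pd.concat(frames, ignore_index=True)
    allf["timestamp"] = pd.DatetimeIndex(allf["timestamp"]).strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    allf.to_csv(path, sep=sep, index=False, float_format="%.6f")


def _season_of(month: np.ndarray) -> np.ndarray:
    """0 summer, 1 winter, -1 shoulder."""
    out = np.full(month.shape, -1)
    out[np.isin(month, SUMMER_MONTHS)] = 0
    out[np.isin(month, WINTER_MONTHS)] = 1
    return out


def split_windows(traj: Trajectory, windows: SeasonWindows | None = None,
                  min_fixes: int = 30, strict: bool = True) -> WindowSplit:
    """Partition a trajectory into 2 summers, 2 winters and monthly windows.

    Seasonal windows with fewer than ``min_fixes`` fixes are flagged absent;
    monthly windows below the threshold become ``None`` entries.  With
    ``strict`` (the default) an :class:`UnclassifiableError` is raised when
    fewer than two usable summers or winters remain -- the record cannot
    support between-year overlap metrics; ``strict=False`` returns the partial
    split with the gaps recorded in ``absent``.
    """
    del windows  # boundary convention is fixed; parameter kept for config surface
    df = traj.fixes
    if len(df) == 0:
        raise ValueError("empty trajectory")
    ts = pd.DatetimeIndex(df["timestamp"])
    month = ts.month.to_numpy()
    year = ts.year.to_numpy()

    # monthly windows, sequentially indexed from the first month of data
    seq = (year * 12 + month)
    first = seq.min()
    last = seq.max()
    monthly: list[pd.DataFrame | None] = []
    absent: list[str] = []
    for m in range(first, last + 1):
        sub = df[seq == m]
        if len(sub) >= min_fixes:
            monthly.append(sub.reset_index(drop=True))
        else:
            monthly.append(None)
            absent.append(f"month_{m - first + 1:02d}")

    # summers by calendar year, winters by Dec-year
    seasonal: dict[str, pd.DataFrame] = {}
    summers, winters = [], []
    summer_years = sorted(set(year[np.isin(month, SUMMER_MONTHS)]))
    for k, yr in enumerate(summer_years, start=1):
        sub = df[np.isin(month, SUMMER_MONTHS) & (year == yr)]
        if len(sub) >= min_fixes:
            summers.append(sub.reset_index(drop=True))
        else:
            absent.append(f"summer_{k}")
    winter_year = np.where(month <= 2, year - 1, year)
    winter_years = sorted(set(winter_year[np.isin(month, WINTER_MONTHS)]))
    for k, yr in enumerate(winter_years, start=1):
        sub = df[np.isin(month, WINTER_MONTHS) & (winter_year == yr)]
        if len(sub) >= min_fixes:
            winters.append(sub.reset_index(drop=True))
        else:
            absent.append(f"winter_{k}")

    if len(summers) < 2 or len(winters) < 2:
        if strict:
            raise UnclassifiableError(
                f"{traj.animal_id}: {len(summers)} usable summers and "
                f"{len(winters)} usable winters; need 2 of each")
    for k, sub in enumerate(summers[:2], start=1):
        seasonal[f"summer_{k}"] = sub
    for k, sub in enumerate(winters[:2], start=1):
        seasonal[f"winter_{k}"] = sub
    return WindowSplit(seasonal=seasonal, monthly=monthly, absent=absent)
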