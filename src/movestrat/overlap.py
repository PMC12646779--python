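"""Bhattacharyya affinity between occurrence distributions and the four
per-animal movement metrics.

The Bhattacharyya affinity between two discrete probability surfaces is
``BA = sum_i sqrt(p_i * q_i)`` -- 1 for identical distributions, 0 for
disjoint ones.  Before comparison each OD is restricted to its own 95%
volume isopleth and renormalized (the overlap index is conditioned on the
95% ODs); setting ``truncate=False`` computes the full-support coefficient
for sensitivity checks.

Per animal, four continuous metrics summarize strategy:

1. ``seasonal_overlap`` -- mean of within-year summer-vs-winter BA (year 1
   and year 2): near 1 for residents, near 0 for migrants.
2. ``summer_overlap`` -- BA between the two summer ranges.
3. ``winter_overlap`` -- BA between the two winter ranges; low values flag
   animals that switch winter ranges between years.
4. ``annual_overlap`` -- mean BA over all pairs of monthly ODs more than one
   month apart in the sequential record (adjacent months are excluded to
   limit temporal autocorrelation; a July OD is compared with every other
   month except June and August of the same sequence position).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .occurrence import GridSpec, OccurrenceDistribution, volume_isopleth

SEASONAL_KEYS = ("summer_1", "summer_2", "winter_1", "winter_2")


@dataclass
class MovementMetrics:
    """The four overlap statistics for one animal; all proportions in [0, 1]."""

    seasonal_overlap: float
    summer_overlap: float
    winter_overlap: float
    annual_overlap: float
    n_monthly_pairs: int

    def __post_init__(self) -> None:
        for name in ("seasonal_overlap", "summer_overlap", "winter_overlap"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1 + 1e-9):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_monthly_pairs < 1 and np.isfinite(self.annual_overlap):
            raise ValueError("annual_overlap defined but no monthly pairs")


class IncompleteMetricsError(ValueError):
    """A required seasonal OD is absent; the animal cannot be scored."""


def _restricted(od: OccurrenceDistribution, level: float,
                truncate: bool) -> np.ndarray:
    mass = od.mass
    if truncate and level < 1.0:
        mask = volume_isopleth(od, level)
        mass = np.where(mask, mass, 0.0)
        mass = mass / mass.sum()
    return mass


def _union_grid(gp: GridSpec, gq: GridSpec) -> GridSpec:
    cell = gp.cell_size
    x0 = min(gp.x0, gq.x0)
    y0 = min(gp.y0, gq.y0)
    x1 = max(gp.x_max, gq.x_max)
    y1 = max(gp.y_max, gq.y_max)
    return GridSpec(x0=x0, y0=y0, cell_size=cell,
                    n_cols=int(round((x1 - x0) / cell)),
                    n_rows=int(round((y1 - y0) / cell)))


def _place(mass: np.ndarray, src: GridSpec, dst: GridSpec) -> np.ndarray:
    """Re-bin a mass surface onto a covering grid with the same cell size.

    Lattice-aligned grids shift by whole cells; a fractional offset is handled
    by mass-conserving area-weighted splitting of each source cell across the
    (up to four) destination cells it overlaps.
    """
    out = np.zeros((dst.n_rows, dst.n_cols))
    fx = (src.x0 - dst.x0) / dst.cell_size
    fy = (src.y0 - dst.y0) / dst.cell_size
    ox, oy = round(fx), round(fy)
    if abs(fx - ox) < 1e-9 and abs(fy - oy) < 1e-9:
        out[oy:oy + src.n_rows, ox:ox + src.n_cols] = mass
        return out
    jx, rx = int(np.floor(fx)), fx - np.floor(fx)
    jy, ry = int(np.floor(fy)), fy - np.floor(fy)
    for dy, wy in ((0, 1 - ry), (1, ry)):
        for dx, wx in ((0, 1 - rx), (1, rx)):
            w = wx * wy
            if w == 0:
                continue
            r0, c0 = jy + dy, jx + dx
            out[r0:r0 + src.n_rows, c0:c0 + src.n_cols] += w * mass
    return out


def bhattacharyya_affinity(od_p: OccurrenceDistribution,
                           od_q: OccurrenceDistribution,
                           level: float = 0.95,
                           truncate: bool = True) -> float:
    """Isopleth-restricted Bhattacharyya affinity between two ODs.

    Each OD is truncated to its own ``level`` volume isopleth and
    renormalized before the coefficient is computed on the union grid.
    """
    if not np.isclose(od_p.grid.cell_size, od_q.grid.cell_size):
        raise ValueError("incompatible cell sizes")
    p = _restricted(od_p, level, truncate)
    q = _restricted(od_q, level, truncate)
    if od_p.grid == od_q.grid:
        return float(np.sqrt(p * q).sum())
    union = _union_grid(od_p.grid, od_q.grid)
    pu = _place(p, od_p.grid, union)
    qu = _place(q, od_q.grid, union)
    return float(np.sqrt(pu * qu).sum())


def monthly_pair_indices(present: Sequence[bool]) -> list[tuple[int, int]]:
    """Index pairs (i, j), i < j, with j - i >= 2 and both months present."""
    idx = [i for i, ok in enumerate(present) if ok]
    return [(i, j) for i, j in combinations(idx, 2) if j - i >= 2]


def movement_metrics(seasonal: Mapping[str, OccurrenceDistribution],
                     monthly: Sequence[OccurrenceDistribution | None],
                     level: float = 0.95,
                     truncate: bool = True) -> MovementMetrics:
    """Distill one animal's ODs into the four movement metrics."""
    missing = [k for k in SEASONAL_KEYS if k not in seasonal]
    if missing:
        raise IncompleteMetricsError(f"missing seasonal ODs: {missing}")

    # the isopleth restriction is the costly step; compute it once per OD
    cache: dict[int, np.ndarray] = {}

    def restricted(od: OccurrenceDistribution) -> np.ndarray:
        key = id(od)
        if key not in cache:
            cache[key] = _restricted(od, level, truncate)
        return cache[key]

    def ba(od_a: OccurrenceDistribution, od_b: OccurrenceDistribution) -> float:
        if not np.isclose(od_a.grid.cell_size, od_b.grid.cell_size):
            raise ValueError("incompatible cell sizes")
        p, q = restricted(od_a), restricted(od_b)
        if od_a.grid == od_b.grid:
            return float(np.sqrt(p * q).sum())
        union = _union_grid(od_a.grid, od_b.grid)
        return float(np.sqrt(_place(p, od_a.grid, union)
                             * _place(q, od_b.grid, union)).sum())

    s1, s2 = seasonal["summer_1"], seasonal["summer_2"]
    w1, w2 = seasonal["winter_1"], seasonal["winter_2"]
    metric1 = 0.5 * (ba(s1, w1) + ba(s2, w2))
    metric2 = ba(s1, s2)
    metric3 = ba(w1, w2)

    pairs = monthly_pair_indices([od is not None for od in monthly])
    if pairs:
        vals = [ba(monthly[i], monthly[j]) for i, j in pairs]
        metric4 = float(np.mean(vals))
    else:
        metric4 = float("nan")
    return MovementMetrics(seasonal_overlap=metric1,
                           summer_overlap=metric2,
                           winter_overlap=metric3,
                           annual_overlap=metric4,
                           n_monthly_pairs=len(pairs))
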