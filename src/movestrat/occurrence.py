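"""Occurrence distributions on a regular grid.

An occurrence distribution (OD) is a per-cell probability mass surface for an
animal's position over a time window.  Two estimators are provided:

* :func:`estimate_bbmm` -- Brownian bridge movement model: the path between
  consecutive fixes is a Brownian bridge with diffusion ``sigma2_m`` (m^2/h)
  and GPS error SD ``delta``; at fraction ``alpha`` of a segment of duration
  ``T`` the position is Gaussian around the linear interpolation of the
  endpoints with variance ``alpha*(1-alpha)*T*sigma2_m +
  (1-alpha)^2*delta^2 + alpha^2*delta^2`` per axis.  The OD is the
  duration-weighted mixture of these Gaussians, discretized with ``n_alpha``
  midpoint steps per segment and integrated over cells by the cell-centre
  approximation, then normalized.
* :func:`estimate_kud` -- isotropic Gaussian kernel density with the
  reference bandwidth ``h = sigma_hat * n**(-1/6)``,
  ``sigma_hat = sqrt((var_x + var_y) / 2)``.

``sigma2_m`` is fitted by the standard leave-one-out likelihood: odd-indexed
fixes are predicted from the bridge between their even-indexed neighbours
(:func:`fit_bbmm_variance`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import minimize_scalar

_MAX_STAMP_ELEMS = 4e7  # chunking threshold for vectorized Gaussian stamping


@dataclass(frozen=True)
class GridSpec:
    """Regular grid of square cells; masses are arrays of shape (n_rows, n_cols).

    Row ``i`` spans y in [y0 + i*cell, y0 + (i+1)*cell); cell centres sit at
    the half-cell offsets.  Grids built by :func:`make_grid` share a global
    lattice anchored at the origin, so two grids with equal cell size align
    exactly (integral index offsets) and can be re-binned without resampling.
    """

    x0: float
    y0: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def x_max(self) -> float:
        return self.x0 + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y0 + self.n_rows * self.cell_size

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    def x_centres(self) -> np.ndarray:
        return self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centres(self) -> np.ndarray:
        return self.y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def col_of(self, x: np.ndarray) -> np.ndarray:
        return np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)

    def row_of(self, y: np.ndarray) -> np.ndarray:
        return np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return ((x >= self.x0) & (x < self.x_max)
                & (y >= self.y0) & (y < self.y_max))


def make_grid(x: np.ndarray, y: np.ndarray, cell_size: float = 150.0,
              margin: float | None = None, bandwidth: float | None = None,
              ) -> GridSpec:
    """Grid covering the points plus a margin, aligned to the global lattice.

    ``margin`` defaults to 3 bandwidths when ``bandwidth`` is given, else to
    10 cells.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0:
        raise ValueError("no points")
    if margin is None:
        margin = 3.0 * bandwidth if bandwidth else 10.0 * cell_size
    x0 = np.floor((x.min() - margin) / cell_size) * cell_size
    y0 = np.floor((y.min() - margin) / cell_size) * cell_size
    n_cols = int(np.ceil((x.max() + margin - x0) / cell_size))
    n_rows = int(np.ceil((y.max() + margin - y0) / cell_size))
    return GridSpec(x0=x0, y0=y0, cell_size=cell_size,
                    n_cols=n_cols, n_rows=n_rows)


@dataclass
class OccurrenceDistribution:
    """Probability masses on a grid for one time window."""

    grid: GridSpec
    mass: np.ndarray
    window_id: str = ""

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, float)
        if self.mass.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("mass shape does not match grid")
        if np.any(self.mass < -1e-12):
            raise ValueError("negative mass")
        total = self.mass.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"masses must sum to 1, got {total}")


@dataclass
class BBMMParams:
    sigma2_m: float = 1000.0     # m^2 / h
    loc_error_sd: float = 20.0   # m
    max_lag: float = 8.0         # h
    n_alpha: int = 10

    def __post_init__(self) -> None:
        if self.sigma2_m < 0:
            raise ValueError("sigma2_m must be >= 0")
        if self.n_alpha < 5:
            raise ValueError("n_alpha must be >= 5")


def _segments(df: pd.DataFrame, max_lag: float):
    """Consecutive-fix segments with gaps <= max_lag hours."""
    t = pd.DatetimeIndex(df["timestamp"])
    dt_h = np.diff(t.view("int64")) / 3.6e12
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    keep = dt_h <= max_lag
    return x, y, dt_h, keep


def fit_bbmm_variance(df: pd.DataFrame, loc_error_sd: float = 20.0,
                      max_lag: float = 8.0) -> float:
    """Leave-one-out ML estimate of the Brownian motion variance (m^2/h).

    Each odd-indexed fix is scored under the Brownian bridge between its
    even-indexed neighbours; the predictive variance carries the bridge term
    plus observation variance ``loc_error_sd**2`` at both endpoints and at
    the scored fix itself.  The likelihood is
    maximized over ``log10(sigma2_m)`` bracketed on [-3, 8] (xatol 1e-6 in
    log10 units); a zero estimate is returned when it scores at least as well.
    """
    n = len(df)
    if n < 3:
        raise ValueError("need at least 3 fixes to estimate sigma2_m")
    t = pd.DatetimeIndex(df["timestamp"]).view("int64") / 3.6e12  # hours
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    i = np.arange(1, n - 1, 2)
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    T = t2 - t0
    usable = T <= max_lag
    if not usable.any():
        raise ValueError("no usable bridges: all triplet spans exceed max_lag")
    i = i[usable]
    t0, t1, T = t0[usable], t1[usable], T[usable]
    alpha = (t1 - t0) / T
    mx = x[i - 1] + alpha * (x[i + 1] - x[i - 1])
    my = y[i - 1] + alpha * (y[i + 1] - y[i - 1])
    d2 = (x[i] - mx) ** 2 + (y[i] - my) ** 2
    delta2 = loc_error_sd ** 2

    err_factor = 1.0 + (1 - alpha) ** 2 + alpha ** 2  # scored fix + endpoints

    def nll(log10_s2: float) -> float:
        s2 = 10.0 ** log10_s2
        v = alpha * (1 - alpha) * T * s2 + err_factor * delta2
        v = np.maximum(v, 1e-12)
        return float(np.sum(np.log(2 * np.pi * v) + d2 / (2 * v)))

    res = minimize_scalar(nll, bounds=(-3.0, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    # the zero-diffusion limit (pure measurement error)
    v0 = err_factor * delta2
    nll0 = float(np.sum(np.log(2 * np.pi * v0) + d2 / (2 * v0))) \
        if delta2 > 0 else np.inf
    if nll0 <= res.fun:
        return 0.0
    return float(10.0 ** res.x)


def _stamp_gaussians(grid: GridSpec, mx: np.ndarray, my: np.ndarray,
                     sd: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Accumulate isotropic Gaussian densities at cell centres (times area).

    Returns an unnormalized mass array.  Each Gaussian is evaluated on a
    +-5 SD window around its mean; windows are clipped at the grid edge.
    """
    nr, nc = grid.n_rows, grid.n_cols
    cell = grid.cell_size
    # floor keeps degenerate (zero-spread) kernels representable: mass then
    # collapses onto the nearest cell centre instead of underflowing to zero
    sd = np.maximum(np.asarray(sd, float), cell / 20.0)
    mx = np.asarray(mx, float)
    my = np.asarray(my, float)
    weight = np.broadcast_to(np.asarray(weight, float), mx.shape)

    hw = int(np.ceil(5.0 * sd.max() / cell))
    hw = max(1, min(hw, max(nr, nc)))
    win = 2 * hw + 1
    offs = np.arange(-hw, hw + 1)
    flat = np.zeros(nr * nc)

    chunk = max(1, int(_MAX_STAMP_ELEMS / (win * win)))
    for s in range(0, mx.size, chunk):
        e = min(s + chunk, mx.size)
        cmx, cmy, csd, cw = mx[s:e], my[s:e], sd[s:e], weight[s:e]
        ic = grid.col_of(cmx)
        ir = grid.row_of(cmy)
        cols = ic[:, None] + offs            # (N, win)
        rows = ir[:, None] + offs
        xs = grid.x0 + (cols + 0.5) * cell
        ys = grid.y0 + (rows + 0.5) * cell
        inv2 = 1.0 / (2.0 * csd ** 2)
        wx = np.exp(-((xs - cmx[:, None]) ** 2) * inv2[:, None])
        wy = np.exp(-((ys - cmy[:, None]) ** 2) * inv2[:, None])
        okc = (cols >= 0) & (cols < nc)
        okr = (rows >= 0) & (rows < nr)
        wx = np.where(okc, wx, 0.0)
        wy = np.where(okr, wy, 0.0)
        amp = cw / (2.0 * np.pi * csd ** 2)
        vals = amp[:, None, None] * wy[:, :, None] * wx[:, None, :]
        idx = (np.clip(rows, 0, nr - 1)[:, :, None] * nc
               + np.clip(cols, 0, nc - 1)[:, None, :])
        np.add.at(flat, idx.ravel(), vals.ravel())
    return flat.reshape(nr, nc) * grid.cell_area


def estimate_bbmm(df: pd.DataFrame, grid: GridSpec,
                  params: BBMMParams | None = None,
                  window_id: str = "") -> OccurrenceDistribution:
    """Brownian bridge OD for one window's fixes on the given grid."""
    params = params or BBMMParams()
    if len(df) < 2:
        raise ValueError("need at least 2 fixes")
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    if not grid.contains(x, y).all():
        raise ValueError("grid does not cover all fixes")
    _, _, dt_h, keep = _segments(df, params.max_lag)
    if not keep.any():
        raise ValueError("no segment within max_lag of a neighbour")

    idx = np.flatnonzero(keep)
    T = dt_h[idx]                                   # (S,)
    x0, x1 = x[idx], x[idx + 1]
    y0, y1 = y[idx], y[idx + 1]
    na = params.n_alpha
    alpha = (np.arange(na) + 0.5) / na              # midpoint rule
    mx = (x0[:, None] + alpha * (x1 - x0)[:, None]).ravel()
    my = (y0[:, None] + alpha * (y1 - y0)[:, None]).ravel()
    var = (alpha * (1 - alpha))[None, :] * T[:, None] * params.sigma2_m \
        + ((1 - alpha) ** 2 + alpha ** 2)[None, :] * params.loc_error_sd ** 2
    sd = np.sqrt(var).ravel()
    w = np.repeat(T / na, na)                       # duration weighting
    mass = _stamp_gaussians(grid, mx, my, sd, w)
    total = mass.sum()
    if total <= 0:
        raise ValueError("all probability mass fell outside the grid")
    return OccurrenceDistribution(grid=grid, mass=mass / total,
                                  window_id=window_id)


def reference_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """h = sigma_hat * n**(-1/6) with sigma_hat = sqrt((var_x + var_y)/2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sigma = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
    return float(sigma * n ** (-1.0 / 6.0))


def estimate_kud(points: pd.DataFrame, grid: GridSpec,
                 bandwidth: float | None = None, min_fixes: int = 2,
                 window_id: str = "") -> OccurrenceDistribution:
    """Kernel utilization distribution on the grid.

    With a bandwidth of many cells the kernel sum is computed by binning the
    points and convolving with a Gaussian (numerically indistinguishable at
    that scale and far cheaper); otherwise each kernel is evaluated exactly.
    """
    x = points["x"].to_numpy(float)
    y = points["y"].to_numpy(float)
    if x.size < min_fixes:
        raise ValueError(f"need at least {min_fixes} points")
    if not grid.contains(x, y).all():
        raise ValueError("grid does not cover all points")
    if bandwidth is None:
        if x.size < 2 or (x.var() == 0 and y.var() == 0):
            raise ValueError("zero-variance point set requires an explicit "
                             "bandwidth")
        bandwidth = reference_bandwidth(x, y)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")

    hw = 5.0 * bandwidth / grid.cell_size
    if hw > 8.0:
        counts = np.zeros((grid.n_rows, grid.n_cols))
        np.add.at(counts, (grid.row_of(y), grid.col_of(x)), 1.0)
        mass = gaussian_filter(counts, sigma=bandwidth / grid.cell_size,
                               mode="constant", truncate=5.0)
    else:
        sd = np.full(x.size, bandwidth)
        mass = _stamp_gaussians(grid, x, y, sd, np.ones(x.size))
    total = mass.sum()
    if total <= 0:
        raise ValueError("all probability mass fell outside the grid")
    return OccurrenceDistribution(grid=grid, mass=mass / total,
                                  window_id=window_id)


def volume_isopleth(od: OccurrenceDistribution, level: float = 0.95) -> np.ndarray:
    """Smallest cell set (by descending mass) with cumulative mass >= level.

    Ties are broken by row-major cell index (stable sort), so the mask is
    deterministic.  Returns a boolean array of the grid shape.
    """
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    flat = od.mass.ravel()
    if level == 1.0:
        return (od.mass > 0)
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level - 1e-12)) + 1
    k = min(k, flat.size)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(od.mass.shape)
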