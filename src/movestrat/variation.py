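"""Per-animal summaries of the resource environment.

For each animal, variation in resources is measured either over the empirical
year-round range (95% kernel utilization distribution of the full 21--23
month record) or over a standardized circular availability domain around the
winter centroid (decoupling the environment from realized space use):

* spatial variation -- SD of each covariate across the masked cells (annual
  covariates are first averaged across years cell-wise; population SD,
  denominator n, since the masked cells are a census of the range), then
  aggregated across covariates into a single PC1 score;
* year-to-year variation -- SD across years of a covariate's annual spatial
  mean within the mask (sample SD, denominator n-1: years are a sample);
* climatic conditions -- mean snow depth over masked cells and years
  (``winter_conditions``) and its cohort z-score (``winter_severity``);
* anthropogenic indices -- masked means of percent agriculture and distance
  to roads.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .occurrence import GridSpec, estimate_kud, volume_isopleth
from .simulate import CovariateStack

logger = logging.getLogger(__name__)

YTY_COVARIATES = ("spring_length", "biomass")


def year_round_range(fixes: pd.DataFrame, grid: GridSpec,
                     level: float = 0.95,
                     bandwidth: float | None = None) -> np.ndarray:
    """95% KUD volume isopleth of all fixes, as a boolean mask on ``grid``.

    Fixes outside the grid are dropped with a warning (the covariate stack may
    not extend under every excursion).
    """
    inside = grid.contains(fixes["x"].to_numpy(), fixes["y"].to_numpy())
    if not inside.all():
        logger.warning("dropping %d fixes outside the covariate grid",
                       int((~inside).sum()))
        fixes = fixes[inside]
    od = estimate_kud(fixes, grid, bandwidth=bandwidth)
    return volume_isopleth(od, level)


def spatial_variation(stack: CovariateStack, mask: np.ndarray) -> pd.Series:
    """Per-covariate SD over masked cells of the across-year mean layer."""
    mask = np.asarray(mask, bool)
    if mask.sum() < 2:
        raise ValueError("mask must cover at least 2 cells for an SD")
    out = {}
    for name in stack.covariates:
        vals = stack.mean_over_years(name)[mask]
        out[name] = float(vals.std(ddof=0))
    return pd.Series(out, name="spatial_sd")


class SpatialVariationPCA(TransformerMixin, BaseEstimator):
    """PC1 aggregation of the animals x covariates spatial-SD matrix.

    Columns are centred and scaled to unit variance; zero-variance columns
    are dropped with a warning.  The component sign is oriented so the
    covariate with the largest-magnitude loading has a positive loading,
    making higher scores mean more spatial heterogeneity.

    Attributes: ``loadings_`` (Series per kept covariate),
    ``explained_variance_ratio_``, ``columns_``.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("need >= 2 animals and >= 2 covariates")
        if not np.isfinite(X.to_numpy(float)).all():
            raise ValueError("SD matrix must be finite")
        std = X.std(ddof=0)
        dead = std[std == 0].index.tolist()
        if dead:
            logger.warning("dropping zero-variance covariates: %s", dead)
            X = X.drop(columns=dead)
            std = std.drop(dead)
        self.columns_ = list(X.columns)
        self.mean_ = X.mean()
        self.scale_ = std
        Z = (X - self.mean_) / self.scale_
        pca = PCA(n_components=1)
        pca.fit(Z.to_numpy(float))
        load = pca.components_[0]
        if load[np.argmax(np.abs(load))] < 0:
            load = -load
        self.loadings_ = pd.Series(load, index=self.columns_)
        self.explained_variance_ratio_ = float(pca.explained_variance_ratio_[0])
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = pd.DataFrame(X)[self.columns_]
        Z = (X - self.mean_) / self.scale_
        return Z.to_numpy(float) @ self.loadings_.to_numpy()


def pca_spatial_score(sd_matrix: pd.DataFrame) -> pd.Series:
    """PC1 score per animal from the spatial-SD matrix (fit + transform)."""
    est = SpatialVariationPCA().fit(sd_matrix)
    return pd.Series(est.transform(sd_matrix),
                     index=pd.DataFrame(sd_matrix).index,
                     name="spatial_variation_score")


def yty_variation(stack: CovariateStack, mask: np.ndarray,
                  covariates: Sequence[str] = YTY_COVARIATES) -> pd.Series:
    """SD across years of each covariate's annual spatial mean within the mask."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    out = {}
    for name in covariates:
        arr = stack.layers[name]
        if arr.ndim != 3 or arr.shape[0] < 2:
            raise ValueError(f"{name}: need >= 2 annual layers")
        annual_means = arr[:, mask].mean(axis=1)
        out[f"yty_{name}_sd"] = float(annual_means.std(ddof=1))
    return pd.Series(out, name="yty_sd")


def winter_centroid(fixes: pd.DataFrame) -> tuple[float, float]:
    month = pd.DatetimeIndex(fixes["timestamp"]).month
    winter = fixes[np.isin(month, (12, 1, 2))]
    if len(winter) == 0:
        raise ValueError("no winter fixes (1 Dec - 28/29 Feb)")
    return float(winter["x"].mean()), float(winter["y"].mean())


def standardized_domain(fixes: pd.DataFrame, domain_area_km2: float,
                        grid: GridSpec) -> np.ndarray:
    """Circular availability domain around the winter centroid, as a cell mask.

    The circle has the species-standard area (radius ``sqrt(area / pi)``) and
    is rasterized by cell-centre inclusion on the covariate grid.
    """
    if domain_area_km2 <= 0:
        raise ValueError("domain_area_km2 must be > 0")
    cx, cy = winter_centroid(fixes)
    radius = float(np.sqrt(domain_area_km2 * 1e6 / np.pi))
    xs = grid.x_centres()[None, :]
    ys = grid.y_centres()[:, None]
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= radius ** 2


def climate_anthro_indices(stack: CovariateStack,
                           masks: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Snow and anthropogenic indices per animal, with cohort-level severity.

    ``winter_conditions`` is the mean snow depth over the animal's masked
    cells across available years.  ``winter_severity`` is a relative index of
    the worst winter the animal experienced: the cohort z-score (computed
    within species, i.e. within whatever cohort the masks represent) of the
    maximum annual masked-mean snow depth.  Using the worst year rather than
    the mean keeps severity from being an affine copy of the overall
    conditions, so the two can enter one model together.  Raises if the
    stack lacks a snow layer.
    """
    if "snow_depth" not in stack.layers:
        raise ValueError("snow layers absent; climatic indices unavailable")
    rows = {}
    for animal_id, mask in masks.items():
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError(f"{animal_id}: empty mask")
        annual_snow = stack.annual("snow_depth")[:, mask].mean(axis=1)
        row = {"winter_conditions": float(annual_snow.mean()),
               "worst_winter_snow": float(annual_snow.max())}
        if "pct_agriculture" in stack.layers:
            row["pct_agriculture"] = float(
                stack.mean_over_years("pct_agriculture")[mask].mean())
        if "dist_roads" in stack.layers:
            row["dist_roads"] = float(
                stack.mean_over_years("dist_roads")[mask].mean())
        rows[animal_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "animal_id"
    worst = df.pop("worst_winter_snow")
    sd = worst.std(ddof=0)
    df["winter_severity"] = 0.0 if sd == 0 else (worst - worst.mean()) / sd
    return df


def variation_table(stack: CovariateStack,
                    masks: Mapping[str, np.ndarray],
                    domain: str = "empirical") -> pd.DataFrame:
    """Full per-animal variation summary for one availability-domain type.

    Combines per-covariate spatial SDs, the PC1 spatial-variation score,
    year-to-year SDs and the climatic/anthropogenic indices into one table
    (all indices share the mask, so the two domain types differ only through
    it).
    """
    spat = {aid: spatial_variation(stack, m) for aid, m in masks.items()}
    sd_matrix = pd.DataFrame.from_dict(spat, orient="index")
    scores = pca_spatial_score(sd_matrix)
    yty = pd.DataFrame.from_dict(
        {aid: yty_variation(stack, m) for aid, m in masks.items()},
        orient="index")
    clim = climate_anthro_indices(stack, masks)
    out = pd.concat(
        [sd_matrix.add_prefix("spatial_sd_"), scores.rename(
            "spatial_variation_score"), yty, clim], axis=1)
    out.insert(0, "domain", domain)
    out.index.name = "animal_id"
    return out.reset_index()
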