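"""Candidate beta-regression sets and AICc model selection.

Four data subsets are analysed, each with the response metric that separates
the strategies being compared:

=================  ==========================================  ================
subset             animals                                     response metric
=================  ==========================================  ================
all                everyone                                    seasonal_overlap
dual_vs_multi      dual- and multi-range migrants              winter_overlap
resident_vs_dual   residents and dual-range migrants           seasonal_overlap
resident_vs_multi  residents and multi-range migrants          annual_overlap
=================  ==========================================  ================

Objective-2 candidates per subset: (i) spatial variation (PC1 score), (ii)
year-to-year variation (spring-length SD + biomass SD), (iii) intercept only.
Spatial and year-to-year variation never co-occur in one candidate (they are
strongly correlated in the field data this design mirrors).

Objective-3 candidates (seven per subset): the objective-2 top model, an
intercept-only model, climatic conditions (winter conditions + relative
winter severity), anthropogenic features (percent agriculture + distance to
roads), and the top-model covariates combined with climate, with
anthropogenic features, and with both.

Predictors are centred and scaled within each subset before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .betareg import BetaRegression

SUBSETS = ("all", "dual_vs_multi", "resident_vs_dual", "resident_vs_multi")

RESPONSE_BY_SUBSET = {
    "all": "seasonal_overlap",
    "dual_vs_multi": "winter_overlap",
    "resident_vs_dual": "seasonal_overlap",
    "resident_vs_multi": "annual_overlap",
}

STRATEGIES_BY_SUBSET = {
    "all": ("resident", "dual_range_migrant", "multi_range_migrant"),
    "dual_vs_multi": ("dual_range_migrant", "multi_range_migrant"),
    "resident_vs_dual": ("resident", "dual_range_migrant"),
    "resident_vs_multi": ("resident", "multi_range_migrant"),
}

SPATIAL_TERMS = ("spatial_variation_score",)
YTY_TERMS = ("yty_spring_length_sd", "yty_biomass_sd")
CLIMATE_TERMS = ("winter_conditions", "winter_severity")
ANTHRO_TERMS = ("pct_agriculture", "dist_roads")

OBJECTIVE2_CANDIDATES: dict[str, tuple[str, ...]] = {
    "spatial": SPATIAL_TERMS,
    "yty": YTY_TERMS,
    "intercept": (),
}


@dataclass
class SubsetResult:
    """Selection and coefficient tables for one subset."""

    subset: str
    response: str
    selection: pd.DataFrame
    coefficients: pd.DataFrame
    top_model: str
    fits: dict[str, BetaRegression] = field(default_factory=dict)


def objective3_candidates(top_terms: tuple[str, ...]
                          ) -> dict[str, tuple[str, ...]]:
    """The seven objective-3 candidates given the objective-2 top model."""
    cands = {
        "top_obj2": tuple(top_terms),
        "intercept": (),
        "climate": CLIMATE_TERMS,
        "anthro": ANTHRO_TERMS,
        "top_obj2+climate": tuple(top_terms) + CLIMATE_TERMS,
        "top_obj2+anthro": tuple(top_terms) + ANTHRO_TERMS,
        "top_obj2+climate+anthro": tuple(top_terms) + CLIMATE_TERMS + ANTHRO_TERMS,
    }
    # de-duplicate term tuples (arises when the obj-2 top model is the null)
    seen: dict[tuple[str, ...], str] = {}
    out: dict[str, tuple[str, ...]] = {}
    for name, terms in cands.items():
        terms = tuple(dict.fromkeys(terms))
        if terms in seen:
            continue
        seen[terms] = name
        out[name] = terms
    return out


def _fit_candidates(df: pd.DataFrame, response: str,
                    candidates: dict[str, tuple[str, ...]],
                    ) -> tuple[pd.DataFrame, pd.DataFrame, str,
                               dict[str, BetaRegression]]:
    all_terms = sorted({t for terms in candidates.values() for t in terms})
    scaled = df.copy()
    for t in all_terms:
        col = df[t].to_numpy(float)
        sd = col.std(ddof=0)
        scaled[t] = (col - col.mean()) / sd if sd > 0 else 0.0

    rows, coef_rows = [], []
    fits: dict[str, BetaRegression] = {}
    y = scaled[response].to_numpy(float)
    for name, terms in candidates.items():
        X = scaled[list(terms)].to_numpy(float) if terms else \
            np.empty((y.size, 0))
        fit = BetaRegression().fit(X, y)
        fits[name] = fit
        rows.append({"model": name, "k": fit.k_params_,
                     "loglik": fit.loglik_, "aicc": fit.aicc_,
                     "pseudo_r2": fit.pseudo_r2_, "n": fit.n_})
        for term, est, se, (lo, hi) in zip(
                ("intercept", *terms), fit.params_, fit.se_, fit.conf_int_):
            coef_rows.append({"model": name, "term": term, "estimate": est,
                              "se": se, "ci_lo": lo, "ci_hi": hi})
    sel = pd.DataFrame(rows).sort_values(
        ["aicc", "model"], kind="stable").reset_index(drop=True)
    sel["delta_aicc"] = sel["aicc"] - sel["aicc"].iloc[0]
    rel = np.exp(-0.5 * sel["delta_aicc"].to_numpy())
    sel["weight"] = rel / rel.sum()
    top = str(sel["model"].iloc[0])
    sel["top"] = sel["model"] == top
    return sel, pd.DataFrame(coef_rows), top, fits


def run_model_sets(metrics: pd.DataFrame, assignments: pd.DataFrame,
                   variation: pd.DataFrame, objective: int = 2,
                   min_n: int = 10) -> dict[str, SubsetResult]:
    """Fit every candidate on every subset and rank by AICc.

    Tables are joined on ``animal_id``; predictors are scaled and centred
    within each subset.  Subsets with fewer than ``min_n`` animals are
    refused with a diagnostic.
    """
    if objective not in (2, 3):
        raise ValueError("objective must be 2 or 3")
    df = metrics.merge(assignments[["animal_id", "strategy"]], on="animal_id")
    df = df.merge(variation, on="animal_id")
    results: dict[str, SubsetResult] = {}
    for subset in SUBSETS:
        response = RESPONSE_BY_SUBSET[subset]
        sub = df[df["strategy"].isin(STRATEGIES_BY_SUBSET[subset])]
        needed = set(SPATIAL_TERMS + YTY_TERMS)
        if objective == 3:
            needed |= set(CLIMATE_TERMS + ANTHRO_TERMS)
        sub = sub.dropna(subset=[response, *needed]).reset_index(drop=True)
        if len(sub) < min_n:
            raise ValueError(
                f"subset {subset!r} has {len(sub)} animals with complete "
                f"data; need at least {min_n}")
        if objective == 2:
            candidates = dict(OBJECTIVE2_CANDIDATES)
        else:
            _, _, top2, _ = _fit_candidates(sub, response,
                                            dict(OBJECTIVE2_CANDIDATES))
            candidates = objective3_candidates(OBJECTIVE2_CANDIDATES[top2])
        sel, coefs, top, fits = _fit_candidates(sub, response, candidates)
        sel.insert(0, "subset", subset)
        coefs.insert(0, "subset", subset)
        results[subset] = SubsetResult(subset=subset, response=response,
                                       selection=sel, coefficients=coefs,
                                       top_model=top, fits=fits)
    return results


def selection_table(results: dict[str, SubsetResult]) -> pd.DataFrame:
    """Concatenate per-subset selection tables into one tidy frame."""
    return pd.concat([r.selection for r in results.values()],
                     ignore_index=True)


def coefficient_table(results: dict[str, SubsetResult]) -> pd.DataFrame:
    return pd.concat([r.coefficients for r in results.values()],
                     ignore_index=True)
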