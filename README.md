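# movestrat

Tools for classifying the year-round movement strategies of GPS-collared
temperate ungulates (pronghorn, elk and similar species) and for testing
whether spatiotemporal variation in resources explains those strategies.
Intended for movement ecologists with multi-year telemetry: the library
takes 21–23-month relocation records, scores each animal on a set of
continuous range-overlap metrics, clusters animals into strategies, and
runs beta-regression model selection against per-animal summaries of the
resource environment. A synthetic-data module generates ground-truthed
trajectories and covariate landscapes so the whole pipeline can be
verified without field data.

## The method

**Occurrence distributions.** For each seasonal window (summer 1 Jun–31 Aug,
winter 1 Dec–28/29 Feb, winter of year *t* spanning Dec *t*–Feb *t*+1) and
each calendar month, the animal's space use is estimated on a 150 × 150 m
grid, either with a Brownian bridge movement model (BBMM) when fixes are
frequent (gap ≤ 4 h) or an isotropic Gaussian kernel utilization
distribution (KUD) otherwise. In the BBMM, the position at fraction α of a
segment of duration *T* is Gaussian about the linear interpolation of the
endpoint fixes with per-axis variance

    α(1−α)·T·σ²_m + (1−α)²δ² + α²δ²,

where σ²_m is the Brownian motion variance (m²/h, estimated per animal by
the leave-one-out likelihood of odd-indexed fixes) and δ the GPS error SD.

**Overlap metrics.** Pairs of occurrence distributions are compared with
the Bhattacharyya affinity BA = Σᵢ √(pᵢqᵢ) after restricting each surface
to its own 95 % volume isopleth and renormalizing. Four metrics summarize
each animal: (1) mean within-year summer–winter overlap ("seasonal"),
(2) between-year summer overlap, (3) between-year winter overlap, and
(4) mean overlap over all monthly pairs more than one month apart
("annual"; adjacent months are excluded to limit temporal autocorrelation).

**Classification.** k-means (k = 3, k-means++ with 50 restarts) on metrics
1–3 separates *residents* (high seasonal overlap), *dual-range migrants*
(low seasonal, high winter overlap) and *multi-range migrants* (low
seasonal and low winter overlap — animals that switch winter ranges
between years). Clusters are named automatically from their centroids.

**Resource variation and model selection.** Over each animal's year-round
range (95 % KUD mask), or over a standardized circular availability domain
around its winter centroid, the package computes per-covariate spatial SDs
(aggregated to a single PC1 score), year-to-year SDs of annual means of
spring length and herbaceous biomass, snow-based winter indices and
anthropogenic indices. Candidate beta regressions
(y ~ Beta(μφ, (1−μ)φ), logit μ = x′β, constant φ) of the overlap metrics
on these predictors are ranked by AICc across four data subsets
(all animals, dual vs multi, resident vs dual, resident vs multi).

## Worked example

```python
from movestrat import (simulate_population, kmeans_strategies,
                       PipelineConfig)
from movestrat.pipeline import compute_metrics_one
from movestrat.trajio import Trajectory
import pandas as pd

trajs, stack, truth = simulate_population(20, seed=101)  # 60 animals
cfg = PipelineConfig()
metrics = pd.DataFrame([compute_metrics_one(Trajectory(a, df), cfg)
                        for a, df in trajs.items()])
assignments = kmeans_strategies(metrics)
print(metrics[["seasonal_overlap", "winter_overlap"]].median().round(3))
print(assignments["strategy"].value_counts())
```

Output from this exact run:

```
seasonal_overlap    0.00
winter_overlap      0.92
dtype: float64
strategy
dual_range_migrant     21
resident               20
multi_range_migrant    19
Name: count, dtype: int64
```

The median seasonal overlap is 0 because two-thirds of the synthetic
cohort migrates 30 km between seasonal centres, so summer and winter 95 %
isopleths are disjoint; winter overlap is high because only the
multi-range third redraws its winter range. 59 of the 60 animals are
assigned to their generating strategy (98.3 % recovery for this seed: one
multi-range animal happened to redraw a nearby winter centre and looks
dual-range).

The same pipeline is available from the shell:

```bash
movestrat all --run-dir runs/demo          # 30-animal synthetic demo
movestrat simulate --run-dir runs/demo     # or stage by stage
```

which writes `metrics.csv`, `assignments.csv`, the two variation tables,
the AICc selection tables and a machine-readable run manifest; reruns with
the same config and seed are byte-identical.

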