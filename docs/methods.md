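# Methods

This note documents the models implemented in `movestrat`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data can and cannot certify.

## Movement model and occurrence estimation

The Brownian bridge movement model treats the path between consecutive GPS
fixes as a Brownian motion conditioned on both endpoints. At fraction α of
a segment of duration *T* hours the position is bivariate normal around the
linear interpolation of the endpoints with isotropic per-axis variance
α(1−α)·T·σ²_m + (1−α)²δ² + α²δ², where σ²_m (m²/h) is the diffusion
parameter and δ (m) the GPS location-error SD. The occurrence distribution
(OD) for a window is the duration-weighted mixture of these densities over
all segments whose gap does not exceed `max_lag` (default 8 h), discretized
with `n_alpha` midpoint steps per segment (default 10), evaluated at cell
centres, multiplied by cell area and normalized. Doubling `n_alpha` changes
the OD by less than 0.02 total variation at the defaults (tested), so the
midpoint discretization is adequate; tests that compare against closed-form
quadrature oracles raise `n_alpha` to 200, where the midpoint error
(∝ n_alpha⁻²) is below 10⁻⁶.

σ²_m is estimated once per animal from the full record by the standard
leave-one-out likelihood: each odd-indexed fix is scored under the bridge
between its even-indexed neighbours. The predictive variance for a scored
fix adds its own observation error to the two endpoint contributions,
i.e. α(1−α)Tσ²_m + (1 + (1−α)² + α²)δ²; omitting the scored fix's δ² term
biases σ̂²_m upward by roughly 2δ²/(α(1−α)T), which is material at short
fix intervals. The likelihood is maximized over log₁₀ σ²_m on [−3, 8]
(bounded Brent, xatol 10⁻⁶), and the zero-diffusion limit is returned when
it scores at least as well. Fitting per animal rather than per window
follows common BBMM practice and keeps monthly windows (with ~360 fixes)
from producing noisy per-window diffusion estimates.

Windows whose largest gap exceeds 4 h fall back to a kernel utilization
distribution with the isotropic reference bandwidth h = σ̂·n^(−1/6),
σ̂ = √((var_x+var_y)/2). When h spans many grid cells (> 8), the kernel sum
is computed by binning fixes and Gaussian convolution — numerically
indistinguishable at that scale (tested < 0.01 TV against direct sums) and
far cheaper; otherwise each kernel is evaluated directly. Degenerate
kernels (σ → 0) are floored at cell/20 so mass collapses onto the nearest
cell centre instead of underflowing.

Grids are animal-specific, at 150 m resolution, aligned to a global
lattice anchored at the origin and covering the full 21–23-month point
cloud plus a margin of max(3 bandwidths, 10 cells). Lattice alignment means
any two grids with the same cell size re-bin onto their union by whole-cell
shifts; fractionally offset grids (possible with externally produced
rasters) are re-binned by mass-conserving area-weighted splitting.

## Overlap metrics

The Bhattacharyya affinity between two ODs is Σᵢ√(pᵢqᵢ) computed after
restricting each OD to its own 95 % volume isopleth (smallest cell set
holding 95 % of mass, ties broken by cell index) and renormalizing.
Truncate-then-renormalize is one of two defensible readings of
"volumetric overlap using the 95 % ODs"; the untruncated coefficient is
available via `truncate=False` for sensitivity analysis. The four metrics:

1. seasonal — mean of BA(summer₁, winter₁) and BA(summer₂, winter₂);
2. summer — BA(summer₁, summer₂);
3. winter — BA(winter₁, winter₂);
4. annual — mean BA over monthly pairs whose sequential indices differ by
   ≥ 2. The sequence spans the whole record, so a July of year 1 *is*
   compared with a June of year 2; adjacency is adjacency in sequence, not
   in calendar month. A 22-month record yields C(22,2) − 21 = 210 pairs.

## Classification

k-means with k = 3 runs on metrics 1–3 unstandardized (all three live on
[0, 1], so rescaling would only distort their relative spread), k-means++
initialization, 50 restarts, fixed seed. Clusters are named by a fixed
rule: highest metric-1 centroid → resident; of the rest, highest metric-3
centroid → dual-range migrant; remainder → multi-range migrant. A metric-1
tie at machine precision aborts with a request for manual labels. The rule
is the only automated encoding of the verbal strategy definitions;
alternative clusterings (model-based, k selection) are out of scope.

## Resource variation

Spatial variation: per covariate, annual layers are averaged cell-wise
across years, then the SD is taken over the cells of the animal's mask
with denominator *n* (the masked cells are a census of the range, not a
sample). The per-covariate SDs are aggregated by PCA on centred,
unit-variance columns; PC1 scores are the spatial-variation index, with
the component sign oriented so the largest-magnitude loading is positive
(higher score = more heterogeneous range). Zero-variance columns are
dropped with a warning.

Year-to-year variation: per covariate (spring length, biomass), the annual
spatial mean over the mask, then the SD across years with denominator
n − 1 (years are a sample from a climate process).

Climatic and anthropogenic indices: `winter_conditions` is the mean snow
depth over masked cells and years. `winter_severity` is the cohort z-score
of the *worst* winter the animal experienced (maximum annual masked-mean
snow). An earlier candidate definition — the z-score of the mean winter
snow — is, after the within-subset centring and scaling the model stage
applies, an exact affine copy of `winter_conditions`, which makes any
model containing both rank-deficient; the worst-winter definition keeps
"severity" meaningfully distinct (how extreme winters get) from
"conditions" (how snowy they are on average). Percent agriculture and
distance to roads are masked means of the static layers.

The standardized availability domain is a circle of species-standard area
(radius √(area/π); e.g. 3765 km² → 34 619 m) around the winter-fix
centroid, rasterized by cell-centre inclusion. The quoted "radius equal to
the 95 % quantile of range areas" conflates a length with an area; the
area-equivalent-circle reading is used here. All variation indices are
computed by the same code path for both domain types — the two tables can
differ only through the mask (property-tested).

## Beta regression and model selection

Responses are proportions that include exact zeros, where the beta
likelihood is undefined, so observations are compressed by
y′ = (y(n−1) + 0.5)/n before fitting. The model is y′ ~ Beta(μφ, (1−μ)φ)
with logit link for μ and a single constant precision φ (log link) —
the standard first parameterization. Maximum likelihood uses statsmodels'
beta-model implementation with start values from an OLS fit of logit(y′)
and a moment estimate of φ; a fit is accepted when the score norm is
negligible relative to the log-likelihood, with Nelder–Mead/BFGS restarts
otherwise. Standard errors come from the pseudo-inverse of the observed
information (robust to the near-singular Hessians that tiny extreme
subsets produce), 95 % intervals are Wald, and the pseudo-R² is the
squared Pearson correlation between logit(y′) and the fitted linear
predictor (zero for intercept-only models). AICc = −2ℓ + 2k +
2k(k+1)/(n−k−1) with k counting the mean coefficients plus φ.

Candidates never mix the spatial score with year-to-year terms (they are
strongly correlated by construction of the field data this mirrors). The
objective-3 set is: objective-2 top model, intercept, climate, anthropogenic,
and the top model combined with climate, with anthropogenic, and with both —
seven candidates per subset, de-duplicated if the objective-2 top model is
the null. Predictors are centred and scaled within each subset; AICc
ordering is invariant to that affine rescaling (tested). Subsets with
fewer than 10 complete animals are refused, and models whose parameter
count approaches the subset size are rejected by the n > k + 1 guard.

## Synthetic data: what it emulates, what it does not

Trajectories are discrete-time Ornstein–Uhlenbeck tracks whose attraction
centre follows the seasonal calendar, with linear interpolation through
the shoulder seasons (any monotone transition schedule would serve the
recovery tests; real migration paths are not modelled). Defaults: 2 h
fixes (within the 1–4 h collar range, halving test cost relative to 1 h),
22 months starting 1 May (guaranteeing two usable summers and winters),
attraction 0.05 h⁻¹ and step SD 300 m·h^(−1/2), giving a stationary range
SD of ≈ 950 m (a seasonal range of ~25 km², realistic for these species),
and a 30 km seasonal displacement for migrants (typical of the tens-of-km
migrations in this region; the field literature gives no single canonical
value, so this is a free parameter of the test conditions). Multi-range
animals redraw the winter centre uniformly on the 30 km circle each year;
about 5 % of draws land close enough to the previous winter range to
resemble dual-range migration, which is why strategy recovery is asserted
at ≥ 90 % rather than 100 %. The recorded `loc_error_sd` (20 m) is
metadata for the estimators, not added noise, so generator truth is exact.

Landscapes are Gaussian random fields (white noise smoothed at
`corr_length`) plus additive annual effects drawn N(0, yty_sd²) for annual
covariates. The per-covariate amplitude is calibrated so the nominal
spatial SD is attained at a 1500 m reference correlation length; the
realized SD then scales as 1/corr_length, making corr_length a genuine
heterogeneity dial for the PC1 rank-correlation test. Fields are clipped
to physical ranges (e.g. percent agriculture to [0, 1]); base means sit
far enough from the bounds that clipping is rare at the default SDs.

None of this reproduces real topography, step selection, social behaviour,
collar failure patterns, or true nomadism. Passing tests therefore certify
the *computational* pipeline — that the metrics, classifier, variation
indices and model selection recover known generating structure — not that
the ecological conclusions transfer to any particular field system.

## Problem sizes and numerical choices

The verification suite uses a 60-animal cohort (20 per strategy) for
classification recovery, 50-seed Monte-Carlo studies for year-to-year
recovery and AICc selection consistency, 200 simulated datasets (n = 500)
for Wald coverage, and a 30-animal demo run for byte-level reproducibility
— sizes chosen so each study has tight sampling error while the whole
suite runs in a few minutes on one CPU. All randomness flows through
`numpy.random.SeedSequence` children of a single seed; k-means and the
pipeline stages are deterministic given that seed, and output tables are
written with fixed float formatting so reruns are byte-identical.

## Known limitations

- The BBMM uses the cell-centre mass approximation; with location errors
  well below the 150 m cell size, within-cell density variation is
  resolved only after normalization. Halving the cell size is the remedy
  when δ ≪ cell.
- Monthly windows with fewer than 30 fixes are dropped rather than
  estimated; the annual metric is then a mean over fewer pairs.
- The winter-severity index is a design choice (see above), not a
  validated snow-severity product.
- Beta regressions assume independent animals; spatial or population
  random effects are out of scope.
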