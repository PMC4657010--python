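# Methods

## The model

`occuscale` implements the single-season site-occupancy model with imperfect
detection. The latent occupancy state of site *i* is

    z_i ~ Bernoulli(ψ_i),

and the detection on occasion *k*, conditional on occupancy, is

    y_ik | z_i ~ Bernoulli(p_ik · z_i).

Both probabilities are logit-linear in covariates, logit(ψ_i) = β₀ + β₁x_i
and logit(p_ik) = γ'w_ik. Marginalising z gives the site likelihood

    L_i = ψ_i ∏_{k∈obs(i)} p_ik^{y_ik} (1−p_ik)^{1−y_ik}
          + (1−ψ_i) · 1{all observed y_ik = 0},

with non-operational (missing) occasions excluded from the product. The
package fits this by direct numerical maximum likelihood (L-BFGS-B from a
moment-based warm start plus dispersed random starts, default 5; objective
tolerance 1e-12), takes the coefficient covariance from the inverse of a
central-difference Hessian at the optimum, and reports Wald SEs, two-sided
normal p-values and the coefficient of variation CV = SE/|β̂₁|. Estimates
with |coef| > 10 on the logit scale are flagged as boundary (separation)
fits. AIC = −2ℓ̂ + 2K throughout.

The scientific question the package serves is scale sensitivity: how the
*grain* (pixel size of the land-cover raster) and *extent* (radius of the
circular focal patch around a camera station) of habitat covariates change
the support for occupancy models of small rainforest mammals surveyed by
camera traps.

## Covariates

From a categorical land-cover raster (9 classes, 5-m cells by default) the
package derives, per station:

* `D.PLANT_g`, `D.WATER_g` — Euclidean distance (m) to the nearest
  plantation / water cell centre at grain *g* ∈ {5, 30, 90, 250} m. Coarse
  grains come from majority resampling: each coarse cell takes the modal
  class of its block, ties to the smallest class code, partial edge blocks
  aggregated. A point inside a qualifying cell is at distance 0. If a class
  vanishes entirely at a coarse grain the distance is a distinguished
  missing value, never a number.
* `FS_r` — forest score at radius *r* ∈ {10, 50, 100, 150, 250, 500} m: the
  weighted mean of class proportions in the focal patch with integer
  forest-quality weights (bare, grassland, plantation, water 0; shrub 1;
  forest 2; dense and primary forest 3), so FS ∈ [0, 3].
* `HET_r` — Pielou's evenness J = (−Σ p_c ln p_c)/ln S over the S classes
  present in the patch; J := 0 when S = 1 (the formula is 0/0 there) and
  J = 1 at perfect evenness. S counts classes present in the patch, not the
  9-class universe.
* `CC_d` — mean canopy closure of all transect samples within *d* ∈
  {50, 100, 150} m of the station, pooled across the three 250-m transects.

A focal patch contains every cell whose *centre* lies within the radius.
This pixel-in-patch rule reproduces the printed patch areas at 5-m cells
(0.8 ha at 50 m, 3.1 ha at 100 m, 78.5 ha at 500 m). Note that the
conventional figure of 16.9 ha sometimes quoted for a 250-m patch
contradicts the geometry (π·250² ≈ 19.6 ha); the implementation follows the
geometry. Patches clipped by the raster edge are used with a logged
coverage fraction. Occupancy covariates are z-scored before fitting by
default; the mean/SD record travels with the fit so predictions and raw-
scale coefficients are always recoverable (the fitted log-likelihood is
invariant to this, which the tests check).

## The two-stage selection workflow

Stage 1 fixes the detection model: the four candidates p(1), p(road),
p(reserve), p(road+reserve) are fitted with constant occupancy and the
AIC-best wins (ties to fewer parameters). Stage 2 fits one
single-occupancy-covariate model per scale variant (grain or radius) with
the fixed detection terms, plus the constant-occupancy model, and reports
AIC, ΔAIC, Akaike weights w_m = exp(−Δ_m/2)/Σexp(−Δ_j/2), β̂₁, SE, CV and
p-value per row. Non-converged variants are retained in tables with missing
inference and excluded from the weight normalisation.

The consensus radius aggregates evidence across species: for each covariate
family and radius, the radius's ΔAIC (computed within each species' own
candidate set, constant model included) is summed over species; the
consensus radius minimises the grand total restricted to radii available
for every family (CC is only measured to 150 m), ties to the smaller
radius.

## Goodness of fit

The MacKenzie–Bailey test groups sites into cohorts sharing a missingness
pattern, enumerates all 2^K detection histories per cohort, and forms the
Pearson statistic χ² = ΣΣ (O_h − E_h)²/E_h with E_h = Σ_i Pr(h | ψ̂_i, p̂_i);
terms with E_h < 1e-10 are skipped and cohorts with more than 20 observed
occasions are rejected (enumeration bound). The p-value is a parametric
bootstrap: re-simulate from the fit on the template's missingness pattern,
refit (warm-started at the original estimates; the Hessian is skipped in
refits since only ψ̂, p̂ are needed), recompute χ², and report
p = (1 + #{χ²_b ≥ χ²_obs})/(n_boot + 1) — strictly positive by
construction — and the variance-inflation factor ĉ = χ²_obs/mean(χ²_b).
Default n_boot is 100; 1000 is recommended for reporting. No quasi-AIC
re-ranking is performed; ĉ is reported only.

## The synthetic-data generator

The generator emulates a logged Bornean production-forest study so the full
pipeline is testable without field data:

* **Landscape** (default 21 × 17 km at 5-m cells): a contiguous oil-palm
  block on the left edge (~15% of area) with a near-linear, slightly noisy
  boundary; rivers drawn as corridors of width 5, 15, 60 and 300 m plus 40
  ponds of 10–60 m radius, spanning the sub-pixel-to-multi-pixel regimes
  that make distance-to-water grain-sensitive while the wide river keeps
  water present even at the 250-m grain; and a forest-quality mosaic from
  thresholded multi-octave smoothed noise (equal-amplitude octaves from
  200 m down to 25 m). The multi-scale structure matters: with a single
  smooth scale, patch summaries at neighbouring radii are nearly collinear
  and no scale-selection experiment can distinguish them. The disturbed
  (lowest-quality) zone is drawn as a fine mix of shrub, grassland and bare
  ground, and additional open patches concentrate where quality is low —
  in logged forest, gaps and regrowth sit where the canopy is already
  degraded — so land-cover heterogeneity co-varies with forest quality.
* **Stations**: a systematic grid at 1.4-km spacing with random origin and
  radial jitter ≤ 200 m (so nearest-neighbour distances stay in
  [spacing − 2·jitter, spacing + 2·jitter]), restricted to the forest side
  of the plantation edge (cameras sample reserves, not plantations), split
  into three reserve blocks with staggered 42-day deployments, road flags
  i.i.d. Bernoulli(0.5).
* **Canopy transects**: densiometer-style samples every 50 m along three
  250-m transects (bearings 0°/120°/240°). Closure is the local
  forest-quality weight mapped into [0.1, 0.9] plus a smooth canopy
  deviation field (60-m scale, SD 0.25) plus small reading noise — canopy
  is a distinct vegetation-structure variable coupled to, not determined
  by, the land-cover class. Under the defaults this yields a CC₅₀–FS₅₀
  rank correlation of ≈0.6–0.7, matching the magnitude reported for real
  field data.
* **Detection histories**: drawn exactly from the two-stage model, with the
  slope acting per 1 SD of the named covariate; each station-occasion is
  independently missing with probability 0.1 (field camera-failure rates
  vary widely and are rarely reported; 0.1 is a guess and is flagged as
  such in the config docs). True z values ride along for recovery scoring.

Everything is deterministic given its seed; pipeline stage seeds derive
from the master seed by hashing the stage name.

What the generator does **not** emulate: classification error in the land
cover map (the raster is the truth), spatial autocorrelation of occupancy
beyond what covariates induce, heterogeneous camera effort within an
occasion, animal movement or temporary emigration, and real river network
topology (corridors are straight-ish bands). Passing recovery tests
therefore demonstrates the estimators and the selection machinery, not
robustness to classification noise or non-independence.

## Simulation-study problem sizes

The statistical acceptance tests run, per study: 150 stations × 7
occasions; ten independently generated landscapes shared across replicates,
with detection histories redrawn per replicate (10 draws each for the
grain-direction study, 5 × 6 species for the consensus study); 200
replicates for slope recovery; 50 outer replicates × 99 bootstrap draws for
goodness-of-fit calibration. Occupancy slopes of |β₁| ∈ [1.2, 2.0] per SD
and a per-occasion detection probability of 0.35 are used as realistic
field-strength effects. These sizes are the package's chosen design points
for a serial run.

## Numerical choices and edge cases

* Optimizer: L-BFGS-B, ftol 1e-12, gtol 1e-8, ≤500 iterations; best of the
  multi-start runs, re-polished once if the winning run ended abnormally.
* Hessian: central differences with relative step 1e-5; a non-positive-
  definite Hessian yields `converged=False` and missing SEs, never a crash.
* Likelihood underflow is avoided via `logaddexp` on the two z-branches;
  p = 0/1 and ψ = 0/1 are handled exactly.
* Majority-resample ties: smallest class code (deterministic stand-in for
  unspecified GIS behaviour).
* Distances are measured point-to-cell-centre, which is resolution-
  consistent and exhaustively verifiable.
* Occasion calendars are anchored at each study area's earliest deployment
  date; a station-occasion is operational if the deployment overlaps the
  occasion by at least one day; the final occasion may be short.
* Detection-model AIC ties (< 1e-6) go to fewer parameters; consensus ties
  to the smaller radius.
* The "global model" used for goodness of fit is the best detection terms
  plus the consensus-radius forest score, keeping the
  one-occupancy-covariate design.

## Known limitations

* Detection covariates are station-level only (road, reserve); true
  occasion-varying detection (weather, season) is not modelled.
* No spatial dependence between stations is modelled or tested; the 1.4-km
  spacing is assumed sufficient, as in the field design.
* The bootstrap refit reuses the original design matrices; it does not
  re-standardise covariates per replicate (the covariates are fixed by
  design, only detections are re-drawn).
* Real-data mode expects the same CSV/ASCII-grid formats the synthetic
  writer produces; GeoTIFF and CRS handling are out of scope.
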