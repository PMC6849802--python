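# Methods

## The indices

The species temperature index (STI) is a fixed per-species scalar: the
long-term mean temperature a species experiences across its range. The
community temperature index (CTI) of one site-year is the STI of the
species present, weighted by relative abundance:

    CTI_st = sum_i n_ist * STI_i / sum_i n_ist

over species with positive abundance. Species whose abundance index is
unavailable in a given year still count as *present* (they enter the
species count and the index-coverage fraction) but contribute nothing to
CTI or assemblage totals. Weighting is within site-year only; there is no
cross-site normalisation.

To see which species drive a CTI change, the species pool is stable-sorted
by (STI, species id) and cut at the 25/50/75% rank boundaries into four
contiguous assemblages (low, medium-low, medium-high, high STI) whose
sizes differ by at most one (cut points `round(n*k/4)`, k = 1..3). A
rank-based split was chosen over interpolation quantiles because it is
deterministic under ties and yields balanced groups; the tie-break by
species id makes re-runs bit-identical. By default quartiles are computed
over the full species list of the scheme; a `quartile_scope: filtered`
option restricts the pool to species surviving the inclusion filters.

Inclusion filters: a site-year is kept when at least 10 species are
present **and** strictly more than 75% of them have an index; sites then
need at least 6 surviving years (more than five years' data). Both
thresholds are configurable; the coverage comparison is deliberately
strict (`>`), so coverage of exactly 0.75 fails.

## Mixed models

All community-level models share one random structure: crossed random
intercepts for Site, Year (categorical — common weather shocks) and the
50-km grid cell (floor(easting/50 km), floor(northing/50 km); a coarse
block absorbing residual spatial autocorrelation), plus, for the CTI and
assemblage trend models, a random Year slope within Site. Year enters the
fixed effects centred; slopes are reported per calendar year.

Estimation is maximum likelihood wherever a likelihood-ratio test or an
AIC comparison is involved (so those are valid); the gaussian fitter
also offers profiled REML, used for pure interval estimation — notably
the coverage study — because ML variance components are biased low when
a random factor has few levels (25 years), which shrinks Wald intervals.
AIC counts fixed coefficients plus variance components (plus the
residual variance for gaussian models) and refuses REML fits.

The estimator is a variance-components core written for this package:

* **Gaussian**: the residual variance is profiled out and the marginal
  likelihood evaluated through the Woodbury identity on the q x q scale
  (q = total random-effect levels), making replicate studies cheap even
  with crossed designs. Agreement with statsmodels `MixedLM` (ML) is at
  the 1e-6 level on crossed test problems, and the zero-variance limit
  reproduces OLS.
* **Poisson log-link**: a Laplace approximation. For each candidate
  vector of log random-effect standard deviations, the joint penalised
  likelihood is maximised over (fixed effects, random effects) by Newton
  iterations with step halving; the marginal likelihood is the penalised
  optimum minus half the log-determinant of the random-effects Hessian.
  This is the *joint-mode* Laplace variant: the fixed effects are part of
  the inner mode rather than of the outer (determinant-aware) objective.
  On small fixtures it matches R `lme4::glmer` variance components and
  standard errors to well under 1%, log-likelihoods to ~0.005, and fixed
  effects to a few percent of a standard error — the documented offset of
  the two Laplace variants. The outer optimisation is Nelder-Mead on the
  log-SD scale with bounds [-7, 4]; a component within 1e-3 of zero SD
  flags the fit as singular (never an error).

Assemblage abundance indices may be non-integer (transect-derived
indices); for Poisson-family fits they are rounded half-to-even with a
logged warning. Per-site trends use quasipoisson GLMs (statsmodels,
Pearson chi-square dispersion), whose slope and z are invariant to
multiplicative rescaling of counts. Per-species trends use a Poisson
mixed model with a Site intercept; single-site species fall back to a
plain Poisson GLM and are flagged.

Spatial autocorrelation of per-site slopes is screened with a
distance-binned Moran's I plus a permutation envelope — a deliberately
small stand-in serving the same detection purpose as a spline
correlogram, with equal-width bins up to half the maximum inter-site
distance.

## Interaction models and scale of effect

The land-use interaction model for an assemblage's total abundance has
fixed effects Year, high-intensity buffer proportion, centred site mean
annual temperature, Year x land-use and Year x temperature, with the
three random intercepts (no random slope — the slope variation is exactly
what the interactions model). Two deliberate covariate choices:

* land use enters as the **proportion of the buffer** rather than raw
  area, so coefficients are comparable across radii and the interaction
  is log-abundance per year per unit proportion;
* temperature is the **site mean over its recorded years** (the
  interaction asks whether persistently warmer sites change differently),
  centred; a site-year-varying temperature is available to the reader by
  passing a different covariate.

High-intensity land use is any of six combinations of arable (A), urban
(U) and improved grassland — IG1 = total grassland minus calcareous, IG2
= additionally minus lowland meadows — each with or without sea, at
buffer radii 0.5/2/5/10 km. `select_best` fits the full grid, ranks by
AIC, breaks exact ties toward the combination with fewer categories, then
without sea, then the smaller radius, and flags (and excludes from
ranking) non-converged cells.

Variance explained uses the Nakagawa–Schielzeth decomposition: marginal
R2 = var(fixed predictor) / (fixed + random + additive), conditional adds
the random-effect variance to the numerator. The additive variance is the
residual variance (gaussian) or the lognormal approximation
`ln(1 + 1/lambda_bar)` with `lambda_bar = exp(intercept)` at centred
covariates (Poisson); random slopes contribute their variance times the
mean squared slope covariate.

## Spatial CTI model and back-calculation

CTI is regressed on five percentage covers in the 0.5-km buffer (arable,
improved grassland, urban/suburban, broadleaved woodland, low-intensity
grassland — the grassland pair defined per IG1 or IG2), plus easting and
northing, with the three random intercepts. Covariates are screened for
degeneracy (constant covers) and collinearity (condition number > 1e8
names the worst-correlated pair). Back-calculation inverts a habitat
slope: required cover change = (cumulative CTI change) / (deg C per unit
proportion), flagged infeasible when the implied final cover leaves
[0, 1]. Only single-habitat solutions are computed; multi-habitat
combinations trade off linearly. The cumulative change itself is the
annual coefficient times the span in years; the bird-scheme arithmetic
0.0046 x 36 = 0.166 is used as the worked example (the printed span is
quoted inconsistently in the source material as 1964–2009 next to data
ending in 2000; both spans are accepted as inputs here — the arithmetic
shown matches the 36-year product).

## The synthetic generator

The generator emulates a monitoring scheme, not any real landscape. Log
expected counts follow

    log mu[i,s,t] = a_i + u_s + v_t + w_g(s)
                    + (beta_g(i) + delta_g(i) H_s + gamma_g(i) Tc_s + e_s) (t - t_bar)

with species intercepts `a_i ~ N(2.0, 0.7)` (typical index of ~7 per
species), site/year/grid intercepts with SD 0.5 / 0.08 / 0.2, site slope
noise SD 0.004, per-assemblage trends `beta_g` defaulting to the bird
scheme's values (-0.025, +0.006, +0.010, -0.013 for low..high), and
land-use/temperature interactions defaulting to zero. Year effects are
shared across sites and species (common weather), which is precisely why
a Year random intercept is needed downstream and why strong nonlinear
reorganisation (the butterfly-like regime) renders the *aggregate* CTI
trend non-significant even as warm-associated abundance rises steeply —
the year term absorbs the curvature. Counts are Poisson, or gamma-mixed
Poisson when `overdispersion > 0`; the default is 0 because the
site/year/slope effects already induce marginal overdispersion and the
community-level models are Poisson. STIs are normal(10.5, 1.5) deg C.

The landscape is built from independent Gaussian-blurred white-noise
fields (one per category, blur length 800 m), combined by offset-shifted
argmax with offsets calibrated iteratively (on a strided subsample) until
realized grid-wide proportions sit within ~0.02 of the configured
targets. This yields clumped, mutually independent category patterns
whose 0.5-km high-intensity proportions span essentially [0, 1] across
sites, making interaction effects identifiable. Sites sit on a jittered
grid at 8-km spacing with a 10-km margin so every buffer fits. The
default raster cell is 100 m: the analysis only consumes buffer
*compositions*, which at these radii are insensitive to cells far coarser
than a 25-m source product (buffer-geometry tests run at 25 m and 5 m).
Temperatures combine a north-south gradient (-1.5 deg C per 100 km),
site-level noise (SD 0.4), shared annual anomalies (SD 0.5) and site-year
noise (SD 0.15).

What the generator does **not** emulate: species interactions, dispersal,
observer effort drift, detectability, spatially autocorrelated *trends*
beyond the 50-km block structure, and land-cover change over time (the
source land-cover data are treated as static). Passing tests therefore
validate the estimators and the pipeline logic under the assumed data
model — not the ecological conclusions one would draw from real scheme
data.

## Validation studies and problem sizes

Four replicate studies validate the chain end to end (sizes are the
package's chosen desk-scale study conditions; master seeds fan out to
per-replicate seeds):

* **Masking** — 20 replicates x 2 scenarios at 100 sites x 25 years x 60
  species, full observation model. Bird-like (the four bird trend values)
  and butterfly-like (+0.26 on the high-STI quartile, others zero)
  regimes must be distinguished by the sign pattern of the assemblage
  slopes; sign agreement is assessed only where the generating trend is
  nonzero, since a sign is meaningless for a zero truth.
* **Recovery** — 100 replicates at the default 150 sites x 25 years x 60
  species; 95% Wald coverage of the generating coefficient for the CTI
  LMM (slope 0.0046 on its gaussian generative twin, fitted by REML since
  no LRT is involved — Wald-z intervals still sit a point or two below
  nominal because the slope's error is dominated by the 25-level year
  factor, a small-sample effect the 90–99% acceptance band absorbs), the
  assemblage
  GLMM (the -0.013 high-STI trend) and the interaction GLMM (-0.28 Year x
  land-use on the low-STI assemblage). Survey gaps, missing indices and
  site slope noise are off here so each fitted model matches its
  generating process exactly; the interaction model's precision makes
  even small generator/model mismatches (e.g. a temperature covariate
  averaged over different year sets) visible as undercoverage, which is a
  feature of the check, not noise to be absorbed.
* **Calibration** — 100 replicates at 80 sites x 20 years with zero
  interactions; both interaction z-statistics must be standard normal
  (fraction within +/-1.96 and a Kolmogorov–Smirnov check).
* **Scale-of-effect selection** — 50 replicates at 60 sites x 20 years
  generated with arable+urban at 2 km (interaction -0.54); `select_best`
  runs the six sea-free combinations x four radii. The synthetic
  landscape contains no sea, under which sea-inclusive combinations are
  numerically identical to their sea-free twins, so the sea variants are
  excluded from this grid to keep the selection well posed.

Replicate studies use 150-m raster cells (buffer composition at 2 km is
insensitive to this) and warm-start the variance parameters across
replicates and grid cells; warm starts change only the optimiser path,
not the objective.

## Numerical choices and degenerate inputs

* Outer optimiser: Nelder-Mead; xatol 2e-4 (gaussian) / 2e-4 (Poisson) on
  log-SDs. Inner Newton: gradient tolerance 1e-6 scaled by sqrt of total
  intensity, max 100 iterations, step halving, linear predictor clipped
  at +/-30.
* Empty communities raise; species with positive abundance but no STI
  raise unless an explicit drop-with-log option is set, so a silent index
  distortion is impossible.
* All-zero count series, all-equal STIs (< 4 species), non-nested LRT
  pairs, zero-length spans and near-zero back-calculation slopes are
  errors, not warnings.
* Buffer membership is cell-centre inclusive; the buffer-area denominator
  is the full buffer (sea included) — the source material does not state
  either convention, so both are documented choices here.

## Known limitations

* The Poisson GLMM is joint-mode Laplace; for very small counts per
  level its fixed-effect point estimates can differ from profiled-Laplace
  implementations by a few percent of a standard error.
* Richness models reuse the abundance model's random structure, including
  the Year slope within Site; with little richness variation those
  components often fit at the boundary and are flagged singular.
* The correlogram stand-in detects, but does not model, residual spatial
  autocorrelation; the 50-km random intercept is the only spatial term.
* GeoTIFF rasters are not read; land cover is exchanged as ESRI ASCII
  grids (plain text).
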