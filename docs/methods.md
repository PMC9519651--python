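# Methods

`grazerange` asks a displacement question: when a herded livestock flock
grazes a site inside a wild herbivore's range, does the animal's use of the
site — and its selection of the surrounding landscape — change before,
during and after the grazing term?  The package implements the two-step
analysis used for this kind of GPS-telemetry study, together with a
synthetic world that makes every step testable against known truth.

## The two-step analysis

**Step 1 — direct use of the grazed sites.**  Each 2-hourly GPS fix is
classified as inside/outside the grazing-site polygons and labelled with a
21-day treatment window relative to the grazing term at the animal's site
group: *before* (the 21 days preceding the start), *early* (days 1–21),
*ongoing* (days 22–42) and *after* (the 21 days following the end).  A
random-intercept logistic regression models the probability of being inside
a site from treatment, time of day (day / night / twilight from solar
geometry), and calving/rut flags, with animal identity as the grouping
factor.  Fixes within six days after a driven hunt are excluded first, and
data are split into summer (May–October) and winter (November–January)
models.

**Step 2 — resource selection functions.**  A use–availability design
contrasts each used fix with `ratio` random points (default 16, following a
stability analysis interface provided as `ratio_sensitivity`) drawn
uniformly from the animal's home range, each inheriting the used fix's
timestamp and therefore all temporal labels.  The home range is the 0.99
isopleth of a fixed-kernel density estimate built from *all* of the
animal's fixes.  A random-intercept logistic model over scaled tree cover,
NDVI, distance-to-site (with quadratics of the scaled values) and their
interactions with treatment and time of day is AIC-selected; coefficients
with p < 0.05 form the exponential RSF

    w(x) = exp(beta_1 x_1 + ... + beta_n x_n),

a relative (not probabilistic) measure of selection.  Scenario maps and
score–distance profiles (scores divided by the scenario median) visualise
displacement.

## The mixed logistic likelihood

`MixedLogit` maximises the exact marginal likelihood of a logistic model
with one Gaussian random intercept per animal.  The per-group integral is
evaluated by adaptive Gauss–Hermite quadrature: an inner Newton iteration
finds each group's conditional mode and curvature, and the Hermite rule is
applied on the re-centred, re-scaled axis.  Fifteen nodes are the default
(nine is the floor; 9 vs 25 nodes moves the log-likelihood by < 1e-3 on the
test fixtures).  The analytic score treats the adapted node locations as
fixed — their parameter-dependence is second-order when the quadrature is
accurate, and the gradient agrees with finite differences to ~1e-5
relative.  Standard errors come from central differences of that score
(observed information); p-values are Wald.  The implementation reproduces
`lme4::glmer(..., nAGQ=15)` log-likelihoods and estimates to four decimals
on clustered test data, and collapses exactly to iteratively reweighted
least squares when the random-effect SD is fixed at zero.  Any coefficient
beyond 15 on the link scale triggers a quasi-separation warning rather
than an error — such terms occur in real sparse strata.

AIC is `-2 logLik + 2 (k_fixed + 1)` with the variance component counted
when estimated; model selection calls a gap of ≥ 10 AIC units "decisive".
Collinearity is screened by pairwise Pearson correlation and the
determinant-ratio generalised VIF (with `GVIF^(1/2df)` for multi-column
terms).  Marginal and conditional R² use the logistic-link variance
decomposition with residual variance π²/3.

## The synthetic world

The generator emulates the study system the pipeline targets: a ~10 × 12 km
forest–heath mosaic at 20 m resolution, three grazing sites of roughly
62, 22 and 102 ha in a northern and a southern group, a 25-day December
term in the first year, long June–September/October terms in later years
(the flock alternating between site groups in 6–9-week blocks), and about
a dozen collared animals recording a fix every two hours for three years.

Tree cover and NDVI are Gaussian-smoothed white-noise fields min–max
rescaled into their physical ranges (0–100 %, −0.2–0.9); the smoothing SD
(default 300 m) sets the spatial autocorrelation scale.  Deer are an
independent weighted point process: each fix is drawn from the raster cells
of the animal's home region with probability ∝ exp(η), where η is the true
model's linear predictor in that fix's treatment/time-of-day context.
Movement autocorrelation is deliberately absent — the RSF's
exchangeability assumption is the generative assumption, so a green
recovery test establishes correctness of the estimator, not robustness to
serially correlated tracks.  Animal-level intercepts are drawn from
N(0, 0.5²); within a home range they cancel from the location distribution
(and with a fixed 1:16 design they are absorbed by the intercept), so the
use–availability fit correctly estimates their variance near zero.

Two generative choices matter and were made deliberately:

- **Soft-edged home ranges.**  The generative support is a generous box
  around each home-range centre; the distance-decay of the selection
  surface itself (distance in fixed units of 600 m, quadratic coefficient
  −0.5) confines the animal well inside it.  A hard-edged support would
  put truly unusable area inside the estimated 0.99 isopleth, and
  availability points with zero use density bias distance coefficients
  severely — an artifact of simulating sharp boundaries that real home
  ranges do not have.
- **One domain for used and available.**  Used fixes outside the animal's
  own 0.99 isopleth (~0.1–1 % by construction) are dropped before the RSF
  fit.  The use–availability log-odds is only defined over the
  availability domain; keeping points beyond it gives them unbounded
  leverage and measurably attenuates the quadratic distance term.

Coefficients of the true model are expressed under a *reference* scaling
(landscape-wide moments for the fields, the fixed 600 m unit for
distance).  The pipeline scales covariates by the pooled data moments, so
recovery reports re-express the fitted coefficients under the reference
scaling by the exact linear map induced by the affine change of basis
(quadratics expand binomially; the covariance transforms as `T' Σ T`).
Intercept and categorical main effects absorb within-home-range
normalising constants in a use–availability design and are not compared.

## Kernel home ranges

The utilisation distribution is a binned KDE: fixes are histogrammed onto
the analysis grid (default 20 m, matching the covariate rasters) and
smoothed with an isotropic Gaussian; at telemetry scales this is
indistinguishable from exact evaluation.  The default bandwidth is the
bivariate reference value σ·n^(−1/6) with σ² the mean marginal variance —
the study this emulates did not state its bandwidth, so the conventional
plug-in is used and recorded in every output.  The isopleth threshold is
found by ranking cells by density and accumulating mass, ties included;
the retained cells are polygonised exactly (unions of cell squares), so
contained mass is consistent with the polygon by construction.
Availability is drawn by rejection sampling from the isopleth bounding
box.

## Cross-validation

Validation is rank-based: held-out used and available points are scored by
the refitted model (same term list per fold, no per-fold reselection),
scores are cut into 10 quantile bins of the held-out availability scores
(equal availability mass; tied edges merge bins), and the Spearman
correlation between bin rank and area-adjusted frequency
(used share / available share) summarises how monotonically the model
orders habitat.  Random folds are stratified within animal, with each
availability point following its paired used fix; blocked folds assign
whole animals, balancing fold sizes by data volume — the stricter test of
transfer across individuals.

## Numerical and convention details

- Treatment windows are calendar-date windows under a fixed UTC offset
  (default +1).  Terms shorter than 42 days produce no *ongoing* window
  (a 25-day December term yields three treatment levels); days 43+ of a
  long term are unassigned.  Where windows of consecutive terms collide,
  within-term labels win over before/after.
- Time-of-day intervals are half-open; an instant exactly at a solar event
  belongs to the later class.  Sunrise/sunset sit at solar elevation
  −0.833°, nautical dawn/dusk at −12°, from the NOAA low-accuracy solar
  position algorithm (sub-minute accuracy at mid-latitudes; one reference
  coordinate serves the whole study area).
- Quadratic model terms are squares of the *scaled* variable.
- Raster extraction is nearest-cell; boundary points count as inside
  grazing sites, and distance-to-site is zero there.
- Rasters are plain numpy grids with ESRI ASCII-grid text I/O; inputs
  must share one planar metric CRS and grid (no reprojection).
- Every generator and sampler is a pure function of its explicit seed.

## Known limitations

- No movement model: step lengths, turning angles and serial correlation
  are out of scope, so effective sample sizes in real telemetry will be
  smaller than the nominal fix count.
- The schedule generator reproduces the qualitative grazing pattern, not
  dated historical intervals.
- Only one Gaussian random intercept; no random slopes or crossed effects.
- Prediction maps reuse the training-data scaling verbatim; applying an
  RSF to a landscape with very different covariate ranges extrapolates.
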