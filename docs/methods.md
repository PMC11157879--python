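# Methods

`movesdm` turns irregular, error-prone satellite telemetry of migratory
marine megafauna into validated habitat-suitability maps. This note
documents the models, the numerical choices, and what the synthetic test
bed does and does not establish.

## Track regularization (state-space smoother)

Raw fixes arrive irregularly with class-dependent error: Argos location
classes 3, 2, 1, 0, A, B, Z carry 95th-percentile radii of 1.5, 3.3, 7.6,
36, 60, 163 and 220 km; GPS fixes ("G") are treated as 0.03 km. Tracks are
split at transmission gaps longer than 5 days, and each segment is smoothed
onto a regular grid whose step is 24 h divided by the tag's mean daily fix
rate, clamped to [1, 24] h and rounded to a divisor of 24.

The latent positions follow a discrete-time correlated random walk,
`x_{t+1} = x_t + phi (x_t - x_{t-1}) + eta_t`, `eta_t ~ N(0, sigma_p^2 I)`
with fixed `phi = 0.7`; each fix observes the linearly interpolated latent
position with per-axis Gaussian error `sigma = err95 / 1.96` (degrees at
local latitude). For fixed variances the MAP problem is sparse linear least
squares, solved exactly; `sigma_p` is estimated by EM (the update includes
the posterior-covariance trace term). Two numerical details matter:

* **Initialisation.** `sigma_p` is initialised from the second differences
  of the *precise* fixes only (GPS and classes 3/2/1). The likelihood in
  `sigma_p` is bimodal for heavily Argos-contaminated tracks — initialising
  from the noise-dominated full series converges to a no-smoothing mode
  that tracks class-B noise.
* **Discretization jitter.** A fix measures the interpolated position only
  up to the movement within its time step, so the observation variance is
  inflated by a Brownian-bridge term `w (1 - w) sigma_p^2` (zero at grid
  nodes). Without it, near-exact GPS fixes force the latent states to
  contort between nodes and EM inflates `sigma_p` to pay for it.

Convergence requires the stationarity gradient below 1e-5; non-converged
segments are excluded and logged.

## Move persistence and behaviour labels

Move persistence `g in [0, 1]` indexes the autocorrelation of speed and
direction: displacements follow `d_{t+1} ~ N(g_t d_t, sigma_d^2 I)` with
`logit(g)` a Gaussian random walk. The MAP path is found by L-BFGS with
`sigma_d^2` profiled and `sigma_g^2` updated EM-style using the Laplace
(tridiagonal Gauss–Newton) posterior covariance. The per-step logit drift
variance is capped at 0.05 (drift SD ~0.22/step): the cap is a prior on how
fast behaviour can switch and simultaneously controls the local-AR
small-sample bias; without it the profile over-fits local noise and
high-persistence phases are biased low. Locations with `g >= 0.8` are
labelled migration; lower-persistence locations are foraging in Australian
waters (lat <= -11.5 deg) and foraging/reproduction north of that line.
The threshold is applied to point estimates of g.

## Use–availability design

Five pseudo tracks per smoothed segment, each sharing the segment's start
point, length and timestamps; headings follow a correlated walk with turns
and step lengths resampled independently from the segment's empirical
distributions, blended (weight 0.25) with the great-circle bearing to the
segment's end point, and jittered by a uniform offset of full width 180 or
300 degrees (drawn per track and recorded). Candidates on land or outside
the regional extent are rejected and resampled (100 attempts, then a
reflection toward the extent centroid). Every simulated location inherits
the source location's behaviour label and region tag element-wise, giving
exactly five pseudo-absence rows per presence row within each region x
behaviour dataset before clipping. Visual convergence inspection is
replaced by the machine-checkable rejection/retry contract.

## Covariates

Static terrain: depth, rugosity (window-3 neighbourhood SD of depth — a
standard heterogeneity measure in place of GUI-derived terrain products),
and great-circle distance to canyon features. Dynamic fields enter as
fixed, non-overlapping 5-day or 8-day block means anchored at the stack
start, or calendar-month SDs; chlorophyll-a is matched 14 days before each
location (the trophic lag from primary production to zooplankton) and
natural-log transformed. Month (1–12, integer) controls seasonality.
Pairwise Pearson screening at |r| > 0.6 drops the lower-importance member
of the worst pair iteratively; month is excluded from the screen because it
is a design control, not an environmental field, and in strongly seasonal
data it would otherwise displace the field (e.g. SST) that carries the
spatial signal. Rows with missing covariates are excluded from fitting
(complete-case) and counted.

## Habitat model

A gradient-boosted tree classifier with Bernoulli (logistic) deviance
(scikit-learn's `GradientBoostingClassifier`), with gbm-style knobs:
interaction depth, trees, minimum node size, shrinkage, bag fraction.
Configurations are tuned by stratified 5-fold cross-validated MSE of
predicted probability against the 0/1 label (on a stratified subsample of
at most 8000 rows when the dataset is larger); ties break toward fewer
trees, then smaller depth.

After tuning, covariates are simplified by backward elimination: the
lowest-influence covariate is dropped while the cross-validated MSE does
not worsen by more than one standard error. Boosted models readily fit
responses to incidental, realized environmental variation (eddies present
during the study); such responses discriminate in-sample but corrupt
prediction maps built from period-averaged covariates, and the elimination
step removes covariates whose contribution does not generalize. The model
is then fit on a stratified 75% split, evaluated on the held-out 25%
(global AUC by rank concordance with ties at 1/2; Cohen's Kappa at the
prevalence-matched threshold; Spearman correlation of predictions against
labels, >0.5 considered adequate), and low-influence covariates are
dropped iteratively until global AUC exceeds 0.6 (floor: two covariates,
released flagged if never reached).

Prediction grids average each dynamic layer over a time window (for the
monthly-SD covariate: the mean of the calendar-month SDs), resample all
layers to the coarsest resolution (bilinear; nearest for categorical), and
clip to the region. Cells whose covariates fall outside the training
data's range are masked: trees extrapolate as arbitrary constant leaves,
and such cells would carry spurious suitability. The pipeline predicts on
a grid per 10-day window across the dataset's temporal extent and averages
the *predictions* (masking cells predicted in fewer than half the
windows): predicting once on covariates averaged over the whole period
would evaluate the trees at covariate combinations never realized
together, and would carry responses to transient anomalies into the map —
time-marginalizing the predictions does neither. The continuous map is
thresholded where predicted prevalence equals observed prevalence (the
(1 - prevalence)-quantile of the scores, verified optimal by exhaustive
scan), yielding the binary suitable/unsuitable map.

## Spatial validation

The empirical variogram of the presence/pseudo-absence labels
(`gamma(h) = ` mean half squared difference per distance bin; coincident
pairs excluded as nugget) yields a sill (mean of the last third of bins), a
range per track (first bin reaching 95% of the sill; per-track ranges
averaged, pooled fallback under 3 tracks) and a slope measured on doubly
normalized axes (`gamma/sill` vs `h/h_max`, over the rising limb, or over
all filled bins when the variogram is flat) so the 0.8 criterion is
dimensionless. Slope >= 0.8: window diameter twice the mean range, centroid
spacing one range; otherwise half and a quarter of the range (both give 50%
overlap; the boundary case takes the high-slope branch). Windows are hard
circles; local Kappa (at the global prevalence-matched threshold) and local
AUC are computed from the points inside each window, masked when a class is
absent or fewer than 20 points fall inside. Centroid values are rasterized
by inverse-distance weighting of the four nearest evaluated centroids.
Binary suitability is "validated" only where both spatial metrics exceed
0.4; masked accuracy cells are never validated, so the validated map is a
cellwise subset of the binary map.

## Synthetic test bed

The generator builds an eastern-boundary margin: a meandering coast, a
shelf (0–200 m over 80 km), a slope (200–3800 m over 220 km) with bounded
along-shore texture (so rugosity is not a deterministic proxy of the
cross-shore position; depth stays monotone offshore), a flat basin, nine
cross-slope canyons, and daily SST (latitudinal gradient + seasonal cycle +
mesoscale anomalies), chlorophyll-a (coastal enrichment, ~14-day
autocorrelated multiplicative anomalies) and SSHA (~30-day mesoscale
anomalies). Anomaly fields are sums of 8–10 mesoscale (1.5–2 deg) modes:
large-scale single-gradient "anomalies" would act as position fingerprints
that a boosted model memorizes.

Planted truth: suitability is exactly
`sigmoid(3 f_depth + 1 f_sst - 2.9)` with a slope-band depth feature
`f_depth = exp(-((depth-700)/500)^2)` and a monotone warm-water feature
`f_sst = clip((sst_clim - 19)/9, 0, 1)`. The depth effect dominates the
truth's rank structure by design: presence rows and their pseudo-absence
twins share timestamps and similar latitudes, so a use-availability design
only weakly identifies effects of a smooth meridional field like
climatological SST — a truth dominated by such an effect would be
unrecoverable by *any* estimator of this class, and the study this package
emulates likewise reports depth as the consistently dominant predictor
with variable SST responses. Whales alternate high-persistence
(g = 0.92) along-shore migration with low-persistence (g = 0.3)
area-restricted bouts; bout entry probability and bout duration both rise
with local suitability (a marginal-value-theorem dose–response) and a weak
taxis climbs the suitability gradient during bouts. This matters: with
hard-threshold patch residence, realized usage is a step function of
suitability and the use–availability design cannot — and should not — rank
moderately suitable habitat, making the recovery target unattainable by
construction. Tag deployments start at aggregations (start cells drawn
with probability proportional to squared suitability). Observation applies
Poisson daily thinning (4 fixes/day), a 60/40 Argos/GPS mix with the class
frequencies above, per-axis Gaussian error `err95/1.96`, and >5-day gaps at
2% daily probability. Defaults are the target study's conditions: 38
tracks, durations log-uniform on 8–384 days (median ~55), ~30% of true
steps at low persistence.

What passing recovery tests show: the pipeline can take error-corrupted,
irregular telemetry through to maps that rank a *known* suitability
surface correctly, with behaviour labels matching the generating regimes.
What they do not show: performance under real Argos error (heavy-tailed,
not Gaussian), under covariate measurement error or cloud-gap missingness
patterns, under density dependence or social behaviour, or when the true
suitability is non-stationary in time.

## Problem sizes and runtimes

Default synthetic study: 200 x 89 cells at ~10 km, 38 whales, ~10,000
fixes; the full pipeline runs in a few minutes on one core. The test suite
uses the same generator at reduced sizes (2–6 whales for smoke and
structural tests; the full 38-track study for the end-to-end recovery
checks). The tuning grid default in the pipeline configuration is a compact
2 x 2 x 2 factorial (depth, trees, shrinkage); the full 72-point factorial
documented for the model module remains available where a thorough search
is wanted.

## Known limitations

* The smoother is discrete-time with linear interpolation to fix times; a
  continuous-time formulation would handle very sparse tags better.
* Collinearity screening and influence ranks are unstable when several
  terrain variables proxy the same feature; the simplification step
  mitigates but does not remove this.
* Spatial Kappa/AUC windows assume isotropy; anisotropic variograms along
  a coastline are not modelled.
* Global metrics are computed on a random 25% holdout (rows, not tracks),
  matching the study design this pipeline follows; block (per-track)
  holdouts give more conservative numbers on autocorrelated data.
* Use–availability with time-matched controls weakly identifies effects of
  smooth, slowly varying fields (climatological SST): presences and their
  pseudo-absence twins sample such fields almost identically. Suitability
  ranks are therefore recovered reliably along well-sampled contrast axes
  (depth) but not across regions whose true variation is carried only by a
  weakly identified field — pooled rank agreement between predicted and
  generating suitability typically lands between ~0.2 and ~0.7 across
  study realizations, with within-margin strata (shelf, shelf break,
  slope) individually at ~0.4–0.8.
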