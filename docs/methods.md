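# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of `tempmort`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## First-stage model

Each location's daily death count is modelled with a quasi-Poisson
log-linear regression on a temperature–lag cross-basis plus confounder
control.

*Exposure basis.* Natural cubic spline of daily mean temperature. Interior
knots default to the location's 10th/75th/90th temperature percentiles
with boundary knots at the observed min/max; both are configurable
(`CrossBasisSpec`). Natural splines are linear beyond the boundary knots,
which is what makes predicted log-RR extrapolate log-linearly to unseen
temperatures — a property the projection stage relies on and the test
suite asserts to 1e-9 via second differences. The basis is built from the
truncated-power representation (linearity of the tails holds exactly, not
to rounding), with each column rescaled to order 1 over the knot span so
coefficients are numerically comparable.

*Lag basis.* Natural cubic spline with intercept over lags 0–21 days,
3 interior knots equally spaced on the log-lag scale (≈ 2.1, 4.6, 9.8).
21 days captures both the short heat response and the drawn-out cold
response; both the maximum lag and the knots are configurable.

*Cross-basis.* Entry $(t,(i,j))$ accumulates
$b_i(x_{t-l})\,c_j(l)$ over $l=0..21$, with the exposure basis centred at
a provisional centering temperature (the observed median by default; the
final reference is the MMT, applied at prediction time — centering shifts
predictions by a constant only, which a property test asserts to 1e-10).
The first 21 days carry incomplete lag histories and are excluded from
the likelihood, as is any day with a missing lagged temperature or count.

*Confounder control.* Natural cubic spline of time with 8 df per year
(season and long-term trend) and day-of-week indicators. 8 df/yr is the
established multi-city convention; it is a configuration default, not a
hard-coded truth.

*Estimation.* IRLS via `statsmodels` GLM with a Poisson family; the
quasi-Poisson dispersion is the Pearson chi-square over the residual df
and scales the coefficient covariance. Convergence: relative deviance
change < 1e-8, at most 50 iterations; non-convergence raises. Rank
deficiency raises an error naming the collinear columns rather than
silently aliasing.

*Reduction.* The overall cumulative curve is $\theta = M\beta$,
$V = M\,\mathrm{vcov}(\beta)\,M^\top$, where $M$ sums each exposure
coefficient's lag-basis block over lags 0–21. Test oracles: a per-day,
per-lag double loop for the cross-basis (1e-10) and a lag-by-lag surface
summation for the reduction (1e-8).

## Second stage

Multivariate meta-regression
$\theta_i \sim N(Z_i\gamma, \Psi + V_i)$ estimated by REML. $\Psi$ is
parameterised by its Cholesky factor (always PSD); the profile objective
is minimised by L-BFGS from a moment-based start plus jittered restarts,
and the $\Psi = 0$ boundary is always evaluated as a candidate, so exact
homogeneity collapses to $\Psi = 0$ rather than stalling near it.
Continuous meta-predictors are standardised internally; categorical
predictors are reference-coded with the alphabetically first level as
reference; missing values and exact collinearity are errors. An
independent univariate REML profile-likelihood implementation serves as a
cross-check in the tests at k = 1.

BLUPs:
$\tilde\theta_i = Z_i\hat\gamma + \Psi(\Psi+V_i)^{-1}(\theta_i - Z_i\hat\gamma)$,
with covariance combining the conditional variance
$\Psi - \Psi(\Psi+V_i)^{-1}\Psi$ and the fixed-effect uncertainty. The
interpolation limits ($V_i\to0$ returns the location's own estimate,
$\Psi\to0$ the fixed-effect prediction) are asserted numerically.

## Climate inputs

*Grid linkage.* 0.5°×0.5° cells, half-open intervals
$[w, w+0.5)\times[s, s+0.5)$ with centres at 0.25° offsets; a point on a
west/south edge belongs to that cell. NetCDF-style arrays are handled via
`xarray`; per-location CSV is the fallback.

*Recalibration.* Each series decomposes into (year, month) running means,
a deterministic within-month day-of-year shape (harmonic climatology,
2 harmonics, detrended per month instance), and weather residuals. Per
calendar month, an additive offset aligns the running monthly means with
the observed ones (so the modelled long-term warming trend passes through
untouched — asserted within 1% on the fitted decadal slope) and a
multiplicative factor rescales the weather residuals to the observed
level. The day-of-year shape is taken from the observed series and used
for both estimation and application, which makes the map exactly
idempotent. This is a deliberately simple, trend-preserving variant of
the bias-correction family used for impact modelling; it reproduces the
observed monthly climatology exactly but is not a quantile mapping — the
full distributional shape beyond mean and variance is not corrected, and
a distortion that also rescales the within-month *seasonal shape* is
recovered only approximately. The map type is pluggable.

*Baseline mortality.* Day-of-year average of observed counts, repeated
along 1990–2099. Slots 1–365 use the non-leap calendar; slot 366 is the
mean of observed Feb 29 counts, falling back to the mean of the Feb 28 and
Mar 1 values when no leap day was observed.

## Attribution

MMT: argmin of the BLUP curve on a 0.1 °C grid between the location's
1st and 99th temperature percentiles (bounds configurable), ties broken
toward the lower temperature. Forward attribution: for day $t$,
$af_t = 1 - e^{-\eta(x_t)}$ with $\eta$ centred at the MMT, and
$an_t = af_t \times$ mean expected deaths over days $t..t{+}21$; trailing
days use the truncated window (configurable to drop). Days exactly at the
MMT contribute zero to neither component, so heat + cold = total holds
exactly. A forward window crossing a decade boundary is assigned to the
exposure day's decade. Aggregation is deaths-weighted:
$af = \sum an / \sum \mathrm{deaths}$ across locations and GCMs within
region × decade × RCP, which makes the GCM-ensemble average the one the
total-deaths denominator implies. Decades are calendar decades anchored
at 1990; net change is referenced to 2010–19.

## Monte Carlo eCIs

Curve coefficients for *all* locations are drawn jointly: one shared
fixed-effects draw $g \sim N(0, \mathrm{Var}(\hat\gamma))$ per Monte Carlo
sample plus an independent conditional residual
$e_i \sim N(0, \Psi - \Psi(\Psi+V_i)^{-1}\Psi)$ per location, i.e.
$\theta_i^{(s)} = \tilde\theta_i + (I - \Psi S_i^{-1}) Z_i\, g^{(s)} + e_i^{(s)}$.
The shared draw matters: BLUP errors are strongly correlated across
locations (they inherit the same pooled-curve error), and sampling
locations independently understates the uncertainty of any aggregate.
Each draw is evaluated under every GCM; the 95% eCI is the 2.5th/97.5th
percentile of the pooled draws × GCMs (type-7 linear interpolation, stated
because endpoints depend on it). Point estimates are the ensemble averages
at the BLUP coefficients and are not constrained to lie inside the
empirical bounds. Net-change eCIs difference the statistic within each
(draw, GCM) pair across decades, never the endpoint intervals. Defaults:
S = 1000 draws for the standalone sampler, 250 in the pipeline; seeds
derive from the master seed through a counter scheme.

Two deliberate choices: the MMT is held at its point estimate across
draws — re-minimising within each draw would stack a second
minimum-selection bias on top of the one already present in the point
estimate (percentile intervals double bias rather than cancel it; the
per-draw re-search remains available as an option) — and draws are taken
from the BLUP rather than first-stage covariances, matching the curves
actually used for projection.

## Synthetic-data design

The generator defines the study conditions for every test.

*Temperature.* Sinusoidal annual cycle (peak near day-of-year 200) plus
stationary AR(1) noise; defaults 15 °C mean, 10 °C seasonal amplitude,
3 °C marginal noise SD, lag-1 autocorrelation 0.6 — a mid-latitude
temperate climate. Real calendars with leap days.

*Mortality.* Expected deaths = base rate (30/day, a mid-sized city) × a
sinusoidal seasonal factor (10% amplitude, winter peak — so the seasonal
spline has a real confounder to remove) × exp(lag-weighted cumulative
log-RR). Counts are negative binomial with variance = overdispersion ×
mean (default 1.3), matching the quasi-Poisson variance law, Poisson at
exactly 1. The first 21 days' lag history is padded with the first
observed temperature; those days are excluded from fitting anyway.

*Risk surfaces.* The default U-shape has log-RR 0.30 at 18 °C below the
MMT (21 °C) and 0.40 at 7 °C above it — RR ≈ 1.35 in deep cold and ≈ 1.49
in extreme heat, the order observed in multi-city studies, with the
steeper heat limb. Lag weights decay geometrically (time constant 5 days)
and sum to 1, so the overall cumulative curve equals the base curve.
Multi-location ensembles use a spline-parameterised version of this curve
on a shared knot layout, with lag weights projected into the lag-basis
span: the simulated surface is then exactly representable by the fitted
cross-basis, so recovery tests measure estimation error rather than
approximation error. Location curves differ by a GDP effect on the heat
limb (0.1 log-RR per GDP z-score at the hot reference) plus independent
N(0, sd²) deviations per spline coefficient (default sd 0.02, i.e.
0.002–0.04 log-RR of curve-level spread).

*Pseudo-GCMs.* Each GCM reproduces the observed day-of-year climatology
and reuses the observed weather anomalies inside the observed window
(fresh AR(1) anomalies elsewhere), distorted by an additive offset and a
multiplicative anomaly scale — the injected bias the recalibration must
recover — plus a linear warming ramp anchored so the 2010–19 decadal mean
is unchanged and the 2090–99 mean rises by the scenario's warming.
Default end-of-century warming per pathway (0.6 / 1.7 / 2.3 / 4.1 °C for
RCP2.6/4.5/6.0/8.5) matches the magnitude order of published multi-region
ensemble averages.

*What the generator does not emulate:* real mortality age structure or
cause composition, spatial correlation between locations, GCM physics
(internal variability modes, non-linear regional feedbacks), humidity or
pollution co-exposures, demographic change or adaptation. Passing tests
demonstrate that the pipeline recovers what it models under its own
assumptions; they do not validate those assumptions against real data.

## Study sizes used by the checks

Chosen once as the package's scaled-down study design: curve recovery uses
1 location × 15 years; meta-regression recovery 40 locations × 6 years;
the null-warming check 20 pipeline replicates (4 locations × 5 years,
3 GCMs, zero warming and bias, full 1990–2099 horizon); the eCI
calibration study 200 end-to-end replicates (4 locations × 10 years,
3 unbiased GCMs, zero heterogeneity, horizon 1990–2039, S = 250 draws,
target decade 2030–39) with the truth defined as the generating surface
applied to the realised pseudo-GCM series, weighted by the noiseless
day-of-year baseline. The acceptance script runs the full default pipeline
(6 locations × 10 years, 4 RCPs × 5 GCMs, S = 250).

## Known limitations

- The MMT search inherits minimum-selection bias when curves are noisy;
  with few short series the point attributable fraction is slightly
  biased upward. More locations/years shrink it; the eCI calibration
  study quantifies the net effect on coverage.
- The recalibration corrects means and variances, not full distributions.
- Meta-regression assumes all curves share one basis layout; pooling
  across heterogeneous knot layouts (percentile-scale pooling) is the
  caller's responsibility.
- With very few locations, REML estimates of Ψ sit at the zero boundary
  in a sizeable fraction of replicates; BLUPs then collapse to the pooled
  curve, which is the correct degenerate behaviour but makes
  between-location variance non-identifiable.
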