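# tempmort

Two-stage temperature–mortality modelling and climate-change mortality
projections: distributed lag non-linear models (DLNM) per location,
multivariate meta-regression pooling with best linear unbiased predictions
(BLUPs), recalibration of modelled climate series, forward attribution of
excess deaths to heat and cold, and Monte Carlo empirical confidence
intervals (eCIs) for decadal, scenario-specific projections.

## Who this is for

Environmental epidemiologists and climate-health modellers who want a
tested, reusable implementation of the multi-city projection workflow:
estimate how daily mean temperature relates to daily death counts in many
locations, pool those relationships, and project heat- and cold-related
excess mortality through 2099 under alternative emission pathways
(RCP2.6–RCP8.5) with an ensemble of general circulation models (GCMs).
Because the observational archives this design is usually applied to are
not redistributable, the package ships a first-class synthetic-data module
that emulates them with known ground truth, so every stage of the pipeline
is verifiable end to end.

## The model

**First stage (per location).** Daily deaths $Y_t$ follow a quasi-Poisson
log-linear model

$$\log E[Y_t] = \alpha + \sum_{l=0}^{21} f(x_{t-l}, l) + s(t) + \mathrm{DOW}_t,$$

where $f(x,l)$ is a bidimensional *cross-basis* — a natural cubic spline in
temperature (log-linear beyond the boundary knots, so the curve
extrapolates linearly outside the observed range) tensored with a
natural-spline lag basis over lags 0–21 days — $s(t)$ is a natural cubic
spline of time (8 df/year) absorbing season and trend, and DOW are
day-of-week indicators. The fitted surface is reduced to the *overall
cumulative* exposure–response curve $\theta$ (log relative risk summed over
all lags at constant temperature) with covariance $V$.

**Second stage.** The reduced curves are pooled by multivariate
meta-regression, $\theta_i \sim N(Z_i\gamma,\ \Psi + V_i)$, estimated by
REML with location-level meta-predictors (region, climate class, GDP per
capita, temperature mean/range); BLUPs shrink each location's curve toward
the meta-regression prediction.

**Projection.** Modelled daily temperature (per location × GCM × RCP,
1990–2099) is recalibrated against the observed series month by month
(means matched exactly, within-month weather variability rescaled, warming
trend preserved). Projected mortality is the day-of-year average of
observed counts repeated along the horizon. For each day, the fraction
$1-e^{-\eta(x_t)}$ of the expected deaths over the next 21 days is
attributed to that day's temperature, with $\eta$ the BLUP curve centred
at the minimum-mortality temperature (MMT); contributions split into heat
($x_t>$ MMT) and cold ($x_t<$ MMT) and aggregate into deaths-weighted
GCM-ensemble attributable fractions by region, decade and RCP, with net
change versus 2010–19. eCIs come from joint Monte Carlo draws of all
locations' curve coefficients evaluated under every GCM.

## Worked example

```python
import tempmort as tm

cfg = tm.PipelineConfig(
    master_seed=1,
    n_locations=4, n_years=6,
    rcps={"RCP2.6": 0.6, "RCP8.5": 4.1},   # warming by 2090-99 vs 2010-19 (deg C)
    n_gcms=3, mc_samples=100, formula=(),
)
res = tm.run_pipeline(cfg)
cols = ["grouping", "decade", "rcp_id", "af_heat", "af_cold", "net_change"]
print(res.aggregates.query("decade in ('2010-19','2090-99')")[cols]
      .round(4).to_string(index=False))
```

```
grouping  decade rcp_id  af_heat  af_cold  net_change
   North 2010-19 RCP2.6   0.0398   0.1061      0.0000
   North 2010-19 RCP8.5   0.0442   0.0992      0.0000
   North 2090-99 RCP2.6   0.0469   0.0981     -0.0009
   North 2090-99 RCP8.5   0.1320   0.0566      0.0452
   South 2010-19 RCP2.6   0.0398   0.0900      0.0000
   South 2010-19 RCP8.5   0.0443   0.0833      0.0000
   South 2090-99 RCP2.6   0.0473   0.0822     -0.0004
   South 2090-99 RCP8.5   0.1330   0.0440      0.0493
```

Reading the output: under the strong-warming pathway (RCP8.5) the
heat-attributable fraction in the "North" region grows from 4.4% of deaths
in 2010–19 to 13.2% in 2090–99 while the cold fraction falls from 9.9% to
5.7%; the net change (+4.5 percentage points) means warming increases
total temperature-attributable mortality there. Under the mitigation
pathway (RCP2.6) the net change is slightly negative — the small warming
removes more cold-related deaths than it adds heat-related ones. The
`eci_low`/`eci_high` columns (when `mc_samples >= 2`) bound each fraction
with a 95% empirical CI combining curve-estimation uncertainty and
across-GCM spread.

A command-line interface mirrors the stages:

```bash
tempmort run-all --config config.yaml --out-dir out/   # full chain
tempmort fit --series obs.csv --out curve.json         # one location
tempmort pool --curves c1.json --curves c2.json ... --out-dir pooled/
```

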