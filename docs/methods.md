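# Methods

## The problem

Daily mortality responds not only to the level of ambient temperature but
to its *instability* — swings within a day (diurnal range) and between
neighbouring days. This package implements a two-stage multi-community
time-series analysis of that association, built around a composite
temperature-variability index, and validates every stage on a synthetic
generator with known ground truth (multi-city mortality registries are not
redistributable, so the pipeline ships with its own data-generating
process).

## The TV index

For exposure window 0–k days,

    TV_{0-k}(t) = SD( tmin_{t-j}, tmax_{t-j} : j = 0..k ),

the sample standard deviation (denominator 2(k+1) − 1) of the daily minima
and maxima of the current and the k preceding days. A single-day window
reduces to intraday spread; longer windows add the interday component, so
both sources of variability and their lag structure enter one index.
Conventions that the definition leaves open are configurable and fixed as
follows by default:

* **SD denominator** n − 1 (the usual sample SD);
* **IQR quantiles** linear interpolation ("type 7", the default of most
  statistical environments), used to express effects per community-specific
  interquartile-range increase of TV;
* **missingness**: TV is undefined whenever any constituent tmin/tmax is
  missing — partial windows would deflate the variance silently.

## First stage: community-level quasi-Poisson regression

Per community, daily death counts enter a log-linear model

    log E[Y_t] = α + β·TV_{0-k}(t) + s_time(t; 7 df/yr) + dow(t)
                 + crossbasis(tmean; 4 df × 4 df, 21 lags) [+ rh spline]
                 [+ heat-wave, cold-spell indicators]

estimated by Poisson IRLS with Pearson-χ² dispersion (quasi-Poisson:
identical point estimates, standard errors inflated by √φ̂). The TV term is
linear. The distributed-lag cross-basis controls the non-linear, delayed
main effect of mean temperature: a natural cubic spline over temperature
(internal knots at the 25th/50th/75th percentiles, boundary knots at the
observed range) tensor-multiplied with a natural cubic spline over lag
0–21 days (internal knots at 1.4 and 5.5 days, plus intercept — the
log-spaced placement for a 21-day window). Natural splines use the
truncated-power construction; they are C²-continuous and exactly linear
beyond the boundary knots (asserted numerically in tests).

Reported effect: percent change in mortality per community IQR increase in
TV, 100·(exp(β·IQR) − 1), with Wald 95% CIs computed on the log scale and
exponentiated.

Decisions where the design was genuinely open:

* **Centering** of the temperature basis at the community median tmean; it
  moves only the intercept, which a test asserts.
* **Day-of-week reference** Monday; immaterial to β (tested).
* **Season stratification** uses one interaction model with season main
  effects (moderate reference) *and* season-specific TV slopes, so each
  season's slope is directly interpretable; seasons are the 4 coldest /
  4 hottest / remaining 4 calendar months by long-run monthly mean
  temperature, with a deterministic month-order tie-break.
* **Humidity**, when requested, enters as a 3-df natural spline of same-day
  relative humidity.
* **Heat waves / cold spells**: runs of ≥ 3 consecutive days (duration
  strictly greater than 2) above the community 95th / below the 5th
  percentile of daily mean temperature, computed over the full study
  period.
* **Min+max control** builds two separate cross-bases (tmin and tmax); the
  strong collinearity hazard is logged rather than silently absorbed.
* **Complete-case fitting**: rows with any missing design entry or outcome
  are dropped and counted; the burn-in of the TV window and lag window is
  missing by construction.
* **IRLS convergence** uses a deviance-change tolerance of 1e-6
  (deviances are O(n), so this is far below estimate precision) with a
  hard failure — not a warning — on non-convergence or rank deficiency.

## Granger-style lead-exposure check

Because the future cannot cause the past, regressing today's deaths on the
TV of days t+1..t+lead (all controls kept, lagged TV removed) is a negative
control: systematic non-zero lead coefficients indicate residual
confounding. The package refits the model for each lead 1–7 and reports
coefficient, SE and z per lead.

## Second stage: ML random-effects pooling

Community log effects per IQR, y_i ± se_i, are pooled under
y_i ~ N(μ, se_i² + τ²). (μ, τ²) maximise the marginal likelihood with
τ² ≥ 0; the pooled SE is (Σ 1/(se_i²+τ̂²))^{-1/2}. Maximum likelihood (not
REML, not DerSimonian–Laird) is the primary estimator; REML is an option.
Cochran's Q and I² are reported descriptively. The optimiser is a bounded
1-D search on the τ² profile; tests pin it against a brute-force
profile-likelihood grid (coarse 1e-4 sweep, 1e-6 refinement) and against
`metafor::rma(method = "ML")`.

Pooling groups are countries or climate zones; zones are quartiles of
community annual mean temperature with brackets ≤ 25th (cold), 25–50th
(moderate cold), 50–75th (moderate hot), > 75th (hot). Pooling happens on
the per-IQR log scale because community TV ranges need not overlap; a
per-°C mode exists for sensitivity use.

## The synthetic generator

The generator is the exact generative counterpart of the fitted model:

* **Weather**: tmean = annual sinusoid (amplitude 10 °C, configurable
  phase) + stationary AR(1) noise (ρ = 0.7, innovation SD 2.5 °C); diurnal
  range is Gaussian (mean 8 °C, SD 1.5 °C) with a seasonal component,
  floored at 0.1 °C; tmin/tmax sit symmetrically around tmean. This yields
  TV_{0-1} distributions with IQRs near 1 °C.
* **Mortality**: log-mean = log baseline (default 30 deaths/day, a
  mid-sized city) + β_true·TV + linear trend + seasonal winter excess +
  day-of-week offsets + a U-shaped lagged temperature surface
  (curvature·(T−optimum)² with geometric lag decay over 14 days) —
  the cold-delayed/heat-acute structure the cross-basis exists to control.
* **Overdispersion** φ ≥ 1 via gamma-mixed Poisson with day-specific shape
  μ/(φ−1), giving Var = φ·μ exactly — the generative stand-in for the
  quasi-Poisson variance assumption, which itself specifies no generative
  law. Default φ = 1.3.
* **Ensemble**: community TV slopes drawn N(μ = 0.002, τ = 0.0005 per °C);
  baseline temperatures uniform over 7–27 °C so communities span
  cold-to-hot climates; each community gets its own child seed from a
  `SeedSequence` tree, so a one-community ensemble is bit-identical to the
  composed weather+mortality calls.

What the generator does **not** emulate: spatial correlation between
communities, weather measurement error, seasonally varying temperature
*noise* (winters are no more volatile than summers here), demographic
structure, harvesting/mortality displacement. Passing tests therefore show
estimator correctness under the assumed model class, not robustness to
every feature of real registry data.

## Validation studies and problem sizes

`tvmort.studies` runs the Monte-Carlo validation suite; sizes were chosen
so each check resolves its question at desk scale:

* single-community recovery: 200 replicates × 10 years, true slope
  0.002/°C; bias of the per-IQR percent change vs the closed form
  100·(exp(0.002·IQR)−1) and 95% CI coverage;
* type-I error: 500 replicates × 3 years with slope 0;
* confounding ordering: slope 0 with a strong surface (curvature 1e-3);
  200 paired fits with and without the cross-basis — the unadjusted
  estimate absorbs positive confounding, adjustment shrinks it;
* Granger: 60 × 7 leads well-specified (≈ nominal rejections) and 30
  replicates with an injected *centered* 21-day moving average of TV in
  the log-rate — a slow unmodelled confounder correlated with both past
  and future TV — which must light the lead coefficients up;
* climate-zone pattern: 4 zones × 6 communities × 10 years at 300
  deaths/day. Overlapping TV windows are correlated (ρ ≈ 0.7 between
  the 0–1 and 0–7 windows), so a short-window effect leaks into the
  long-window estimate at ≈ ρ × its per-IQR size; the scenario gives hot
  (short-window) and moderate (long-window) zones equal per-IQR effect
  sizes, making each zone's own window dominate by a (1−ρ) margin that the
  chosen series length and death counts place several MC SEs above noise.

## Known limitations

* The finite spline basis cannot represent the generator's quadratic
  surface exactly (natural splines are linear beyond the boundary knots),
  so a small residual-confounding bias in the TV coefficient survives
  adjustment — visible as an adjusted mean slightly above zero in the
  confounding study and a slight upward tilt in recovery. This mirrors the
  behaviour of spline-based adjustment on real data and is why the
  lead-exposure check exists.
* The dispersion-scaled Wald inference is mildly anticonservative at short
  series lengths (type-I error a point or two above 5%).
* ML τ̂ carries the usual small-k downward bias; REML is available where
  that matters.
* Communities are simulated and fitted independently; no shrinkage of
  first-stage estimates (one-stage hierarchical models are out of scope).
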