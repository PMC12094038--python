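# Methods and design notes

This note documents the statistical procedures, the synthetic-data model,
the defaults and the numerical choices, in the spirit of a model-description
vignette. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Temperature phenotypes

A trace is one cow's 5-min temperature series. QC applies two rules, in
this order: a cow with fewer than 7 distinct recording days is excluded
outright, and otherwise records deviating more than 3 raw-trace standard
deviations from the raw-trace mean are removed in a **single pass** (no
iteration; the mean/SD are those of the raw trace). Single-pass trimming is
not a fixed point for Gaussian noise — removing gross outliers shrinks the
SD, so a second pass would trim a further ~0.2% of records — which is why
the idempotence property is only guaranteed, and only tested, when the bulk
noise is bounded within 3 SD of the mean.

The consistency statistic is ln(100·var) of the deviations of records from
the **cow's trial mean** (denominator n−1). At daily resolution the
deviations are still taken from the trial mean, so a day that is
level-shifted from the cow's norm scores as inconsistent; pass
`daily_baseline="day"` to deviate from the day's own mean instead. A "day"
is a calendar day in station-local time. Zero-variance traces return NaN
with a `ZeroVarianceWarning` rather than −∞.

## Meal analysis

Inter-visit intervals are measured end-of-visit to start-of-next ("separated
by" semantics). Their log10 distribution is fitted with a two-component
Gaussian mixture by maximum likelihood (EM with 8 random restarts,
`reg_covar` 1e−6); components are reported sorted by mean. The meal
criterion is 10^x\* where x\* solves
w₁·φ(x; μ₁, σ₁) = w₂·φ(x; μ₂, σ₂) between the two component means, found by
bracketed root solve (Brent, xtol 1e−12); if one weighted density dominates
everywhere between the means, a `CriterionError` carries the diagnostic.
With more than two components the two longest-interval components are used.
Visits with a gap strictly below the criterion merge into one meal (a gap
exactly equal starts a new meal); meal intake is the sum of visit intakes.
The largest meal per cow-day is the highest-intake meal, ties broken by
earliest start.

The post-meal change anchors the pre-meal window **at or before** the meal
start (the mean of the 3 consecutive records nearest to and not after the
start), avoiding contamination by the meal itself, and centres the
post-meal window on the record nearest to 20 min after the meal end (ties
toward the earlier record). On a 5-min grid with a meal aligned to it, the
two window centres are therefore (meal duration + 25) min apart. Meals
without sufficient trace coverage are skipped with a warning; the cow-level
trait is the mean delta over the largest meals, NaN if none was evaluable.

One pooled criterion is estimated per dataset (the pipeline pools intervals
across cows and stations). Overnight gaps are included among the intervals;
they simply add mass to the long-interval component.

## Energy sinks and RFI

MilkE is evaluated weekly from the printed coefficients
(0.0929, 0.0585, 0.0395 Mcal/kg per percentage point of fat, true protein
and lactose) times milk yield, then averaged over weeks (unweighted). BW is
regressed on day of trial by OLS; unmeasured days take the fitted value and
measured days keep their measurement. Metabolic BW is (mean daily BW)^0.75
— the power applied to the average, the alternative mean(BW^0.75) differs
negligibly over a two-week trial. ΔBW is last-day minus first-day of the
fitted/imputed series.

The RFI design uses an intercept with reference-level (treatment) coding
for DIM class (bins [60+15(k−1), 60+15k) for k = 1..8 and [180, 195] for
k = 9; midpoint DIM outside 60–195 is rejected, not extrapolated),
lactation class (1, 2, 3, 4+) and cohort, plus the three continuous sinks.
Aliased columns are dropped greedily in column order (earlier columns win)
by a Gram–Schmidt rank test with relative tolerance 1e−8, so a duplicated
covariate is dropped, never the original. RFI is the OLS residual;
residuals are invariant to the coding choice.

## Associations

Trial-level models are OLS of an efficiency trait on a temperature trait
plus cohort, the per-cow THI covariate, station, and THI × station. The
station main effect is included whenever the interaction is (hierarchical
convention). Cohorts are nested in stations, so the station main effect is
usually aliased with cohort and dropped with a note — the slope of interest
is unaffected. A zero-variance temperature trait raises `ModelError` rather
than silently dropping the predictor.

Daily models regress daily DMI on the daily temperature trait with cohort,
daily THI and THI × station as fixed effects and a random cow intercept,
fitted by REML (L-BFGS, falling back to Powell, and to pooled OLS — the
limiting model — when the variance component is singular; every fallback
attaches a note). With one record per cow the random intercept is
unidentifiable and pooled OLS is used, with a note.

Partial correlations remove cohort means from both variables (equivalent to
regression on cohort indicators with intercept) and correlate the
residuals; the t test uses n − (#cohorts) − 1 degrees of freedom. Raw
p-values are reported throughout (no multiple-testing correction), two-sided,
with complete-case analysis per trait pair. The adjusted-R² comparison
refits the RFI model with and without a temperature trait on the common cow
subset.

The per-cow THI covariate is the unweighted mean of daily THI at the cow's
station over her recording window padded by 3 d on each side. In synthetic
herds where all cows share one trial window, this covariate is nearly
constant within cohort and can be dropped as aliased; real multi-trial data
spread cohorts over seasons and keep it informative.

## The synthetic herd

The generator emulates the data streams of a multi-station trial; all of
its distributions are artifact choices (no distributional model of real
herds is implied), and its defaults are fixed study conditions:

| parameter | default | rationale |
|---|---|---|
| baseline temperature | 38.7 °C, between-cow SD 0.11 °C | typical core temperature and between-cow spread in mid-lactation Holsteins |
| circadian amplitude | 0.25 °C, peak ~18:00 | within-day structure so variance traits are nontrivial |
| day-level offsets | SD 0.05 °C | whole-day shifts (weather, management) |
| residual noise | SD 0.10 °C; quantization 0.0625 °C | logger noise and sensor precision |
| interval mixture | (w₁ 0.5, μ 0.55/2.30, σ 0.25/0.25) log10 min | analytic criterion ≈ 26.6 min, in the field's tens-of-minutes range |
| post-meal dip | depth 0.40 °C, half-life 60 min | calibrated so the cow-level mean post-meal change sits near −0.27 °C at +20 min; the depth exceeds the observed delta because residual decay from the previous meal also depresses the pre-meal window |
| DMI associations | −2.5 (cow level), −2.3 (day level) kg/d per °C | injected effects the estimators must recover |
| RFI coefficients | b₁ 0.37, b₂ 0.10, b₃ 0.30; σₑ 1.0 kg/d | energy-sink coefficients of realistic magnitude |
| BW schedule | endpoints (3-d blocks at start/middle/end); measurement SD 5 kg | the sparsest realistic schedule, exercising imputation |
| missing days | 2% whole-day dropout | exercises the ≥7-d QC rule |

Temperature traces are latent cow mean + day offset + circadian sinusoid +
per-meal exponential dips (starting at each meal end) + Gaussian noise,
quantized to the sensor step. The post-meal effect is simulated as a *dip*;
the sign is configurable. Missing data are whole-day dropouts only — no
within-day gaps. Weather is per-station AR(1) in temperature and humidity.

Two ordering choices matter for what the estimators estimate. First, daily
DMI is generated from the **measured** daily mean temperature deviations of
the realized trace (visits and trace are simulated first, daily DMI second,
visit intakes last, as duration-proportional shares of the day's DMI), so
the day-level slope the mixed model estimates equals the configured
`dmi_temp_slope_daily`; driving DMI from the latent day offsets instead
would attenuate the estimand by the meal-dip share of daily temperature
variance. Second, cow-level DMI is built from the **observed** energy sinks
(weekly MilkE, the OLS-imputed BW series), so the RFI regression sees
exactly the regressors that generated the data and recovers b₁–b₃ without
errors-in-variables attenuation.

All randomness descends from one master seed through named `SeedSequence`
substreams (per cow and per data stream), so a given cow's data are
invariant to herd size and to unrelated config switches.

What the generator does **not** emulate: heat-stress episodes, estrus or
pregnancy temperature signatures, drinking events, within-day device gaps,
station-specific criterion heterogeneity, or any mechanistic
thermoregulation. Passing tests therefore show that the estimators are
correct and calibrated under a controlled data-generating process of this
shape — not that real herds satisfy that process.

Trace means sit slightly below the latent baseline (the dips are
one-sided, ~0.1 °C at the defaults), and the consistency mean is
correspondingly somewhat above the noise-only value; both are properties of
the simulated physiology, not estimator bias.

## Problem sizes and numerics

Validation studies use the sizes at which their claims are sharp: mixture
recovery at 10⁴ intervals over 20 replicates; RFI recovery on a 500-cow
herd; the trial slope on a 1000-cow herd with a 200-replicate null
calibration run on the generator's cow-level shortcut layer
(`simulate_cow_table`, which emits cow-level phenotypes directly — the
trial regression consumes cow-level data either way); the daily mixed model
on 300 cows × 14 d. Variance computations use n−1 denominators. Exact-zero
variance is detected by range, not by the floating-point variance, so
constant traces yield the NaN sentinel rather than ln of rounding noise.
Dates are ISO-8601; CSVs are UTF-8, comma-separated, "." decimal.

## Known limitations

* The mixture fit assumes exactly two interpretable interval components;
  heavy contamination (e.g. drinking visits) would need the optional
  3-component fit, and the criterion then uses the two longest-interval
  components.
* The daily mixed model fits a random intercept only — no random slopes or
  serial correlation within cow.
* The pipeline estimates one pooled meal criterion; per-station criteria
  are out of scope.
* The QC rules are exactly the two stated filters; no device-failure
  heuristics.
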