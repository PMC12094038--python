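# thermofeed

Body-temperature phenotypes and feed-efficiency associations in lactating
dairy cows — a tested, reusable analysis pipeline with a synthetic herd
generator that provides known ground truth.

## The problem

Mid-lactation cows in feed-efficiency trials carry intravaginal loggers that
record body temperature every 5 minutes for about two weeks, alongside daily
dry matter intake (DMI), milk composition, body weight (BW) and feeder-visit
logs. Thermoregulation is tied to the heat increment of feeding, so
temperature traits are candidate indicators of feed efficiency. This package
implements the full chain from raw trace to association estimate, for
researchers in animal science and biostatistics who want to reuse, audit or
stress-test each step:

* **Temperature phenotypes** — QC (cows with < 7 recording days excluded;
  records beyond 3 SD of the cow's mean removed), then the mean temperature
  and the *consistency* statistic ln(100·var), where var is the variance of
  deviations of 5-min records from the cow's mean, at trial and daily
  resolution.
* **Meal analysis** — the meal criterion estimated by maximum-likelihood
  fitting of a two-component Gaussian mixture to log10 inter-visit
  intervals, taking the weighted-density intersection between the component
  means; visit merging; largest meal of the day; and the post-meal change:
  temperature 20 min after the end of the largest meal minus temperature at
  its start, each the average of 3 consecutive records.
* **Energy and RFI** — milk energy
  `MilkE = (0.0929·fat% + 0.0585·protein% + 0.0395·lactose%) · yield`,
  metabolic BW `(mean BW)^0.75` with OLS imputation of sparse BW schedules,
  ΔBW, and residual feed intake from

  `DMI = DIM + Lact + Cohort + b1·MilkE + b2·mBW + b3·ΔBW + e`

  with 9 DIM classes (15-d bins over 60–195 days in milk), lactation classes
  1/2/3/4+, and cohort = trial-treatment. The residual *e* is the cow's RFI.
* **Environment** — the temperature-humidity index
  `THI = (1.8t + 32) − (0.55 − 0.0055·rh)(1.8t − 26)` and its per-cow mean
  over the recording window ± 3 d.
* **Associations** — trial-level OLS of each efficiency trait on each
  temperature trait (cohort, THI and THI × station adjusted), daily linear
  mixed models with a random cow intercept (REML), partial correlations
  controlling for cohort, and adjusted-R² comparison of RFI models with and
  without temperature traits.
* **Synthetic herd generator** — circadian temperature structure, post-meal
  exponential dips, 0.0625 °C sensor quantization, mixture-driven feeder
  visits, whole-day dropout, sparse BW schedules, station weather, and
  injected temperature–intake associations, all reproducible from one seed
  with the truth stored for validation.

## Worked example

`examples/` holds one short script per capability. For instance the RFI fit
on a 300-cow synthetic herd (`python examples/04_rfi_model.py`) prints:

```
cows in model: 300, design rank: 18
  b[milke] = 0.361 +- 0.013   (generated with 0.37)
  b[mbw] = 0.084 +- 0.008   (generated with 0.1)
  b[delta_bw] = 0.311 +- 0.007   (generated with 0.3)
adjusted R2: 0.91
RFI mean: -7.0e-15 (zero by construction), SD 1.04 kg/d
```

The partial regression coefficients land on the values the herd was
generated with, the residual mean is zero by construction of the OLS fit,
and the residual spread is the between-cow RFI variation. The association
example (`examples/05_associations.py`) likewise recovers the injected
−2.5 kg/d per °C DMI–temperature slope within its standard error, and
`examples/03_meal_criterion.py` recovers the analytic 26.6-min meal
criterion from 10,000 simulated intervals.

The same analyses run file-to-file through a thin CLI:

```bash
thermofeed simulate --out herd/ --seed 1
thermofeed validate herd/
thermofeed run --in herd/ --out results/ --seed 1       # or --criterion 26.4
```

`run` writes every intermediate table (phenotypes, meals, post-meal deltas,
efficiency traits with RFI, THI, associations, partial correlations) plus a
manifest that makes reruns byte-identical.

## Layout

```
src/thermofeed/
  simulate.py      synthetic herd generator (SimConfig, simulate_herd, truth)
  phenotypes.py    trace QC, mean temperature, consistency
  meals.py         interval mixture, meal criterion, merging, post-meal delta
  energy.py        MilkE, BW imputation, mBW, ΔBW, RFI model
  thi.py           temperature-humidity index and window covariate
  association.py   trial OLS, daily mixed models, partial correlations, ΔR²
  pipeline.py      file-based orchestration, validation, manifests
  cli.py           thin click CLI (simulate / validate / run / associate)
docs/methods.md    model and design notes
examples/          narrative scripts, one per capability
```
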