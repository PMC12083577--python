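# movereserve

Diurnal activity quantile curves and penalized scalar-on-function regression
for wrist-worn accelerometry, built to quantify **observable movement
reserve** — a person's capacity to generate and sustain peak physical
activity across the day — and to relate it to clinical disability in
multiple sclerosis (the Expanded Disability Status Scale, EDSS, 0–6.5 in
half-point steps).

Most actigraphy analyses reduce two weeks of minute-epoch activity counts
(AC) to daily averages. That discards exactly the feature that tracks
fatigue-related functional decline: *when* during the day a person can still
produce high-intensity movement. This package instead summarizes each
subject's pooled minute counts within 10-minute time-of-day bins by a family
of distributional metrics — mean, mode, SD, MAD, coefficient of variation,
and the 50th/90th/95th/99th/100th percentiles — yielding per-subject diurnal
curves R_i(s) on s ∈ [0, 24] hours, on the raw (AC) or log (LAC = ln(AC+1))
scale.

Disability is then modeled by scalar-on-function regression (SOFR):

    EDSS_i = α₀ + α₁·age_i + α₂·sex_i + α₃·BMI_i + ∫₀²⁴ β(s) R_i(s) ds + ε_i

with β(s) expanded in cubic B-splines (K = 15), a second-order difference
roughness penalty, and the smoothing parameter chosen by GCV (REML
available). Curve types are compared by their repeated cross-validated R²
(5-fold, 100 random replications, paired fold partitions across metrics),
and each fitted model yields a scalar biomarker per subject,
BM_i = ∫ β̂(s) R_i(s) ds — the disability-relevant content of that
subject's diurnal profile.

Because no minute-level MS cohort is publicly deposited, the package ships a
first-class synthetic cohort generator that emulates the study conditions:
~248 subjects × 14 days × 1440 one-minute epochs, overdispersed
negative-binomial counts around a diurnal profile, night-time zero
inflation, ≥90-minute non-wear runs, DST-shifted days, and an EDSS generated
from the functional model with the signal loading on late-day (16:00–22:00)
upper-tail activity. All pipeline stages — QC (non-wear detection, valid-day
and subject filters, DST normalization), curves, SOFR, evaluation — are
tested against this generator's known ground truth.

## Worked example

Simulate a cohort whose disability signal loads on the late-day upper tail,
run the full pipeline, and compare curve types:

```bash
movereserve run-all --outdir demo --seed 7 --n-subjects 120 --n-days 14 \
    --reps 20 --folds 5 --metrics mean,sd,q50,q95,q100 --scale ac --no-figures
```

prints (elided):

```
metric scale  mean_r2   ci_low  ci_high  k  reps
  mean    AC 0.278535 0.238606 0.320138  5    20
  q100    AC 0.337477 0.296543 0.383543  5    20
   q50    AC 0.236763 0.195104 0.278141  5    20
   q95    AC 0.325163 0.285603 0.366742  5    20
    sd    AC 0.322975 0.281994 0.366446  5    20
```

`mean_r2` is the average held-out R² for predicting EDSS from that diurnal
curve type (adjusted for age, sex, BMI) across 20 random 5-fold partitions,
with a 95% percentile interval. The upper quantiles (q95, q100) beat the
diurnal mean, and the median (q50) trails — peak activity, not typical
activity, carries the disability signal this cohort was built around.
The same partitions are used for every metric, so differences between rows
are paired comparisons. `demo/` additionally contains the QC report, curve
matrices, fitted coefficient functions β̂(s) with 95% bands, per-subject
biomarkers and a hash manifest; re-running with the same seed reproduces
every numeric output byte-for-byte.

The same analysis is available as a library (`movereserve.simulate_cohort`,
`preprocess_cohort`, `curve_matrix`, `fit_sofr`, `metric_comparison`, …);
see `docs/methods.md` for the model, conventions and design choices.

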