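# Methods

This note documents the statistical model, the data conventions, the
synthetic cohort generator, and the numerical and design choices behind
`movereserve`. Everything stated here is either a definition or a property
the test suite computes.

## Data model and preprocessing

Input is minute-epoch activity counts (AC): per subject, J days × 1440
non-negative integers, plus a covariate row (age, sex, BMI, EDSS). The
long-CSV reader tolerates absent rows (missing minutes) and duplicated
(date, minute) rows (a daylight-saving fall-back hour).

Preprocessing applies a fixed rule order:

1. **DST normalization.** A fall (25-hour) day's duplicated hour is averaged
   minute-by-minute; a spring (23-hour) day's missing hour is imputed with
   the same-minute mean over the subject's other days.
2. **Final-hour / residual imputation.** Any remaining missing minute
   (truncated final day, stray gaps) is filled by the same same-minute
   donor-mean rule. Donor minutes that are missing or lie in a donor-day
   non-wear run are excluded from the mean. A minute with no donor raises an
   error naming subject and date.
3. **Non-wear detection.** Any maximal run of ≥ 90 consecutive zero-count
   minutes is device-off. Detection depends only on the zero pattern; runs
   do not continue across midnight (days are processed individually).
   Imputed minutes always count as wear.
4. **Valid-day filter.** A day is valid with ≥ 90% wear time — inclusive, so
   exactly 1296 of 1440 wear minutes qualifies — computed on the full
   imputed day.
5. **Subject filter.** Subjects with fewer than 3 valid days are excluded
   and listed in the QC report with the reason.
6. **Optional log transform** to LAC = ln(AC + 1).

Non-wear minutes are *excluded* from downstream bin pools (treated as
missing), not zero-filled: including device-off zeros would bias every
quantile downward. A sensitivity option (`nonwear_policy='include-as-zero'`)
retains them.

## Diurnal distributional curves

The day is partitioned into S equal bins (default 10 minutes, S = 144). For
subject i and bin s, all wear minutes across all retained days are pooled —
ignoring day and within-bin position — and summarized by one metric:

* **mean**, and **SD** with the pooled denominator JT (population-style;
  a sample-denominator option exists);
* **MAD**: median absolute deviation from the pool median;
* **CV** = SD/mean, defined as 0 whenever mean ≤ c or SD ≤ c. The threshold
  c defaults to 0 and is exposed as an option rather than guessed at;
* **mode**: the most frequent integer AC value, ties to the smallest value;
  on the LAC scale the mode is the transform of the AC mode (the transform
  is a bijection on the integers, so frequencies are preserved);
* **quantiles** q50/q90/q95/q99/q100 via the inverse-empirical-CDF (lower
  order statistic, "type 1") estimator by default, so quantiles are observed
  values and commute exactly with the monotone AC→LAC transform; the
  interpolating "type 7" estimator is available. q100 is the pooled maximum.

Bins left empty by non-wear are filled by linear interpolation on the
circular (across-midnight) bin index and flagged; a subject with more than
half the bins empty is marked invalid and dropped from regression with a
logged reason. Bin midpoints map the curves onto s ∈ (0, 24) hours.

## Scalar-on-function regression

EDSS_i = α₀ + α₁ age + α₂ sex + α₃ BMI + ∫₀²⁴ β(s) R_i(s) ds + ε_i.

* **Discretization.** Midpoint quadrature on the bin midpoints
  (weights = bin width in hours; they sum to 24), giving the functional
  design block F[i,k] = Σ_s w_s R_i(s) B_k(s).
* **Basis/penalty.** Cubic B-splines, K = 15, evenly spaced interior knots
  on [0,24]; second-order difference penalty on the coefficients (null
  space: affine functions). The domain is treated as linear [0, 24], as the
  integral is; a cyclic basis would be a natural extension.
* **Fitting.** Penalized least squares with the scalar block unpenalized;
  λ by GCV over a design-scaled grid (65 points, ¼-decade spacing), REML
  available, or fixed. Columns are internally equilibrated to a unit Gram
  diagonal before solving — the objective is exactly invariant, but without
  it the intercept (scale 1) and AC-scale functional columns (~10⁴) mix at
  condition numbers where even exact identities (e.g. a shift in y moving
  only the intercept) fail in double precision. Degenerate designs fall back
  to a minimum-norm (pseudo-inverse) solution with the cutoff set above
  rounding noise.
* **Uncertainty.** σ² = RSS/(n − edf) with edf = tr[(XᵀX + λP)⁻¹XᵀX]. Two
  coefficient covariances are kept: the frequentist sandwich
  σ²(XᵀX+λP)⁻¹XᵀX(XᵀX+λP)⁻¹, used for Wald tests, and the
  Bayesian/smoothing covariance σ²(XᵀX+λP)⁻¹, used for the pointwise bands
  on β̂(s). The sandwich ignores smoothing bias and its bands undercover
  (across-function coverage 0.70–0.95 in simulation); the smoothing
  covariance restores ≈ 0.91 average coverage at the 95% level (the Nychka
  property). Both are exposed.
* **Inference.** Scalar covariates get Wald z-tests from the sandwich. The
  whole-curve test is b̂ᵀ Cov(b̂)⁻¹ b̂ against χ² with df = K (the rank of
  the sandwich covariance): under the null and a fixed λ the shrinkage
  cancels in the standardization and the statistic is exactly χ²_K, which
  simulation confirms (empirical size 0.040–0.045 at fixed λ). An
  edf-based df option exists but is anti-conservative by construction.
  Because GCV's λ adapts to the noise, GCV-fitted models inflate the test
  (size ≈ 0.072 at n = 500); calibration experiments therefore fit with
  REML (size ≈ 0.055), mirroring the usual REML-for-inference guidance.

## Evaluation

* **Repeated CV.** 5-fold × 100 replications (defaults). Fold assignment
  shuffles the *sorted subject IDs* with a replication-specific generator,
  so partitions are functions of the ID set and seed, never of row order;
  fold sizes differ by at most one. λ is re-selected inside every training
  fold (no leakage). Replication R² pools held-out predictions:
  1 − SSE/SST with the full-sample mean as baseline (a per-fold-averaged
  variant is available). The 95% CI is the 2.5/97.5 percentile interval
  across replications. Within a replication all metrics share the same
  partition, so between-metric contrasts are paired.
* **Biomarkers.** BM_i = Σ_s w_s β̂(s) R_i(s) = F b̂, exactly the functional
  contribution to the fitted value, so predict() ≡ Zα̂ + BM. Stratified
  summaries use configurable EDSS thresholds (4.0 and 6.0 are the
  conventional MS cutpoints).

## The synthetic cohort generator

The generator defines the study conditions; no public generative model for
minute-level MS actigraphy exists, so all of its mechanisms are this
package's stand-ins, chosen for realism and then frozen:

* **Counts.** y ~ NegBin(mean a_i m(t) φ_i(t), dispersion 1.5) with
  structural zeros with probability π(t) (~0.9 in sleep hours, ~0.05
  daytime). m(t) is a smooth two-bump profile peaking midday and early
  evening (~2500 counts/min); a_i is a log-normal subject amplitude
  (SD 0.10); φ_i(t) = exp(Σ harmonics) is a smooth per-subject log-shape
  perturbation (6 harmonics, SD 0.15) — subjects differ in *when* they are
  active, which makes the cohort's curve variation full-rank.
* **Disability mechanism.** A latent severity u_i ~ Beta(2,2) gives a
  damping factor γ_i = 0.7·u_i; inside the 16:00–22:00 window, counts above
  the minute-specific 75th percentile are pulled toward it by the factor
  (1 − γ_i): disability suppresses the *upper tail* of late-day activity and
  leaves typical activity mostly intact.
* **EDSS.** Generated from the functional model with true
  β(s) = −5·10⁻⁴ exp(−½((s−19)/1.4)²) against the latent (noise-free)
  curves of a configurable type (q100-like by default; mean-like available),
  α = (α₀, 0.03, 0.10, 0.01), residual SD 1.2, intercept balanced so EDSS
  centres near 3. Continuous by default for clean parameter recovery; the
  clinical half-point grid with clamping to [0, 6.5] is an option. These
  values land the q100-aligned cohort in a realistic regime (mean-curve CV
  R² ≈ 0.1–0.2, q100 higher, EDSS SD ≈ 1.4).
* **Logistics.** Non-wear: Poisson(0.15/day) episodes of 120 zero minutes;
  DST spring/fall days at the conventional 02:00 hour (configurable); all
  randomness flows from one seed through named streams, and the stored truth
  (β, α, latent curves, noise draws) reconstructs the generated EDSS
  exactly.

**What the generator does not emulate:** day-of-week structure, weather and
season, relapses or longitudinal progression, device-specific count
calibration, autocorrelated within-day behavior beyond the smooth profile,
and missingness that correlates with disability. Tests passing on this
cohort therefore certify the *pipeline's* correctness and calibration, not
clinical performance on real wear data.

**Identifiability caveat used by the validation experiments.** Under the
realistic profile, night activity is ~0 counts, so cohort curves carry
almost no information about β(s) at night; estimation error there reflects
the penalty, not the data, and does not shrink with n. Parameter-recovery
and calibration experiments therefore use an *informative* design
(`informative_diurnal_profile`: night base 400 counts, shape SD 0.3) —
the standard practice for validating a functional estimator. Under it, the
median relative ISE of β̂ is ≈ 0.05–0.11 at n = 300 (low noise) and
decreases monotonically in n under moderate noise.

## Problem sizes in the shipped checks

The test suite and acceptance script size their simulations for a single
CPU: recovery uses 50 replicates at n ∈ {75, 150, 300}; null calibration
uses 100 CV replications at n = 1000 and 300–500 Wald replicates at
n = 500; the ranking experiment uses n = 250 × 14 days with 50–100 paired
CV replications; the demo pipeline runs n = 250 × 14 days, both scales, all
ten metrics, 5-fold × 20 replications.

## Known limitations

* Exact numerical equality with other SOFR implementations (e.g. different
  basis dimensions, penalty parameterizations or centering conventions) is
  not expected; equivalence is qualitative and simulation-based.
* The GCV-based whole-curve Wald test is mildly anti-conservative (see
  above); use REML fits for hypothesis testing.
* β̂(s) is only weakly identified where the cohort's curves barely vary
  (night hours on the AC scale); the wide Bayesian bands there reflect that
  honestly, but point estimates in such regions are penalty-driven.
* The CV threshold c and the quantile estimator are conventions, surfaced
  as options; results for CV-based curves in particular can depend on them.
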