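# Methods

## The prediction model

The model is a fixed closed form, evaluated exactly as written:

```
Qu = 6.06 · [ ((4W + 7)/(W + 90)) · 558 · (1 − Hct) ]^1.01
         · pH^0.07 / ( CPB^0.01 · VIS^0.08 · CVP^0.04 )
```

`Qu` is interpreted as the predicted **total urine volume in mL over the
32-hour window**; this is an inference (the source defines only the rate
conversion `Qu / (W · 32)` in ml/kg/hr), but it is the only reading under
which the derived rates (≈ 2.9 ml/kg/hr at cohort-median covariates) are
plausible against the observed median of 2.59 ml/kg/hr. The bracketed
product — including the `(1 − Hct)` factor — is formed first and then raised
to the 1.01 exponent. All arithmetic is double precision; a property test
checks agreement with an independent log-domain evaluation (sum of
exponent-weighted logarithms) to 1e−9 relative over the valid domain.

Domain: all six covariates strictly positive, hematocrit a fraction in
(0, 1). VIS = 0 is rejected with a dedicated error (the VIS term sits in the
denominator); fractional VIS values are allowed. Hematocrit is stored
internally as a fraction; files and tables carry percent, and the conversion
happens exactly once at ingest — a deliberate single conversion point that
prevents double-division bugs. No coefficient refitting is supported: the
constants are parameterized (`ModelCoefficients`) only so that degenerate
settings can be tested and sensitivity explored.

## Synthetic cohorts

Real patient-level data for this problem cannot be redistributed, so the
validation harness runs on synthetic cohorts whose marginals are calibrated
to the published cohort summaries.

**Covariate marginals.** Each positive skewed covariate (weight, age, CPB
duration, CVP, VIS) is drawn log-normal with location `ln(median)` and scale
`(ln q3 − ln q1)/(2 z₀.₇₅)`, `z₀.₇₅ ≈ 0.67449` — the least-committal
two-parameter fit to a printed (median, IQR) triple. It reproduces the
median and the quartile *ratio* exactly; printed quartile asymmetry beyond
log-normal shape (weight is the notable case) is accepted as approximation.
pH and hematocrit-percent use the symmetric normal analogue. Covariates are
drawn independently; real age–weight correlation is not simulated (a known
limitation, immaterial to formula evaluation and to the validation
mechanics, which never use the joint structure).

Two draws are clipped to physiologic ranges: hematocrit to 5–75 % and
weight to 2–60 kg (term neonates around 2 kg are the smallest children
having bypass surgery). Clipping — rather than resampling — preserves the
fitted median and quartiles. The weight clip matters: the unbounded fitted
log-normal (log-scale ≈ 1.04) would place ~1 % of draws below 0.55 kg, and
because the predicted rate grows steeply as weight falls, those impossible
patients would dominate the cohort's prediction variance and poison the
noise calibration below.

**Observed outcome.** Observed UOP is simulated as
`prediction + bias + ε`, `ε ~ N(0, σ²)`, with negative draws redrawn (not
truncated) so the noise mean stays near zero. The closed form

```
σ = sqrt( (Var(pred) · (1 − R²_target) − bias²) / R²_target ),
bias₀ = median_target − median(pred)
```

follows from `R² = 1 − (bias² + σ²)/(Var(pred) + σ²)` and initializes the
calibration; the target is unattainable when
`Var(pred)·(1 − R²) ≤ bias²`, which is raised as an explicit error (it can
legitimately occur for very small cohorts whose few predictions nearly
coincide). Because the negative-draw resampling truncates the noise's lower
tail — raising the realized median and shrinking the realized noise
variance — the closed form alone misses its own targets (measurably so for
low R² targets). A short damped fixed-point refinement (12 steps) therefore
re-draws the noise, nudges the bias by the remaining median gap (clamped to
±0.5 per step), and rescales σ by the ratio of needed to realized
unexplained variance; at small n, where the median estimate itself is
noisy, the loop stops at the last feasible pair rather than walking out of
the feasible region. All draws flow through the one cohort RNG, so a fixed
seed reproduces the cohort bit for bit. With the default calibration
(R² 0.29, median 2.59 ml/kg/hr) the realized values at n = 10,000, averaged
over 50 seeds, are R² ≈ 0.291 and median ≈ 2.59; targets 0.1 and 0.5
recover to 0.092 and 0.504.

**Exclusion events** are independent Bernoulli flags (pre-operative KRT,
re-operation/ECMO/KRT within 32 h, catheter < 32 h, missing data) with
small default rates (0.5–2 %); the source reports only the post-exclusion
cohort size, so these rates are stated as arbitrary. A `repeat_encounter`
rate (2 %) makes some encounters reuse an earlier patient identifier so the
first-encounter rule is exercised. With the defaults, a 213-encounter draw
retains ~185–190 encounters.

**What passing tests show.** The generator matches the *marginal* summaries
and the two calibration targets. It does not emulate covariate
correlations, longitudinal urine curves, diuretic response, or any real
error structure of the model; green calibration tests certify the harness,
not the model's clinical performance.

## The exclusion filter

A row is removed if any exclusion flag is set, VIS is exactly zero, any
model input is missing or out of domain, or the patient already appeared
earlier in the file (input order is the time proxy; "first encounter only").
Each removed row is counted once, under the first matching reason in the
fixed order: duplicate, pre-op KRT, re-operation, ECMO, KRT, catheter,
VIS-zero, missing data. The filter is idempotent, and
`retained + Σ tally = input` always.

## Validation metrics

- MAE, MedAE (even-length median = midpoint of the central order
  statistics), MSE (divisor n), RMSE = √MSE, and R² as the **coefficient of
  determination** `1 − SSres/SStot` — not squared Pearson correlation. The
  distinction is prominent because the two diverge for biased predictions,
  and this model is biased high at the median; R² may be negative. R² is
  reported as undefined (NaN → null in JSON, "—" in tables) when the
  observed vector is constant.
- **Confidence intervals** come from subsampling: 10 iterations, each
  drawing ⌊n/2⌋ indices *without replacement* (that is what "taking 50 % of
  the data" denotes, as opposed to a bootstrap), recomputing every metric,
  and taking the interpolated 2.5th/97.5th percentiles of the 10 values.
  With 10 draws these percentiles sit near the extremes — intervals are
  wide by construction. Point estimates always come from the full sample
  and intervals are not re-centered. A normal approximation
  (mean ± 1.96·SD) is available behind `ci_method="normal"`.
- **Outliers** use Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR) with quartiles
  by linear interpolation at sorted position `p·(n−1)` — the convention is
  fixed and documented because quartile conventions change flags on small
  samples. Detection applies to the observed UOP values by default
  (`outlier_on="residuals"` switches to residuals).
- **Subgroups**: age < 365 days vs ≥ 365 days (the boundary goes to the
  older group) and STAT category {1, 2} vs {3, 4, 5}. Subgroup interval
  seeds are derived deterministically from the analysis seed (+1 … +4), so
  a report is reproducible end to end. A subgroup too small for the
  procedure (fewer than 2 rows, or a half-sample below 2) is reported with
  its n and undefined metrics.

Table cells are rendered `point (lo–hi)` at two decimals; internal values
are never rounded.

## Numerical and interface choices

- Quantile-fit constant `z₀.₇₅` from `scipy.stats.norm.ppf(0.75)`.
- CSV is the single interchange format: header mandatory
  (order/case-insensitive on read), flags 0/1, floats to 6 significant
  digits on write, unparseable or blank numeric cells load the row with its
  `missing_data` flag set rather than dropping it silently.
- Cohorts of fewer than 4 retained rows get an all-false outlier mask
  (Tukey fences need four points).
- The JSON report round-trips: parsing the rendered document reproduces
  every numeric field exactly (floats serialize via `repr`).
- `predict` (CLI) and `run_validation` treat VIS-0 rows differently by
  design: a prediction tool passes over them with a blank output and a
  warning; a validation run excludes them as the cohort rule requires.

## Problem sizes

Default cohort size is 213 encounters (the reference cohort's size);
fidelity and calibration checks use n = 10,000, and calibration-recovery
checks average 50 seeds at that size — large enough that Monte-Carlo error
is well inside the stated ±0.05 (R²) and ±0.1 (median) bands, and small
enough to keep the full test suite under a minute on one core.

## Known limitations

- Independent marginals: no covariate correlations, so joint-distribution
  features (e.g. subgroup-specific error structure) are not emulated; the
  synthetic subgroup metrics differ only by sampling noise, unlike the real
  study where infants showed systematically worse fit.
- The additive-Gaussian noise model cannot reproduce heteroscedastic or
  skewed error patterns (the real outliers were all under-predictions at
  high observed UOP).
- The per-criterion exclusion rates are invented; only the shape of the
  tally machinery is validated.
- No calibration-slope/intercept or decision-analytic measures; no
  hypothesis tests between subgroups.
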