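# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `telotrack`, in the spirit of a statistical software
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. qPCR quantification (`telotrack.qpcr`)

### Replicate QC

Participant DNA is measured in quadruplicate per assay (telomere, albumin),
controls in triplicate. Two outlier rules are provided:

* `literal_2sd` — exclude a well iff it lies outside the replicate set's own
  mean ± 2 sample SD (ddof = 1). For a replicate set of size n the largest
  attainable |z| with the sample SD is (n−1)/√n — 1.5 for a quadruplicate,
  1.155 for a triplicate — so this rule can never fire on the replicate
  structures used here. It is retained as a selectable policy and its
  vacuity is asserted by brute force in the tests.
* `leave_one_out_2sd` (default) — judge each well against the mean ± 2
  sample SD of the *other* replicates. This detects gross outliers with
  probability ~1 (a planted +7-cycle well is always removed) while keeping
  tight replicate sets intact; wells with fewer than two comparators are
  kept. A sample with fewer than `min_valid` (default 2) surviving wells per
  assay is flagged `rerun_needed`.

Identical replicates are a degenerate case: the leave-one-out SD is 0 and
the exclusion test (strict inequality) keeps every well.

SD convention: sample SD (n−1 denominator) everywhere, including CVs.

### Plate normalization and ΔΔCt

Normalization is multiplicative on the Ct scale, per assay:
`factor = Ct_cal_global / Ct_cal_plate`, `Ct_calibrated = Ct_raw × factor`.
Consequences used as test oracles:

* the calibrator quantifies to exactly the anchor on every plate;
* a Ct *scale* shift confined to one plate cancels exactly when the global
  calibrator reference is held fixed (`global_calibrator_ct` argument);
  when the reference is recomputed from the data the cancellation is exact
  up to the shifted plate's weight in the global mean.

An additive-on-Ct batch effect is *not* exactly cancelled by a
multiplicative factor; the plate simulator therefore applies plate effects
multiplicatively by default (see §2), with an additive mode available for
robustness experiments.

The T/S ratio is defined calibrator-relative as 2^ΔΔCt, which makes the
basepair scale a fixed multiple (anchor, default 5,290 bp) of the T/S
scale. The anchor is a configuration value: it is derived once, externally,
from a reference DNA with known terminal-restriction-fragment calibration,
and is not reproducible from plate data.

Reruns: a sample may appear on several plates; the latest plate (input
order) on which it passed QC wins, and a failed attempt never overwrites an
earlier valid result.

Precision reporting: inter-assay CVs are computed across plates on the
internal control (telomere Ct and absolute TL); intra-assay CVs are
computed within each participant's replicates, and the report carries their
maximum per assay.

## 2. Synthetic cohort generator (`telotrack.cohort`)

The generator emulates the statistical structure a repeat-measurement
telomere study assumes, not any particular population's demography.

Latent model, per participant i:

```
age1_i  ~ U(40, 80)                      gap_i ~ N(9.3, 0.43²) yr, clipped to [7, 12]
TL1*_i  = 5600 − 20·age1_i + b_i         b_i ~ N(0, 700²) bp
attr_i  ~ N(−19.3, 5²) bp/yr             (+ optional lifestyle effect, default 0)
TL2*_i  = TL1*_i + attr_i·gap_i
TLk_i   = TLk*_i + ε_ki                  ε ~ N(0, 500²) bp, independent per exam
```

with a 200 bp positivity floor (so log2(TL/anchor) is always defined) and a
+300 bp batch offset added to all exam-2 measurements, emulating the
storage/isolation drift that the age-recalibration step exists to remove.

Choices and what they imply:

* The defaults give a cross-sectional age slope of −20 bp/yr and a
  closed-form R² = b²·var(age)/(b²·var(age)+σ_b²+σ_m²) ≈ 0.067 —
  within the ~0.08 ballpark reported for general-population cohorts. The
  residual split (between-person 700, measurement 500) implies a
  test–retest reliability of ≈ 0.66 for the measured values.
* Measurement error is additive Gaussian on the basepair scale. Assay
  precision in the wet lab is usually quoted as CVs (multiplicative), but
  the bp-scale keeps every closed form used as a test oracle linear; the
  plate simulator (below) provides the multiplicative route when wells are
  synthesized explicitly.
* Lifestyle is confounded with age and, by default, has **zero** effect on
  true attrition — the null that the longitudinal analyses must respect.
  Gradient sizes are chosen to mirror the quartile gradients typical of
  such cohorts: smoking prevalence +0.6 pp/yr of age, weight +0.25 kg/yr,
  exercise −0.08 h/wk/yr (making inactivity rise steeply with age), alcohol
  age-independent. Exam-2 lifestyle evolves from exam-1 values with
  persistence (25% quit probability for smokers, continued drift for
  continuous covariates).
* A small fraction of covariate cells (0.5%) is set missing so the
  imputation path is always exercised.

**Plate synthesis** inverts the quantification model: albumin Ct at the
calibrator's 15 cycles, telomere Ct placed so that
ΔCt − ΔCt_cal = log2(TL/anchor), per-plate multiplicative Ct effects
(log-scale SD 0.005) and per-well Gaussian noise (SD 0.05 cycles),
quadruplicates for participants and triplicates for the calibrator (TL =
anchor by construction) and internal control (TL = 2,577 bp) on every
plate of 92 participant samples. At zero noise the
synthesize → quantify round trip is the identity to ~1e-15 relative error;
at the default noise the median recovery error is ~4%.

**Registry simulation.** Death times follow a Gompertz hazard from the
second examination, h(t) = h₀·e^{0.09·t}·exp(0.09·(age₂−70) +
0.25·(4300−TL₂*)/1000), h₀ = 0.016/yr — i.e. log-hazard linear in attained
age and in true telomere deficit per kbp — sampled by inversion. These
defaults yield ~19% 8-year mortality at the default age range. Disease
endpoints (cancer, COPD, DM2, ICVD, IHD) get constant per-endpoint hazards
with a mild age gradient, started 15 years before the second examination so
a realistic fraction is prevalent (and excluded downstream, making
per-endpoint n vary slightly as in real registry analyses). Diagnosis
events carry concrete 3-character ICD codes drawn from the endpoint's code
set, ICD-8 before 1994 where the endpoint has ICD-8 codes, ICD-10
otherwise. A small fraction (~0.85%) emigrates, after which the registries
observe nothing for them. All outputs are bit-reproducible for a fixed
seed.

What the generator does **not** emulate — hence what passing tests do not
show about real data: leukocyte subpopulation shifts, assay drift that is
nonlinear in age, lifestyle effects on mortality independent of age,
non-Gaussian telomere distributions, within-plate spatial effects, or any
causal lifestyle→attrition pathway (the default is exactly null by design).

## 3. Longitudinal statistics (`telotrack.longitudinal`)

**Age recalibration.** The published description of the inter-campaign
calibration is procedural prose; the implementation is the minimal
transform satisfying its two stated properties. Fit TL = a + b·age per
examination; replace exam-2 values by `a₁ + b₁·age₂ᵢ + r₂ᵢ` with r₂ᵢ the
participant's exam-2 residual. Then (i) the recalibrated exam-2 regression
on age returns (a₁, b₁) exactly, (ii) the exam-2 residual variance is
untouched, (iii) any batch offset common to exam 2 is absorbed into a₂ and
removed, and (iv) the map is idempotent. A consequence worth stating
plainly: the population-mean annualized change after recalibration equals
the *fitted* exam-1 cross-sectional slope (up to a small 1/gap-weighting
covariance), so the population mean change is not an estimate of mean
attrition independent of the cross-sectional slope — only within-person
contrasts are. The tests assert both the exact identity and the
approximate recovery of the configured attrition (the two differ by
0.7 bp/yr under the defaults).

**Change.** Exact-time scaling: basepair change divided by the calendar-day
gap over 365.25, times 10; percent change relative to baseline. Days come
from date arithmetic; no timezone or leap-second handling.

**Quartilation.** Empirical 25/50/75% quantiles (linear interpolation);
quartile 1 holds the largest values — longest telomeres, or largest gains —
matching the field's labelling convention. A value exactly on a boundary
goes to the lower-numbered quartile, so tied values never split across
quartiles; with 4,576 distinct values the groups are exactly 1,144 each,
and boundary ties perturb group sizes by at most the tie multiplicity.

**Regression dilution ratio.** Extreme-quartile gap at follow-up (baseline
membership held fixed) over the gap at baseline. Two statistics:

* `mean` — for bivariate-normal data the ratio equals r·σ₂/σ₁ exactly
  (conditional means of the truncated-normal quartile groups scale by the
  regression slope); this is the version validated against the closed form.
* `median` (default, matching how such figures display median + IQR) —
  systematically ~10% above r·σ₂/σ₁ under substantial follow-up noise,
  because adding symmetric noise to the *skewed* truncated-quartile
  distribution pulls the group median toward the group mean. The tests pin
  both behaviours.

**Change summary.** Fractions of strictly negative / strictly positive
10-year change, with exact zeros reported separately rather than assigned
to a "middle group"; mean annualized change; extreme 10-year changes.

## 4. Association analyses (`telotrack.association`)

* **Covariate definitions.** Heavy alcohol: strictly above 87.5 g/week
  (women) / 175 g/week (men); one alcohol unit = 12 g. Physical
  inactivity: < 4 h/week of exercise. Boundary values are deliberately
  tested (87.5 g is not heavy; 4.0 h is not inactive).
* **Imputation.** Missing continuous covariates are replaced by predictions
  of an OLS fit on age and sex among complete cases; missing categoricals
  get an explicit `"missing"` level; imputed cells are flagged. This is
  single imputation — appropriate for <1% missingness, not a
  multiple-imputation substitute.
* **Trend tests.** The field's tables report "P for trend" without naming
  the method, so the choice is documented here: continuous covariates use
  the OLS slope on the quartile index (1–4) with its two-sided p; binary
  covariates use the Cochran–Armitage score test with scores 1–4
  (hand-implemented — it is a three-line formula; its type-I error is
  verified at ~α by simulation). Constant covariates return estimate 0,
  p = 1.
* **Change-predictor models.** OLS of 10-year change (bp or %) on the
  standard 10-term predictor set, one at a time or jointly; 95% Wald CIs,
  two-sided p. "Between examinations" exposures are the mean of the two
  examinations' reports (the interim aggregation is not otherwise
  specified; this is an assumption). The baseline-TL coefficient is also
  reported on the T/S scale by multiplying by the anchor, since bp and T/S
  regressors are exactly proportional — fitting both would be collinear,
  and collinear designs are rejected with the offending term named.
* **Endpoints.** ICD matching uses the 3-character category only
  (subcodes inherit), inclusive at both range ends; ICD-8 categories are
  3-digit integers, ICD-10 categories letter + two digits, compared
  lexicographically (well-defined for this fixed format). Unparseable codes
  go to a rejects report instead of aborting. Censor dates per endpoint:
  2011-06-07 (death), 2009-12-31 (cancer), 2011-05-10 (others).
* **Follow-up.** Entry at the second-examination date; exit at the earliest
  of endpoint event, death (censoring, not a competing event — plain
  proportional-hazards semantics), emigration, or the censor date;
  prevalent cases excluded, with the count preserved so that included +
  excluded reconstitutes the cohort. Zero-length intervals are nudged by
  half a day for estimability.
* **Cox models.** lifelines `CoxPHFitter` (Efron ties — appropriate for
  heavily tied registry dates); quartile 1 as reference with HR fixed at
  1.00; the trend p from a separate model with the ordinal quartile score
  as a single covariate; multivariable adjustment uses age, sex, current
  smoking, daily tobacco, BMI, heavy alcohol, and physical inactivity from
  the covariates attached to the follow-up table (exam-2 covariates for
  change-quartile analyses; exam-specific covariates if the caller supplies
  them).
* **Proportional-hazards diagnostic.** −ln(−ln S(t)) vs ln t per group,
  restricted to S ∈ [0.10, 0.90] because the transform's sampling noise
  diverges like 1/(S·ln S) at the extremes; the distance statistic is the
  maximum deviation of a pairwise curve difference from its own median, so
  parallel curves (proportional hazards) score near zero regardless of the
  hazard ratio's size.

## 5. Problem sizes and tolerances

Simulation-backed tests use: n = 20,000 for single-cohort moment checks
(slope within ±1.5 bp/yr, R² within ±0.03), 50 replicate cohorts of
n = 5,000 for null-rejection rates (pooling 400 lifestyle p-values and 300
Cox trend p-values, asserted within ±3 pp of the nominal 5%), n = 10⁵ for
the bivariate-normal closed forms (±0.02), 10⁵ quadruplicates for the QC
vacuity theorem, and 10³ planted outliers for the leave-one-out detection
check. Zero-noise round trips are asserted at 10⁻⁶ relative error
(achieved: ~10⁻¹⁵); algebraic identities (calibrator anchor, reference-
quartile HR, T/S scaling) at machine precision. All random draws flow
through `numpy.random.default_rng` with explicit seeds; the acceptance
script derives every stream from its `--seed` argument.

## 6. Known limitations

* The generator's completer population conditions on surviving to the
  second examination but does not model the selection (collider) process
  explicitly; cross-sectional lifestyle gradients here arise purely from
  age confounding.
* Single imputation, no frailty or competing-risks models, no slope-based
  regression-dilution correction of hazard ratios — matching the analysis
  repertoire the package mirrors, not extending it.
* The multiplicative-on-Ct normalization is taken as printed; an
  additive-on-Ct reading would change plate-effect cancellation properties
  (both behaviours are documented in §1 and the simulator can produce
  either kind of plate effect).
* Absolute telomere lengths inherit the anchor's external calibration; the
  package can only guarantee internal consistency with it.
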