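# Methods

## What this package models

Trauma registries summarise injury severity with additive or model-based
scores and ask how well each score separates patients who die in hospital
from those who survive. `traumascores` implements six such scores and the
full evaluation pipeline used to compare them on a cohort with a heavily
imbalanced outcome (about one death per forty survivors at seven days):
discrimination (AUROC and AUPRC with bootstrap confidence intervals),
correlated-AUC hypothesis tests, clinically motivated cutoffs, and
probability-of-death regression models ranked by cross-validated log loss.

## Score definitions and coding tables

All six calculators are pure functions of the patient record.

* **ISS** — maximum AIS per body region, sum of squares of the three
  largest region maxima. **NISS** — same, but the three largest AIS codes
  regardless of region, so NISS ≥ ISS always. An AIS 6 anywhere forces both
  to 75, the standard convention. Patients with fewer than three injured
  regions contribute zero for the absent terms; a patient with no recorded
  injuries (and no injuries-unknown flag) scores 0. The conventional
  printed lower bound of 1 presumes at least one injury; this package
  admits 0 because a screened-in patient can plausibly have none.
* **RTS** = 0.7326·SBPc + 0.2908·RRc + 0.9368·GCSc on the Champion coded
  bands (GCS 13–15→4, 9–12→3, 6–8→2, 4–5→1, 3→0; SBP >89→4, 76–89→3,
  50–75→2, 1–49→1, 0→0; RR 10–29→4, >29→3, 6–9→2, 1–5→1, 0→0). Maximum
  4·(0.7326+0.2908+0.9368) = 7.8408. Band boundaries are closed as written;
  a recorded SBP of 0 is a valid code-0 input, distinct from missing.
* **MGAP** = raw GCS + mechanism (blunt +4, penetrating +0) + age (<60 +5)
  + SBP (>120 +5, 60–120 +3, <60 +0); range 3–29.
* **KTS** = age (<55→1) + SBP (≥89→2, 50–88→1, <50→0) + RR (10–29→2,
  ≥30→1, <10→0) + AVPU (A→3, V→2, P→1, U→0) + serious injuries (0→2, 1→1,
  ≥2→0); range 0–10. "Serious injury" is operationalised as AIS ≥ 3, the
  conventional serious band; KTS variants differ here and the choice is a
  deliberate, documented one.
* **TRISS** — probability of survival 1/(1+e⁻ᵇ) with mechanism-specific
  coefficients (blunt: b = 0.4499 + 0.8085·RTS − 0.0835·ISS − 1.7430·AgeIdx;
  penetrating: b = 2.5355 + 0.9934·RTS − 0.0651·ISS − 1.1360·AgeIdx), age
  index 0 for 15–54 and 1 for ≥55. Undefined for burn/mixed/unknown
  mechanisms; such patients are screened out upstream.

Orientation: higher ISS/NISS is worse; lower RTS/MGAP/KTS/TRISS is worse.
`to_risk` negates the lower-is-worse scores so every downstream metric sees
a larger-is-worse risk axis; threshold reports restore native units (an
oriented cutoff c on a negated score reads back as "score < −c").

## Eligibility screening

Analysable patients have a blunt or penetrating mechanism and complete GCS,
SBP, RR, AVPU and injury data. Mechanism exclusion is checked first, so a
burn patient with a missing GCS is counted once, as a mechanism exclusion.
"ISS missing" means the injuries-unknown flag is set; an empty injury list
without the flag is a genuine ISS of 0. Screening is idempotent and the
report counts partition the input exactly.

## Synthetic cohort generator

There is no deposited patient-level dataset, so the evaluation pipeline is
exercised on a generator whose defaults encode the published marginal
structure of a large South African trauma registry: 80.9% male, 58.8%
penetrating, 2.5% seven-day mortality, age median 31 (IQR 26–39, log-normal,
floored at 18), and region frequencies led by the extremities (0.470),
head/neck (0.336) and chest (0.327).

A single latent severity z ~ Gamma(2, 1) per patient drives every
correlated quantity:

* injured-region count 1 + min(Poisson(0.3 + 0.3z), 5), regions drawn
  without replacement with probability proportional to the region
  frequencies (Gumbel top-k keys);
* per-injury AIS from a latent 0.55z + N(0, 0.8) cut at
  (1.2, 1.9, 2.6, 3.3, 4.2), so AIS 6 is rare and severe codes concentrate
  in high-z patients;
* GCS = clamp(round(15 − 2.2·max(z−1.5, 0)^1.5 + N(0,1)), 3, 15) — mild
  patients pin at 15, severe patients fall toward 3; AVPU follows the
  standard GCS correspondence (A ≥ 13, V 9–12, P 4–8, U 3);
* SBP = max(round(124 − 6·max(z−1.5, 0)^1.5 + N(0,17)), 0);
* RR = max(round(18 + N(0,3)), 0), deliberately severity-flat: in the
  emulated cohort survivors and non-survivors share an RR median of 18;
* age independent of severity (the emulated cohort's age medians barely
  differ between outcome groups);
* death7 ~ Bernoulli(logistic(a + 1.5z)) with the intercept a calibrated by
  quadrature-plus-root-finding so the marginal mortality hits the 2.5%
  target; death30 = death7 OR Bernoulli(0.004), which lifts 30-day
  mortality to ≈2.9%, the secondary-outcome prevalence implied by the
  all-positive-rule accuracy in the emulated cohort's 30-day table.

The severity slope 1.5 was chosen once as a realistic strong association:
it yields oriented AUROCs in the high 0.85–0.96 band typical of trauma
scores against early mortality, without attempting to reproduce any
specific published AUROC (those are cohort-dependent and not reproducible
without the data). Setting `severity_effect=0` produces a null cohort in
which every score's AUROC is ≈0.5 — used as a negative control in tests.

Determinism: each patient consumes one fixed-width row of a single
row-major uniform stream and all variates are inverse-CDF transforms of
that row, so record i is identical for any cohort size ≥ i+1 at the same
seed. Missingness injection blanks each vital independently with the given
rate (rate 1 is rejected: a fully blank cohort has no analysable patient).

What the generator does not emulate: facility/referral structure,
inter-injury correlation beyond the single factor, time-to-event detail,
measurement error in AIS coding, and the exact joint vital-sign
distribution. Passing tests therefore demonstrate correctness of the
*pipeline* under a realistic imbalanced signal, not clinical performance
claims about real cohorts.

## Discrimination

* AUROC is the Mann–Whitney estimator (ties count ½), computed via
  midranks; it is invariant under strictly increasing transforms and obeys
  AUROC(risk) + AUROC(−risk) = 1.
* AUPRC is step-function average precision with tied scores collapsed into
  blocks (the block's recall increment gets the precision at the block
  end). A constant ranker scores the prevalence; a perfect ranker scores 1.
  Packages that interpolate the PR curve nonlinearly can differ slightly in
  the presence of ties; on tie-free data the estimators coincide, which is
  pinned by a cross-check against scikit-learn in the tests.
* Confidence intervals: stratified percentile bootstrap (positives and
  negatives resampled separately, preserving prevalence; no resample can be
  single-class), default 2,000 replicates, seeded. Replicate count,
  stratification and interval type are package choices; percentile
  intervals on a bounded statistic can be narrow near the boundary.
* DeLong covariance via placement values (structural components), computed
  with the midrank identity in O(N log N) per score; pairwise z-tests are
  two-sided normal. With six scores there are 15 comparisons and the
  Bonferroni per-comparison alpha at family-wise 0.05 is 0.0033; both the
  raw p-values and the significance flags are reported. A pair with zero
  difference variance (identical columns) reports p = 1 with a degenerate
  flag so all-pairs tables are always complete.

## Cutoffs

Candidate cutoffs are midpoints between consecutive distinct risk values
plus ±∞ sentinels; prediction is "death iff risk > cutoff", which yields
half-unit cutoffs for integer scores. The Youden rule maximises Se+Sp−1
with ties broken toward higher sensitivity (conservative for mortality
screening). The sensitivity-floor rule (default 95%) maximises specificity
among qualifying cutoffs; the all-positive sentinel always qualifies, so
when nothing else reaches the floor the report shows Se 100%, Sp 0%,
undefined NPV and accuracy equal to the prevalence — the canonical
behaviour of a score whose worst band contains survivors only.

## Risk models

Each score is modelled alone (no multi-predictor models):

* **logistic** — IRLS, deviance tolerance 1e−8, at most 100 iterations;
  complete separation (vanishing deviance) triggers a warned refit with a
  small ridge (1e−4).
* **spline** — penalised logistic regression on a restricted (natural)
  cubic spline basis, three knots at the 10th/50th/90th percentiles of the
  oriented score, linear in the logit beyond the boundary knots. The ridge
  penalty has base strength 1/n scaled by 2 on the linear and 4 on the
  nonlinear coefficient; a factor for interaction terms is accepted in the
  signature but a single-predictor model has none to apply it to. When the
  percentile knots collide (concentrated discrete scores such as KTS),
  knots move to quantiles of the distinct observed values; fewer than three
  distinct values falls back to logistic with a warning.
* **monotone** — isotonic regression: outcomes at tied scores are
  pre-averaged, pool-adjacent-violators enforces monotonicity, and
  out-of-sample prediction interpolates linearly between block centres
  (weighted mean score per block), clamping outside the observed range.
  This realises the contract "worse score never gets lower predicted
  mortality" as a monotone nonparametric smooth.

Model comparison uses stratified, seeded 5-fold cross-validation with the
same fold split for every family, scored by log loss with probabilities
clipped at 1e−15. The closed-form anchor: a constant predictor at
prevalence π has expected loss −(π ln π + (1−π) ln(1−π)), ≈0.1169 at
π = 0.025.

## Pipeline and reproducibility

`run_pipeline(RunConfig)` chains simulate/read → screen → score →
summarise → discriminate → threshold → model, logging one line per stage
with record counts. A single top-level seed derives per-stage sub-seeds
(generator, bootstrap, CV) through a seed sequence, so identical config and
seed give byte-identical `metrics.json` and each stage can be rerun in
isolation. Group summaries use median (IQR) with tie-corrected rank-sum
p-values (normal approximation, no continuity correction) for continuous
variables and chi-squared without Yates correction for categorical ones;
degenerate variables (constant, or an empty group) carry an absent p-value
rather than an error.

## Problem sizes used in the shipped checks

The shipped test suite exercises the generator at 200,000 patients for
marginal calibration, 50,000 for structural invariants, 20,000 for the
model-comparison grid, and 2,000 replicates of n = 500 for the DeLong
type-I-error simulation — sizes at which binomial Monte-Carlo error is well
inside the asserted bands while the whole suite stays fast on one CPU.

## Known limitations

* The KTS and MGAP coding tables follow one published variant each;
  registries using other variants will disagree by a point or two.
* The AUPRC estimator's tie handling differs from nonlinear-interpolation
  implementations; differences vanish without ties.
* Percentile bootstrap intervals are first-order only; BCa is not
  implemented.
* The generator's single-factor severity cannot reproduce joint features
  such as region-specific mortality gradients (e.g. head injuries being
  disproportionately lethal); only marginal region frequencies are matched.
* TRISS coefficients are the classic published set; no recalibration is
  attempted.
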