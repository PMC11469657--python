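# traumascores

Trauma severity scoring and mortality-prediction evaluation for
patient-level trauma cohorts with rare-death outcomes.

Trauma registries — particularly in low-resource settings — need to know
which injury severity score best identifies the patients who will die in
hospital. This package implements six widely used scores and the complete
statistical pipeline for comparing them on a cohort with a heavily
imbalanced outcome (roughly one death per forty survivors):

* **Scores** — ISS, NISS (anatomical, from per-injury AIS codes), RTS
  (coded physiology: GCS, SBP, RR), MGAP and KTS (additive hybrid triage
  scores), and TRISS (logistic probability of survival,
  Ps = 1/(1+e⁻ᵇ), with separate blunt/penetrating coefficient sets).
* **Discrimination** — AUROC (Mann–Whitney, ties ½) and AUPRC (average
  precision with tied-block handling, the right lens under class
  imbalance), with stratified percentile-bootstrap 95% CIs.
* **Correlated-AUC tests** — all-pairs DeLong comparisons via
  placement-value covariance; with six scores, 15 tests at a Bonferroni
  per-comparison alpha of 0.003 (family-wise 0.05).
* **Cutoffs** — Youden-index and sensitivity-floor (Se ≥ 95%) thresholds
  with Se/Sp/PPV/NPV/accuracy.
* **Risk models** — logistic, natural-cubic-spline (penalised, linear
  tails), and monotone isotonic probability-of-death models per score,
  ranked by stratified 5-fold cross-validated log loss.
* **Synthetic cohorts** — a seeded latent-severity generator whose
  defaults emulate a large South African trauma registry (80.9% male,
  58.8% penetrating, 2.5% seven-day mortality), used to exercise the
  pipeline end to end since real registry data are not redistributable.

See `docs/methods.md` for the coding tables, the generator's model, and
every numerical choice.

## Worked example

Score one patient:

```python
import traumascores as ts

panel = ts.score_panel(ts.PatientRecord(
    patient_id="demo", age=34, sex="male", mechanism="penetrating",
    physiology=ts.PhysiologyAtArrival(gcs=9, sbp=82, rr=24, avpu="V"),
    injuries=[ts.InjuryRecord("chest", 4), ts.InjuryRecord("abdomen", 3),
              ts.InjuryRecord("chest", 2)],
))
print(panel.as_dict())
# {'iss': 25, 'niss': 29, 'rts': 6.1714, 'mgap': 17, 'kts': 6, 'triss': 0.9991}
```

ISS takes the best AIS per region (chest 4, abdomen 3 → 16 + 9 = 25) while
NISS reuses the chest (16 + 9 + 4 = 29). RTS codes GCS 9 → 3, SBP 82 → 3,
RR 24 → 4. TRISS combines RTS, ISS and the age index through the
penetrating-mechanism coefficients: this patient has a 99.9% predicted
survival probability despite serious anatomy, because arrival physiology
dominates the model.

Run the full evaluation on a simulated 20,000-patient cohort:

```python
bundle = ts.run_pipeline(ts.RunConfig(n_patients=20_000, n_boot=500, seed=1))
```

which prints tables like (seed 1):

```
score  AUROC (95% CI)    AUPRC   rule      cutoff  Se    Sp    accuracy
niss   0.93 (0.91-0.94)  0.37    youden    >15     87.3  82.6  82.8
niss                             se_floor  >8.5    95.7  67.5  68.2
kts    0.95 (0.95-0.96)  0.46    youden    <6.5    89.0  91.5  91.4
kts                              se_floor  <8.5    95.5  77.1  77.6
```

Every score discriminates strongly (AUROC 0.93–0.95) while AUPRC stays far
below AUROC — the signature of a rare outcome, where precision is the
binding constraint. The sensitivity-floor row trades specificity for
catching ≥95% of deaths. In the model-comparison grid the monotone or
spline family matches or beats plain logistic for most scores
(e.g. NISS: logistic 0.0735, spline 0.0719, monotone 0.0718 CV log loss),
reflecting the nonlinear relationship between score and mortality.

The same pipeline runs from the shell:

```bash
traumascores simulate --n 20000 --seed 1 --out-dir cohort/
traumascores run --n 20000 --seed 1 --out-dir results/
traumascores run --patients cohort/patients.csv --injuries cohort/injuries.csv \
    --outcome death30 --out-dir results30/
```

`run` writes `metrics.json` plus CSV tables: per-score discrimination and
cutoff metrics, the 15-cell pairwise DeLong matrix, the 6×3 model grid,
survivor/non-survivor summaries, and the eligibility accounting.

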