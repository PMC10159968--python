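# strokemark

Detecting treatment benefit in single-arm stroke registries via the
permutation importance of the reperfusion grade.

## The problem

Randomised trials established endovascular thrombectomy (EVT) for
large-vessel-occlusion stroke, but only for selected patients; real-world
registries contain the patients trials excluded — and no untreated control
arm, so classical treatment-effect estimation is impossible. `strokemark`
implements a surrogate-marker framework for exactly this setting: **if a
group of patients benefits from EVT, the achieved reperfusion grade (final
mTICI score, grouped 0–2a / 2b / 3) should carry information about their
90-day functional outcome; if they do not benefit, it should not.**

Concretely, the package

- trains probabilistic outcome classifiers (gradient boosting, with a
  logistic-regression sensitivity learner) under a fixed protocol —
  outcome-stratified 80/20 split, repeated stratified 5-fold CV with
  within-fold down-sampling, test-set AUC;
- measures the **permutation importance** of mTICI — the drop in AUC when the
  mTICI column is shuffled (100 times; median and 5%/95% quantiles reported)
  — and of treatment *allocation* in two-arm RCT-style data as the reference;
- compares baseline vs baseline+treatment-variable classifiers with
  class-stratified **bootstrap AUC intervals** and the **DeLong test** for
  correlated ROC curves;
- filters registries to trial-like eligibility (age 18–80, onset-to-puncture
  < 12 h, pmRS 0–1; or the basilar proxy age 18–85, OTP < 6 h, pmRS < 3,
  NIHSS > 9) and scans importance across clinical strata (age, vessel,
  NIHSS, OTP, ASPECTS, transfer);
- ships a **synthetic cohort generator** with a latent logistic outcome
  model, per-mTICI-step benefit that can be confined to declarative
  subgroups, a mediated RCT design, configurable adverse events and
  missingness — so the whole chain is validated against known ground truth
  (the real registries this design targets are access-restricted).

Who it is for: methodologists and registry analysts who want a tested,
seeded, end-to-end implementation of the reperfusion-grade-importance
framework, plus the simulation machinery to study when it works.

## Worked example

```python
import strokemark as sm

# registry-style cohort: benefit of 0.5 log-odds per mTICI step, confined to
# trial-eligible patients (age <= 80, OTP < 12 h, pmRS 0-1)
cohort = sm.generate_cohort(sm.make_scenario("rct_like_benefit", n=4000, seed=1))

spec = sm.ModelSpec(learner="glm", cv_repeats=5, seed=1)
base, aug, split = sm.fit_pre_puncture_and_augmented(cohort, spec, "mtici")
print(aug.summary())

cmp = sm.delong_test(base.scored_set("test_split"), aug.scored_set("test_split"))
print(f"AUC {cmp.auc_b:.2f} vs {cmp.auc_a:.2f}, DeLong p = {cmp.p:.4f}")

imp = sm.permutation_importance(aug, "mtici", n_perm=100, seed=1)
print(f"mTICI importance: {imp.median:.3f} [{imp.q05:.3f}, {imp.q95:.3f}]")
```

prints

```
Outcome model summary
=====================
learner:        glm {'C': 1000000.0}
endpoint:       mrs_0_2
features:       age, sex, nihss, pmrs, aspects_band, vessel, otp_min, hypertension, diabetes, dyslipidemia, atrial_fibrillation, smoking, oac, antiplatelet, ivt, general_anesthesia, transfer, high_volume_center, symptom_onset_known, mtici
records (cc):   4000  [train 3200 / test 800]
outcome rate:   0.451
CV protocol:    5 x 5-fold, down-sampling on
mean CV AUC:    0.777
test AUC:       0.778
AUC 0.78 vs 0.77, DeLong p = 0.0088
mTICI importance: 0.008 [0.005, 0.010]
```

Adding the reperfusion grade raises the test AUC from 0.77 to 0.78 (DeLong
p ≈ 0.009), and shuffling it costs the model ~0.008 AUC. In this scenario the
benefit is confined to the trial-eligible minority, so the signal in the
*unselected* registry is diluted — filtering to trial-like criteria
(`strokemark.apply_criteria` with `strokemark.HERMES_LIKE`) concentrates it
and raises the mTICI importance, and the subgroup scan
(`strokemark.pipeline.run_subgroup_scan`) localises it; benchmarking against
allocation importance in RCT-style data marks the cohorts that benefit.

The full three-part analysis (RCT reference, subgroup scan, vertebrobasilar
comparison) runs from the command line:

```bash
strokemark run-all --outdir results/demo --seed 1
strokemark simulate uniform_benefit --n 5000 --seed 1 --out cohort.csv
strokemark importance cohort.csv --n-perm 100
```

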