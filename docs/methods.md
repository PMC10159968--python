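# Methods

`strokemark` implements a framework for asking whether a treatment benefits
patients when only single-arm, real-world data exist. The motivating setting
is endovascular thrombectomy (EVT) for large-vessel-occlusion stroke:
prospective registries record every treated patient's final reperfusion grade
(mTICI, grouped 0–2a / 2b / 3) and 90-day modified Rankin Scale (mRS), but
contain no untreated arm. The framework's premise is that **only in patients
who benefit from treatment should the achieved reperfusion grade carry
information about functional outcome**: the permutation importance of mTICI in
an outcome classifier is therefore used as a surrogate marker of treatment
benefit, benchmarked against the importance of treatment *allocation* in
two-arm RCT-style data, and scanned across clinically defined subgroups.

Because the registry and trial datasets this design targets are
access-restricted, the package ships a synthetic cohort generator with known,
injected benefit structure; every downstream claim is validated against that
ground truth.

## The synthetic cohort generator

One row per patient: age, sex, NIHSS, premorbid mRS, ASPECTS band, occluded
vessel, onset-to-puncture time (OTP, minutes), seven comorbidity/drug flags,
IVT, general anesthesia, interhospital transfer, center volume, known symptom
onset, then allocation (RCT designs), mTICI (treated patients), an
adverse-event flag, and the 90-day mRS.

**Covariate marginals** are loosely calibrated, as documentation-level
defaults rather than fitted targets, to published descriptive statistics of
large thrombectomy cohorts: anterior registry (median age 76, NIHSS 15,
OTP 220 min, mTICI frequencies 15.5/34.9/49.6%), vertebrobasilar registry
(age 75, NIHSS 16, 93.5% basilar occlusions, no ASPECTS — the score is not
assessed in the posterior circulation), and trial-archive populations
(age 68, NIHSS 17, 89.5% thrombolysed). Continuous covariates are drawn from
truncated normals matched to median/IQR (log-normal for OTP, integer
minutes); flags are independent Bernoullis. Covariates are mutually
independent by default; the published tables give marginals only, so no joint
dependence is asserted (an mTICI–baseline link is the one exposed exception,
below).

**Outcome model.** With covariates `x`, effective reperfusion step
`s ∈ {0,1,2}` and adverse-event flag `a`:

    logit P(mRS 0–2) = β₀ + Σₖ βₖ xₖ + benefit(x)·s + π·a

Default coefficients follow the replicated directions of stroke outcome
predictors (per-year age −0.045, per-NIHSS-point −0.10, premorbid mRS −0.45,
ASPECTS band +0.35, IVT +0.25, …) with the intercept set so the marginal
good-outcome rate sits near 0.38 under no benefit, a realistic registry
figure. `benefit(x)` is a sum of subgroup rules (pandas query expression ×
log-odds per mTICI step), so heterogeneity is injected declaratively and the
graded (monotone 0–2a → 2b → 3) action of reperfusion is preserved. The full
ordinal mRS is spread from the binary endpoint by a fixed conditional
multinomial — good → mRS 0/1/2 with probabilities .30/.35/.35, bad →
3/4/5/6 with .35/.25/.20/.20 — so the excellent-outcome endpoint (mRS 0–1)
is exercisable.

**mTICI** is drawn independently of baseline covariates by default (real
cohorts show pre-puncture variables cannot predict the achieved grade). An
optional link tilts a latent score cut at the empirical quantiles matching
the configured grade frequencies, inducing dependence without moving the
marginals. In RCT designs allocation is 1:1; control patients keep their
(counterfactual) grade unobserved and accrue no reperfusion benefit unless
spontaneous-equivalent reperfusion is configured, so allocation acts on
outcome only through reperfusion — the mediation structure the benchmark
rests on.

**Adverse events** are Bernoulli, independent of the grade by default, and
act additively on the log-odds (default −1.0 at probability 0.05). A
per-grade probability override exists solely to construct the counterexample
in which apparent mTICI value is driven by procedure-related harm.

MCAR missingness at a configurable rate applies to ASPECTS and OTP by
default. All randomness flows from one seed through named
`SeedSequence` child streams, one per generation stage, so adding draws to
one stage never perturbs another.

**What the generator does not emulate:** correlated baseline covariates
(e.g. age–NIHSS), informative missingness, site/operator effects, ordinal
outcome structure beyond the fixed conditional spread, and selection into
treatment. Passing tests therefore demonstrate that the analysis chain
recovers the benefit structure *its own model class generates*, not that the
chain is robust to real-world misspecification.

## Cohort selection and strata

Trial-eligibility proxies use the printed bounds with these tie conventions
(the sources never state tie handling, so it is fixed here): age ranges
inclusive at both ends (18–80, 18–85); OTP and NIHSS bounds strict
("< 12 h", "> 9"); premorbid-mRS maxima inclusive. Records missing a
criterion field are excluded (complete-case convention throughout; no
imputation). Built-in stratifications: age at 65 and at 75, vessel
(M1 / M2 / ICA with the carotid terminus collapsed into ICA), NIHSS 0–10 /
11–20 / 21–42 (the middle band is an assumption — only the outer bands are
conventional), fine NIHSS 0–5 / 6–10 / 11–15 / 16–42, OTP ≤/> 360 min,
ASPECTS bands, and transfer status.

## Modeling protocol

Outcome classifiers follow one protocol: outcome-stratified 80/20 train/test
split; hyperparameters chosen by mean validation AUC over repeated stratified
5-fold cross-validation (reference protocol 100 repeats; scaled-down runs are
logged); within every CV fold the training portion is down-sampled to equal
class counts (good outcomes are the minority in registry data) keeping all
minority records; final refit on the down-sampled full training split; the
refit convention (rather than averaging CV fits) is adopted and stated here
because either reading is defensible. Learners: gradient-boosted trees
(primary; small default grid over depth 2–3, shrinkage 0.05–0.1, 100–200
trees) and effectively-unpenalised logistic regression behind a standardiser
(sensitivity learner, and the learner used for the large simulation studies,
where its speed allows hundreds of protocol fits). Ordinal scores (NIHSS,
premorbid mRS, ASPECTS band, mTICI step) enter as numeric; vessel is one-hot
against M1; encodings are a package convention, not a claim about the
original analyses.

## ROC statistics

AUC is the Mann–Whitney probability with mid-rank ties. Confidence intervals
are percentile bootstrap (default 2,000 replicates) with class-stratified
resampling so no replicate is degenerate — a deliberate choice where
unstratified resampling would also have been defensible. Correlated ROC
curves on the same test records are compared with the DeLong
structural-components estimator; a zero-variance difference is flagged
degenerate with p = 1. Raw p-values are reported along with the number of
comparisons made; no multiplicity adjustment is applied.

## Permutation importance

Importance of a variable = baseline AUC minus the AUC after shuffling that
variable's raw column (categorical variables move as one block through the
encoder), model never refit, repeated 100 times by default, summarised as the
median and 5%/95% quantiles (numpy linear interpolation). Negative drops are
retained. Evaluation defaults to the full complete-case dataset, with the
held-out test split as an option. The *marginal* permutation scheme is
implemented; a conditional scheme (permuting within strata of correlated
covariates) needs a conditioning structure that is not defined for this
setting — the `scope`/strategy hooks leave room for one, and with the
generator's independent covariates the two schemes coincide anyway.

**Known limitation — compositional sensitivity.** The AUC drop for a variable
depends on how much competing discrimination the model has, so two strata
with different covariate compositions (say, an age-truncated stratum) yield
systematically different mTICI importance even under perfectly homogeneous
benefit; simulation puts this shift near +0.003 for an M2-and-under-65
stratum against its complement. Subgroup comparisons of importance are
therefore directional evidence, not effect-size comparisons. For calibration
experiments the package uses a sex-restricted benefit scenario
(`subgroup_benefit_female`): sex is generated independently of every other
covariate and has no direct outcome coefficient, making the two strata
exchangeable under homogeneous benefit — a true null.

A second structural fact, measured in the validation suite: a binary
allocation indicator whose effect is fully mediated by reperfusion carries
~16% less score variance than the 3-level graded mTICI with the same
per-step benefit (p(1−p)·(b·E[s])² vs b²·var(s) at the default grade
frequencies), so allocation importance sits slightly but systematically
below mTICI importance even under pure mediation; the two quantile bands
overlap in the large majority of replicates, but the allocation median falls
inside the mTICI band in only ~half of them. The validation suite reports
both rates.

## Pipeline

`run_all` executes: (1) the added-value analysis — allocation in the RCT
cohort, mTICI in the trial-criteria-filtered and the unselected registry,
mTICI in the RCT treated arm, each as a baseline-vs-augmented DeLong
comparison plus a permutation-importance summary; (2) the subgroup scan with
the RCT allocation summary as the reference band (an interpretive choice:
the reference line is that cohort's allocation ImportanceSummary); (3) the
vertebrobasilar analysis with the trial-criteria filter, an importance
profile including IVT, an anterior-vs-vertebrobasilar comparison, and a
stratum scan (age > 75, NIHSS bands, transfer); plus the adverse-event
sensitivity re-fit. Strata below 100 records are skipped with a log entry.
Reports are deterministic functions of the plan and seed and carry a
provenance block (plan hash, seed, package version).

## Problem sizes in the shipped experiments

The validation suite and `scripts/acceptance.py` use cohorts of 4,000–20,000
records, 5 CV repeats, 50–100 permutations, and 50–100 simulation replicates
per experiment — sizes at which the logistic learner completes a protocol fit
in well under a second and each experiment's Monte-Carlo error is small
against the property being checked. The reference protocol values (100 CV
repeats, gradient boosting as primary learner) remain the package defaults
for analyses of a single cohort.
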