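"""Split arithmetic, CV protocol contracts, and learner sanity on known data."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from strokemark import (
    ModelSpec,
    OutcomeModel,
    fit_pre_puncture_and_augmented,
    generate_cohort,
    make_scenario,
    predict_mtici_from_baseline,
)
from strokemark.model import (
    _downsample,
    _stratified_folds,
    default_features,
    design_matrix,
    stratified_split,
)


class TestStratifiedSplit:
    def test_exact_arithmetic_100_records_30_positives(self):
        y = np.repeat([1, 0], [30, 70])
        split = stratified_split(y, 0.20, seed=3)
        assert split.class_counts_test == {0: 14, 1: 6}
        assert split.class_counts_train == {0: 56, 1: 24}

    def test_same_seed_identical_split(self, rng):
        y = (rng.random(200) < 0.3).astype(int)
        a = stratified_split(y, 0.2, seed=9)
        b = stratified_split(y, 0.2, seed=9)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.test_idx, b.test_idx)

    def test_partition_and_per_class_share_odd_sizes(self):
        """Per-class test fraction within one record of nominal for n=57."""
        rng = np.random.default_rng(0)
        for seed in range(50):
            y = np.zeros(57, dtype=int)
            y[rng.choice(57, rng.integers(5, 52), replace=False)] = 1
            split = stratified_split(y, 0.2, seed=seed)
            assert len(np.union1d(split.train_idx, split.test_idx)) == 57
            for c in (0, 1):
                n_c = (y == c).sum()
                n_test = split.class_counts_test[c]
                assert abs(n_test - 0.2 * n_c) <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.ones(30, dtype=int), 0.2, seed=0)


class TestProtocol:
    def test_downsample_balances_and_keeps_minority(self, rng):
        y = np.repeat([0, 1], [80, 20])
        idx = _downsample(y, rng)
        assert (y[idx] == 1).sum() == 20  # every minority record kept
        assert (y[idx] == 0).sum() == 20

    def test_folds_partition_and_stratify(self, rng):
        y = (rng.random(100) < 0.3).astype(int)
        folds = list(_stratified_folds(y, 5, rng))
        assert len(folds) == 5
        all_val = np.sort(np.concatenate([val for _, val in folds]))
        assert np.array_equal(all_val, np.arange(100))
        for train, val in folds:
            assert len(np.intersect1d(train, val)) == 0
            assert 0 < y[val].mean() < 1

    def test_separable_feature_glm_auc_high(self):
        """A single overwhelming predictor yields near-perfect held-out AUC."""
        cohort = generate_cohort(make_scenario("null_benefit", n=2000, seed=21))
        df = cohort.data.copy()
        y = cohort.endpoint()
        df["nihss"] = np.clip(20 - 15 * y + np.arange(len(y)) % 3, 0, 42)
        strong = cohort.__class__(df, "registry", "anterior")
        spec = ModelSpec(learner="glm", cv_repeats=2, seed=5)
        res = OutcomeModel(strong, ["nihss", "age"], spec).fit()
        assert res.test_auc() >= 0.95

    def test_permuted_labels_give_chance_auc(self):
        cohort = generate_cohort(make_scenario("uniform_benefit", n=2000, seed=22))
        rng = np.random.default_rng(1)
        shuffled = rng.permutation(cohort.endpoint())
        spec = ModelSpec(learner="glm", cv_repeats=2, seed=5)
        res = OutcomeModel(cohort, default_features(cohort), spec,
                           target=shuffled).fit()
        assert res.test_auc() == pytest.approx(0.5, abs=0.05)

    def test_seeded_determinism_of_fit(self, uniform_cohort, fast_glm_spec):
        feats = default_features(uniform_cohort) + ["mtici"]
        r1 = OutcomeModel(uniform_cohort, feats, fast_glm_spec).fit()
        r2 = OutcomeModel(uniform_cohort, feats, fast_glm_spec).fit()
        assert np.array_equal(r1.test_scores, r2.test_scores)
        pd.testing.assert_frame_equal(r1.tuning_summary, r2.tuning_summary)

    def test_gbm_learner_runs_and_scores_in_unit_interval(self, uniform_cohort):
        spec = ModelSpec(learner="gbm", cv_repeats=1, seed=5,
                         hyperparameter_grid=(
                             {"n_estimators": 30, "max_depth": 2,
                              "learning_rate": 0.1},))
        res = OutcomeModel(uniform_cohort, ["age", "nihss", "mtici"], spec).fit()
        assert 0.5 < res.test_auc() <= 1.0
        assert np.all((res.test_scores >= 0) & (res.test_scores <= 1))

    def test_glm_parameter_recovery_within_3se(self):
        """Unpenalised logistic refit on the generator's own link."""
        import statsmodels.api as smapi

        cohort = generate_cohort(make_scenario("uniform_benefit", n=10_000, seed=23))
        feats = ["age", "nihss", "pmrs", "mtici"]
        X, cols = design_matrix(cohort.data, feats)
        y = cohort.endpoint()
        ref = smapi.Logit(y, np.column_stack([np.ones(len(y)), X])).fit(disp=0)

        spec = ModelSpec(learner="glm", cv_repeats=1, seed=5, downsample=False,
                         split_fraction=0.5)
        res = OutcomeModel(cohort, feats, spec).fit()
        scaler, logit = res.learner_.named_steps.values()
        recovered = logit.coef_[0] / scaler.scale_
        for j, name in enumerate(cols):
            assert recovered[j] == pytest.approx(ref.params[j + 1],
                                                 abs=3 * ref.bse[j + 1]), name

    def test_minority_smaller_than_folds_rejected(self):
        cohort = generate_cohort(make_scenario("null_benefit", n=60, seed=24))
        df = cohort.data.copy()
        df["mrs90"] = np.r_[np.zeros(3, int), np.full(57, 5)]
        tiny = cohort.__class__(df, "registry", "anterior")
        spec = ModelSpec(learner="glm", cv_repeats=1, seed=5)
        with pytest.raises(ValueError, match="minority"):
            OutcomeModel(tiny, ["age", "nihss"], spec).fit()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            ModelSpec(learner="glm", hyperparameter_grid=())

    def test_scoring_refuses_missing_features(self, uniform_cohort, fast_glm_spec):
        res = OutcomeModel(uniform_cohort, ["age", "nihss"], fast_glm_spec).fit()
        broken = uniform_cohort.data.head(10).copy()
        broken["nihss"] = pd.array([None] * 10, dtype="Int64")
        with pytest.raises(ValueError, match="missing"):
            res.predict_proba(broken)


class TestPairedModels:
    def test_shared_split_contract(self, uniform_cohort, fast_glm_spec):
        base, aug, split = fit_pre_puncture_and_augmented(
            uniform_cohort, fast_glm_spec, "mtici")
        assert np.array_equal(base.split.test_idx, aug.split.test_idx)
        assert np.array_equal(base.split.train_idx, aug.split.train_idx)
        assert "mtici" in aug.feature_list and "mtici" not in base.feature_list

    def test_null_extra_variable_adds_nothing(self):
        cohort = generate_cohort(make_scenario("null_benefit", n=5000, seed=25))
        spec = ModelSpec(learner="glm", cv_repeats=2, seed=6)
        base, aug, _ = fit_pre_puncture_and_augmented(cohort, spec, "mtici")
        assert aug.test_auc() - base.test_auc() == pytest.approx(0.0, abs=0.03)

    def test_informative_extra_variable_raises_auc(self, fast_glm_spec):
        wins = 0
        for rep in range(10):
            cohort = generate_cohort(
                make_scenario("uniform_benefit", n=4000, seed=300 + rep))
            spec = dataclasses.replace(fast_glm_spec, seed=rep)
            base, aug, _ = fit_pre_puncture_and_augmented(cohort, spec, "mtici")
            wins += aug.test_auc() > base.test_auc()
        assert wins >= 9

    def test_unknown_extra_variable_rejected(self, uniform_cohort, fast_glm_spec):
        with pytest.raises(ValueError):
            fit_pre_puncture_and_augmented(uniform_cohort, fast_glm_spec, "nihss")


class TestMticiPrediction:
    def test_chance_level_under_default_generator(self, fast_glm_spec):
        cohort = generate_cohort(make_scenario("null_benefit", n=8000, seed=26))
        out = predict_mtici_from_baseline(cohort, fast_glm_spec, n_boot=200)
        assert set(out) == {"grade_3_vs_rest", "grade_2b3_vs_0_2a"}
        for contrast in out.values():
            assert contrast["auc"] == pytest.approx(0.5, abs=0.04)

    def test_injected_link_detectable(self, fast_glm_spec):
        config = dataclasses.replace(
            make_scenario("null_benefit", n=8000, seed=27),
            mtici_baseline_link={"age": 1.5},
        )
        out = predict_mtici_from_baseline(
            generate_cohort(config), fast_glm_spec, n_boot=200)
        assert out["grade_3_vs_rest"]["auc"] > 0.6

    def test_single_grade_rejected(self, fast_glm_spec):
        cohort = generate_cohort(make_scenario("null_benefit", n=200, seed=28))
        df = cohort.data.copy()
        df["mtici"] = "grade_3"
        degenerate = cohort.__class__(df, "registry", "anterior")
        with pytest.raises(ValueError, match="single"):
            predict_mtici_from_baseline(degenerate, fast_glm_spec)
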