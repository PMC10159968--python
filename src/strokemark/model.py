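"""Probabilistic outcome classifiers under the registry-analysis protocol.

The protocol: stratified 80/20 train/test split, hyperparameter tuning by
repeated stratified k-fold cross-validation with within-fold down-sampling of
the majority class (outcomes are imbalanced), final refit on the down-sampled
training split, evaluation by test-set AUC.  Two learners are provided:
gradient-boosted trees (primary) and a generalized linear model (logistic
regression, sensitivity learner).

The public surface follows the Model/Results convention: build an
:class:`OutcomeModel` from a cohort, call :meth:`~OutcomeModel.fit`, and work
with the returned :class:`OutcomeResults` (test AUC, tuning summary,
``predict_proba`` on new records, ``summary()`` table; permutation importance
hangs off the results object in :mod:`strokemark.importance`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from . import rocstats
from .cohort import PRE_PUNCTURE_FEATURES, TICI_STEP, Cohort

VESSEL_ONEHOT = ("M2", "ICA", "ICA_T", "basilar", "vertebral")  # M1 = reference


def default_gbm_grid() -> tuple:
    """Small tree-boosting grid: depth, shrinkage, and ensemble size."""
    return (
        {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 2,
         "min_samples_leaf": 20},
        {"n_estimators": 200, "learning_rate": 0.05, "max_depth": 3,
         "min_samples_leaf": 20},
    )


def default_glm_grid() -> tuple:
    # effectively unpenalised logistic regression
    return ({"C": 1e6},)


@dataclass(frozen=True)
class ModelSpec:
    """Learner choice and the tuning/evaluation protocol parameters."""

    learner: str = "gbm"                   # {"gbm", "glm"}
    hyperparameter_grid: tuple | None = None   # None -> learner default
    cv_folds: int = 5
    cv_repeats: int = 100
    downsample: bool = True
    split_fraction: float = 0.20
    endpoint: str = "mrs_0_2"              # {"mrs_0_2", "mrs_0_1"}
    seed: int = 0

    def __post_init__(self):
        if self.learner not in ("gbm", "glm"):
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be at least 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie strictly between 0 and 1")
        if self.endpoint not in ("mrs_0_2", "mrs_0_1"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        grid = self.hyperparameter_grid
        if grid is not None and len(grid) == 0:
            raise ValueError("hyperparameter_grid must be non-empty")

    def grid(self) -> tuple:
        if self.hyperparameter_grid is not None:
            return tuple(self.hyperparameter_grid)
        return default_gbm_grid() if self.learner == "gbm" else default_glm_grid()


@dataclass(frozen=True)
class SplitResult:
    """Stratified train/test partition of the complete-case records."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    class_counts_train: dict
    class_counts_test: dict

    def __post_init__(self):
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test indices overlap")


def design_matrix(df: pd.DataFrame, features) -> tuple:
    """Numeric design matrix for the listed raw record variables.

    Encodings: ``sex`` -> female indicator; ``aspects_band`` -> ordinal band
    0/1/2 (low/mid/high); ``vessel`` -> one-hot against M1; ``mtici`` ->
    reperfusion step 0/1/2; ``allocation`` -> EVT indicator; ordinal scores
    (NIHSS, premorbid mRS) and everything else enter as numeric.  Rows must be
    complete on the listed features; a missing value raises.

    Returns ``(X, column_names)`` where categorical expansions keep the raw
    variable name as a prefix so one raw variable maps to a contiguous block.
    """
    cols, names = [], []
    for f in features:
        if f not in df.columns:
            raise ValueError(f"unknown feature {f!r}")
        col = df[f]
        if col.isna().any():
            raise ValueError(f"feature {f!r} has missing values; complete cases only")
        if f == "sex":
            cols.append((col == "female").to_numpy(float))
            names.append("sex=female")
        elif f == "aspects_band":
            cols.append(col.map({"low_0_5": 0.0, "mid_6_8": 1.0,
                                 "high_9_10": 2.0}).to_numpy(float))
            names.append("aspects_ord")
        elif f == "vessel":
            for level in VESSEL_ONEHOT:
                cols.append((col == level).to_numpy(float))
                names.append(f"vessel={level}")
        elif f == "mtici":
            cols.append(col.map(TICI_STEP).to_numpy(float))
            names.append("tici_step")
        elif f == "allocation":
            cols.append((col == "evt").to_numpy(float))
            names.append("allocation=evt")
        else:
            cols.append(pd.to_numeric(col).to_numpy(float))
            names.append(f)
    return np.column_stack(cols), names


def default_features(cohort: Cohort) -> list:
    """Pre-arterial-puncture variables usable in this cohort.

    Drops variables that are entirely missing (e.g. ASPECTS in the posterior
    circulation, where the score is not assessed).
    """
    return [f for f in PRE_PUNCTURE_FEATURES if cohort.data[f].notna().any()]


def stratified_split(y: np.ndarray, split_fraction: float, seed: int) -> SplitResult:
    """Outcome-stratified random split; per-class test share within one record
    of the nominal fraction; seeded-deterministic."""
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cannot split a single-class cohort")
    if counts.min() < 2:
        raise ValueError("need at least 2 records per outcome class")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_test = int(round(len(idx) * split_fraction))
        n_test = min(max(n_test, 1), len(idx) - 1)
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    train = np.sort(np.concatenate(train))
    test = np.sort(np.concatenate(test))
    return SplitResult(
        train_idx=train,
        test_idx=test,
        class_counts_train={int(c): int((y[train] == c).sum()) for c in classes},
        class_counts_test={int(c): int((y[test] == c).sum()) for c in classes},
    )


def _make_learner(spec: ModelSpec, params: dict, random_state: int):
    if spec.learner == "gbm":
        return GradientBoostingClassifier(random_state=random_state, **params)
    # standardising inputs speeds up (and does not materially change) the
    # near-unpenalised logistic fit
    return make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000, **params))


def _downsample(y: np.ndarray, rng) -> np.ndarray:
    """Indices of a class-balanced subsample: every minority record is kept,
    the majority class is subsampled without replacement."""
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def _stratified_folds(y: np.ndarray, k: int, rng):
    """Yield (train, val) index pairs of one shuffled stratified k-fold pass."""
    by_class = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        by_class.append(np.array_split(idx, k))
    for fold in range(k):
        val = np.sort(np.concatenate([parts[fold] for parts in by_class]))
        train = np.sort(np.concatenate(
            [parts[j] for parts in by_class for j in range(k) if j != fold]))
        yield train, val


class OutcomeModel:
    """Binary functional-outcome classifier for one cohort.

    Parameters
    ----------
    cohort : Cohort
    features : sequence of raw record variable names
        Typically :func:`default_features` plus optionally ``"mtici"`` or
        ``"allocation"``.
    spec : ModelSpec
    target : ndarray, optional
        Overrides the endpoint-derived labels (used e.g. to predict the
        reperfusion grade itself from baseline covariates).  Must align with
        the cohort rows; rows incomplete on the features are dropped from both.
    """

    def __init__(self, cohort: Cohort, features, spec: ModelSpec,
                 target: np.ndarray | None = None):
        self.cohort = cohort
        self.features = list(features)
        self.spec = spec
        needed = set(self.features) | ({"mrs90"} if target is None else set())
        complete = cohort.data[sorted(needed)].notna().all(axis=1).to_numpy()
        self.frame = cohort.data.loc[complete].reset_index(drop=True)
        if target is None:
            self.y = (
                Cohort(self.frame, cohort.design, cohort.circulation, cohort.label)
                .endpoint(spec.endpoint)
            )
        else:
            self.y = np.asarray(target)[complete].astype(int)
        if len(self.frame) == 0:
            raise ValueError("no complete-case records for the listed features")
        if len(np.unique(self.y)) < 2:
            raise ValueError("outcome has a single class after complete-case filtering")
        self.X, self.columns = design_matrix(self.frame, self.features)

    def split(self) -> SplitResult:
        seed = int(np.random.SeedSequence(self.spec.seed).spawn(1)[0]
                   .generate_state(1)[0] % (2**31))
        return stratified_split(self.y, self.spec.split_fraction, seed)

    def fit(self, split: SplitResult | None = None) -> "OutcomeResults":
        spec = self.spec
        if split is None:
            split = self.split()
        y_train = self.y[split.train_idx]
        X_train = self.X[split.train_idx]
        if np.bincount(y_train).min() < spec.cv_folds:
            raise ValueError("minority class smaller than the number of CV folds")
        grid = spec.grid()

        ss = np.random.SeedSequence((spec.seed, 1))
        cv_rng = np.random.default_rng(ss.spawn(1)[0])
        learner_seed = int(ss.generate_state(1)[0] % (2**31))

        rows = []
        mean_auc = np.zeros(len(grid))
        fold_aucs = [[] for _ in grid]
        for _rep in range(spec.cv_repeats):
            for tr, val in _stratified_folds(y_train, spec.cv_folds, cv_rng):
                if spec.downsample:
                    tr = tr[_downsample(y_train[tr], cv_rng)]
                for gi, params in enumerate(grid):
                    learner = _make_learner(spec, params, learner_seed)
                    learner.fit(X_train[tr], y_train[tr])
                    s = learner.predict_proba(X_train[val])[:, 1]
                    fold_aucs[gi].append(rocstats.auc(y_train[val], s))
        for gi, params in enumerate(grid):
            mean_auc[gi] = float(np.mean(fold_aucs[gi]))
            rows.append({"params": params, "mean_cv_auc": mean_auc[gi],
                         "n_fits": len(fold_aucs[gi])})
        best = int(np.argmax(mean_auc))

        # final refit on the full training split, down-sampled once
        refit_idx = split.train_idx
        if spec.downsample:
            refit_idx = refit_idx[_downsample(y_train, cv_rng)]
        learner = _make_learner(spec, grid[best], learner_seed)
        learner.fit(self.X[refit_idx], self.y[refit_idx])

        test_scores = learner.predict_proba(self.X[split.test_idx])[:, 1]
        return OutcomeResults(
            model=self,
            learner_=learner,
            best_params=grid[best],
            tuning_summary=pd.DataFrame(rows),
            split=split,
            test_scores=test_scores,
        )


@dataclass
class OutcomeResults:
    """Fitted classifier plus the protocol artifacts needed downstream."""

    model: OutcomeModel
    learner_: object
    best_params: dict
    tuning_summary: pd.DataFrame
    split: SplitResult
    test_scores: np.ndarray

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def feature_list(self) -> list:
        return list(self.model.features)

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        """Probability of the good outcome for complete-case records."""
        X, cols = design_matrix(df, self.model.features)
        if cols != self.model.columns:
            raise ValueError("feature encoding mismatch with the fitted model")
        p = self.learner_.predict_proba(X)[:, 1]
        return p

    def scored_set(self, scope: str = "test_split",
                   origin: str = "") -> rocstats.ScoredSet:
        """Scores/labels on the test split or on the full complete-case data."""
        if scope == "test_split":
            return rocstats.ScoredSet(
                self.test_scores, self.model.y[self.split.test_idx], origin)
        if scope == "full_dataset":
            scores = self.learner_.predict_proba(self.model.X)[:, 1]
            return rocstats.ScoredSet(scores, self.model.y, origin)
        raise ValueError(f"unknown scope {scope!r}")

    def test_auc(self) -> float:
        return rocstats.auc(self.model.y[self.split.test_idx], self.test_scores)

    def test_auc_ci(self, n_boot: int = 2000, level: float = 0.95) -> tuple:
        return rocstats.bootstrap_ci(
            self.model.y[self.split.test_idx], self.test_scores,
            n_boot=n_boot, level=level, seed=self.spec.seed)

    def save(self, path) -> None:
        """Persist the fitted results (pickle container).

        The container embeds the full :class:`ModelSpec` (including the seed),
        the raw feature list and encoded column names, the chosen
        hyperparameters, the split, the fitted learner and the complete-case
        frame, so the artifact is self-describing and re-scoreable.
        """
        import pickle

        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "OutcomeResults":
        import pickle

        with open(path, "rb") as fh:
            results = pickle.load(fh)
        if not isinstance(results, OutcomeResults):
            raise TypeError(f"{path} does not contain a fitted model artifact")
        return results

    def summary(self) -> str:
        s = self.spec
        lines = [
            "Outcome model summary",
            "=====================",
            f"learner:        {s.learner} {self.best_params}",
            f"endpoint:       {s.endpoint}",
            f"features:       {', '.join(self.model.features)}",
            f"records (cc):   {len(self.model.frame)}"
            f"  [train {len(self.split.train_idx)} / test {len(self.split.test_idx)}]",
            f"outcome rate:   {self.model.y.mean():.3f}",
            f"CV protocol:    {s.cv_repeats} x {s.cv_folds}-fold, "
            f"down-sampling {'on' if s.downsample else 'off'}",
            f"mean CV AUC:    {self.tuning_summary['mean_cv_auc'].max():.3f}",
            f"test AUC:       {self.test_auc():.3f}",
        ]
        return "\n".join(lines)


def fit(cohort: Cohort, features, spec: ModelSpec) -> OutcomeResults:
    """Protocol fit: split, tune, down-sample, refit, evaluate."""
    return OutcomeModel(cohort, features, spec).fit()


def fit_pre_puncture_and_augmented(
    cohort: Cohort, spec: ModelSpec, extra_variable: str,
    features: list | None = None,
):
    """Baseline (pre-puncture) and augmented model on the identical split.

    ``extra_variable`` is ``"allocation"`` (RCT cohorts) or ``"mtici"``
    (treated cohorts).  Complete cases are taken on the union of features so
    both models see the same records, and the stratified split is shared.
    Returns ``(baseline_results, augmented_results, split)``.
    """
    if extra_variable not in ("allocation", "mtici"):
        raise ValueError("extra_variable must be 'allocation' or 'mtici'")
    base_features = list(features) if features is not None else default_features(cohort)
    aug_features = base_features + [extra_variable]
    complete = cohort.data[aug_features + ["mrs90"]].notna().all(axis=1).to_numpy()
    shared = cohort.subset(complete, label_suffix="|cc")
    base_model = OutcomeModel(shared, base_features, spec)
    aug_model = OutcomeModel(shared, aug_features, spec)
    split = base_model.split()
    return base_model.fit(split), aug_model.fit(split), split


MTICI_CONTRASTS = {
    "grade_3_vs_rest": lambda m: (m == "grade_3").astype(int),
    "grade_2b3_vs_0_2a": lambda m: m.isin(["grade_2b", "grade_3"]).astype(int),
}


def predict_mtici_from_baseline(cohort: Cohort, spec: ModelSpec,
                                n_boot: int = 500) -> dict:
    """Try to predict the achieved reperfusion grade from baseline covariates.

    Trains one classifier per documented binary mTICI contrast on the
    pre-puncture features and reports the held-out AUC with a bootstrap CI.
    An AUC near 0.5 means baseline covariates carry no information on the
    achieved grade.
    """
    observed = cohort.data["mtici"].dropna()
    if observed.nunique() < 2:
        raise ValueError("cohort has a single observed mTICI level")
    out = {}
    features = default_features(cohort)
    for contrast, make_y in MTICI_CONTRASTS.items():
        y = np.where(cohort.data["mtici"].isna(), np.nan,
                     make_y(cohort.data["mtici"]))
        usable = cohort.subset(~np.isnan(y))
        res = OutcomeModel(
            usable, features, spec, target=y[~np.isnan(y)].astype(int)
        ).fit()
        labels = res.model.y[res.split.test_idx]
        out[contrast] = {
            "auc": res.test_auc(),
            "ci": rocstats.bootstrap_ci(labels, res.test_scores,
                                        n_boot=n_boot, seed=spec.seed),
            "n_test": len(labels),
        }
    return out
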