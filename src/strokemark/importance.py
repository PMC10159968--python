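"""Permutation variable importance for fitted outcome classifiers.

The importance of a variable is the drop in AUC when that variable's column is
randomly shuffled (breaking its association with the outcome and the other
covariates) and the fitted model re-scores the records — the model is never
refit.  Shuffling is repeated (default 100 times) and the distribution of
drops is summarised by its median and 5%/95% quantiles.  Drops may be
negative; they are reported as-is.

The marginal permutation scheme is implemented; a conditional scheme
(shuffling within strata of correlated covariates) would need a conditioning
structure that is not defined here, and the ``strategy`` hook is left for it.

Evaluation defaults to the full complete-case dataset; the held-out test split
is available as an alternative scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rocstats
from .cohort import Cohort
from .model import ModelSpec, OutcomeModel, OutcomeResults, default_features


@dataclass(frozen=True)
class ImportanceSummary:
    """Distribution of performance drops for one permuted variable.

    Quantiles use the default linear interpolation of ``numpy.quantile``.
    """

    variable: str
    baseline_perf: float
    drops: np.ndarray
    median: float
    q05: float
    q95: float
    n_perm: int
    evaluation_scope: str

    @classmethod
    def from_drops(cls, variable, baseline_perf, drops, scope):
        drops = np.asarray(drops, dtype=float)
        return cls(
            variable=variable,
            baseline_perf=float(baseline_perf),
            drops=drops,
            median=float(np.median(drops)),
            q05=float(np.quantile(drops, 0.05)),
            q95=float(np.quantile(drops, 0.95)),
            n_perm=len(drops),
            evaluation_scope=scope,
        )

    def band_overlaps(self, other: "ImportanceSummary") -> bool:
        """Do the 5-95% quantile bands of the two summaries overlap?"""
        return self.q05 <= other.q95 and other.q05 <= self.q95


def _scope_arrays(results: OutcomeResults, scope: str):
    model = results.model
    if scope == "full_dataset":
        return model.frame, model.y
    if scope == "test_split":
        idx = results.split.test_idx
        return model.frame.iloc[idx].reset_index(drop=True), model.y[idx]
    raise ValueError(f"unknown scope {scope!r}")


def permutation_importance(results: OutcomeResults, variable: str,
                           n_perm: int = 100, seed: int = 0,
                           scope: str = "full_dataset") -> ImportanceSummary:
    """Permutation importance of one raw record variable.

    For each of ``n_perm`` seeded shuffles the variable's raw column is
    permuted, the design matrix rebuilt (so a categorical variable moves as
    one block), the fitted model re-scores every record in scope, and
    ``drop = baseline AUC - permuted AUC`` is recorded.
    """
    if variable not in results.feature_list:
        raise ValueError(f"variable {variable!r} is not a model feature")
    if n_perm < 2:
        raise ValueError("n_perm must be at least 2")
    frame, y = _scope_arrays(results, scope)
    baseline = rocstats.auc(y, results.predict_proba(frame))

    rng = np.random.default_rng(seed)
    work = frame.copy()
    original = frame[variable].to_numpy()
    drops = np.empty(n_perm)
    for k in range(n_perm):
        work[variable] = original[rng.permutation(len(original))]
        permuted_auc = rocstats.auc(y, results.predict_proba(work))
        drops[k] = baseline - permuted_auc
    return ImportanceSummary.from_drops(variable, baseline, drops, scope)


def importance_profile(results: OutcomeResults, n_perm: int = 100, seed: int = 0,
                       scope: str = "full_dataset") -> list:
    """One ImportanceSummary per model feature, sorted by median drop
    (descending).  Each variable gets its own child seed; negative medians are
    legal and sort last."""
    children = np.random.SeedSequence(seed).spawn(len(results.feature_list))
    summaries = [
        permutation_importance(
            results, var, n_perm=n_perm,
            seed=int(ss.generate_state(1)[0] % (2**31)), scope=scope)
        for var, ss in zip(results.feature_list, children)
    ]
    return sorted(summaries, key=lambda s: s.median, reverse=True)


def adverse_event_sensitivity(cohort: Cohort, spec: ModelSpec,
                              features: list | None = None,
                              variable: str = "mtici",
                              n_perm: int = 100, seed: int = 0,
                              scope: str = "full_dataset") -> dict:
    """Reperfusion-grade importance with and without adverse-event patients.

    Fits the same model specification on the full cohort and on the cohort
    excluding records with an adverse event during the procedure, computes the
    permutation importance of ``variable`` in both, and reports whether the
    5-95% quantile bands overlap.  If the treatment grade matters only through
    procedure-related harm, exclusion collapses its importance; if it reflects
    genuine benefit, the importance is stable.
    """
    flags = cohort.data["adverse_event"]
    if flags.isna().all():
        raise ValueError("cohort has no adverse_event information")
    if (flags.fillna(0) == 1).all():
        raise ValueError("every record has an adverse event; nothing to compare")
    feats = list(features) if features is not None else default_features(cohort)
    if variable not in feats:
        feats = feats + [variable]

    def one(sub: Cohort) -> ImportanceSummary:
        res = OutcomeModel(sub, feats, spec).fit()
        return permutation_importance(res, variable, n_perm=n_perm,
                                      seed=seed, scope=scope)

    full = one(cohort)
    no_ae = one(cohort.subset((flags.fillna(0) != 1).to_numpy(),
                              label_suffix="|no_adverse"))
    return {
        "full": full,
        "without_adverse_events": no_ae,
        "bands_overlap": full.band_overlaps(no_ae),
    }


def importance_table(summaries) -> "pd.DataFrame":
    """Tidy table (variable, median, q05, q95, n_perm, scope) for reporting."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "variable": s.variable,
                "baseline_auc": s.baseline_perf,
                "median_drop": s.median,
                "q05": s.q05,
                "q95": s.q95,
                "n_perm": s.n_perm,
                "scope": s.evaluation_scope,
            }
            for s in summaries
        ]
    )
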