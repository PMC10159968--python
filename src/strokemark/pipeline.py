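"""End-to-end orchestration of the three registry-benefit analyses.

1. **Added value of reperfusion level** — allocation importance and
   baseline-vs-augmented ROC comparison in RCT-style data; the same for the
   reperfusion grade (mTICI) in an RCT-criteria-filtered and in an unselected
   registry; mTICI importance in the RCT treated arm.
2. **Subgroup scan** — mTICI importance across clinical strata of a registry,
   side by side with the RCT allocation reference band.
3. **Vertebrobasilar analysis** — trial-criteria filtering, added-value
   comparison, importance profile including thrombolysis (IVT), an
   anterior-vs-vertebrobasilar comparison of mTICI and IVT importances, and a
   vertebrobasilar stratum scan.

Every number in a report is a deterministic function of the plan (scenarios,
criteria, strata, model spec, seed); reports carry a provenance block with the
plan hash and seed.  Raw DeLong p-values are reported together with the number
of comparisons made.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import Cohort, read_cohort, write_cohort
from .importance import (
    ImportanceSummary,
    adverse_event_sensitivity,
    importance_table,
    permutation_importance,
)
from .model import (
    ModelSpec,
    OutcomeModel,
    default_features,
    fit_pre_puncture_and_augmented,
)
from .rocstats import RocComparison, delong_test
from .selection import (
    BASICS_LIKE,
    HERMES_LIKE,
    SelectionCriteria,
    apply_criteria,
    builtin_strata_by_name,
    stratify,
)
from .simulate import generate_cohort, make_scenario

logger = logging.getLogger(__name__)


@dataclass
class AnalysisPlan:
    """Everything needed to reproduce one full analysis run."""

    #: scenario name (or path to a cohort CSV) per cohort role
    rct: str = "rct_mediated"
    registry_anterior: str = "rct_like_benefit"
    registry_vb: str = "vb_ivt_dominant"
    n_per_cohort: int = 4000
    anterior_criteria: SelectionCriteria = HERMES_LIKE
    vb_criteria: SelectionCriteria = BASICS_LIKE
    strata: tuple = ("age_65", "vessel_group", "nihss_wide", "otp_360",
                     "aspects_bands")
    vb_strata: tuple = ("age_75", "nihss_wide", "transfer")
    spec: ModelSpec = field(
        default_factory=lambda: ModelSpec(learner="glm", cv_repeats=5))
    n_perm: int = 100
    scope: str = "full_dataset"
    min_stratum_size: int = 100
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.spec.cv_repeats < 100:
            logger.info(
                "scaled-down run: cv_repeats=%d (reference protocol uses 100)",
                self.spec.cv_repeats,
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["anterior_criteria"] = dataclasses.asdict(self.anterior_criteria)
        d["vb_criteria"] = dataclasses.asdict(self.vb_criteria)
        for crit in ("anterior_criteria", "vb_criteria"):
            va = d[crit]["vessel_allowed"]
            d[crit]["vessel_allowed"] = sorted(va) if va else None
        return d

    def provenance(self) -> dict:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return {
            "plan_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "seed": self.seed,
            "version": __version__,
        }


@dataclass
class AnalysisReport:
    """Collected tables from one run, traceable to the plan."""

    plan: AnalysisPlan
    sections: dict = field(default_factory=dict)
    logs: list = field(default_factory=list)

    def provenance(self) -> dict:
        return self.plan.provenance()


def _stage_seed(plan: AnalysisPlan, stage: str) -> int:
    h = hashlib.sha256(f"{plan.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _load_role(plan: AnalysisPlan, role: str) -> Cohort:
    ref = getattr(plan, role)
    if ref.endswith(".csv") or "/" in ref:
        return read_cohort(ref)
    config = make_scenario(ref, n=plan.n_per_cohort,
                           seed=_stage_seed(plan, f"cohort:{role}"))
    return generate_cohort(config)


def _spec_for(plan: AnalysisPlan, stage: str) -> ModelSpec:
    return dataclasses.replace(plan.spec, seed=_stage_seed(plan, f"spec:{stage}"))


def _roc_row(label: str, comparison: RocComparison) -> dict:
    return {
        "cohort": label,
        "auc_baseline": comparison.auc_a,
        "ci_baseline_lo": comparison.ci_a[0],
        "ci_baseline_hi": comparison.ci_a[1],
        "auc_augmented": comparison.auc_b,
        "ci_augmented_lo": comparison.ci_b[0],
        "ci_augmented_hi": comparison.ci_b[1],
        "delta": comparison.delta,
        "z": comparison.z,
        "p": comparison.p,
        "n_boot": comparison.n_boot,
    }


def _added_value_one(cohort: Cohort, plan: AnalysisPlan, stage: str,
                     extra_variable: str):
    """Baseline vs augmented comparison plus the extra variable's importance."""
    spec = _spec_for(plan, stage)
    base, aug, _split = fit_pre_puncture_and_augmented(cohort, spec, extra_variable)
    comparison = delong_test(
        base.scored_set("test_split", origin=f"{stage}:baseline"),
        aug.scored_set("test_split", origin=f"{stage}:augmented"),
        n_boot=plan.n_boot,
        seed=_stage_seed(plan, f"boot:{stage}"),
    )
    imp = permutation_importance(
        aug, extra_variable, n_perm=plan.n_perm,
        seed=_stage_seed(plan, f"perm:{stage}"), scope=plan.scope)
    return comparison, imp


def run_added_value(plan: AnalysisPlan, rct: Cohort | None = None,
                    registry: Cohort | None = None) -> dict:
    """Analysis 1: is the treatment variable worth adding to baseline models?"""
    rct = rct if rct is not None else _load_role(plan, "rct")
    registry = (registry if registry is not None
                else _load_role(plan, "registry_anterior"))

    roc_rows, importances = [], {}

    comparison, imp = _added_value_one(rct, plan, "rct_allocation", "allocation")
    roc_rows.append(_roc_row("rct", comparison))
    importances["rct_allocation"] = imp

    filtered = apply_criteria(registry, plan.anterior_criteria)
    comparison, imp = _added_value_one(
        filtered, plan, "registry_filtered_mtici", "mtici")
    roc_rows.append(_roc_row("registry_filtered", comparison))
    importances["registry_filtered_mtici"] = imp

    comparison, imp = _added_value_one(
        registry, plan, "registry_full_mtici", "mtici")
    roc_rows.append(_roc_row("registry_full", comparison))
    importances["registry_full_mtici"] = imp

    evt_arm = rct.subset((rct.data["allocation"] == "evt").to_numpy(),
                         label_suffix="|evt_arm")
    spec = _spec_for(plan, "rct_evt_mtici")
    feats = default_features(evt_arm) + ["mtici"]
    res = OutcomeModel(evt_arm, feats, spec).fit()
    importances["rct_evt_mtici"] = permutation_importance(
        res, "mtici", n_perm=plan.n_perm,
        seed=_stage_seed(plan, "perm:rct_evt_mtici"), scope=plan.scope)

    return {
        "roc_comparisons": pd.DataFrame(roc_rows),
        "importance": importances,
        "importance_table": importance_table(importances.values()).assign(
            cohort=list(importances.keys())),
        "n_comparisons": len(roc_rows),
    }


def run_subgroup_scan(plan: AnalysisPlan, registry: Cohort | None = None,
                      rct_reference: ImportanceSummary | None = None,
                      strata_names: tuple | None = None,
                      variable: str = "mtici") -> dict:
    """Analysis 2: treatment-grade importance across clinical strata."""
    registry = (registry if registry is not None
                else _load_role(plan, "registry_anterior"))
    catalogue = builtin_strata_by_name()
    names = strata_names if strata_names is not None else plan.strata
    skipped, rows, summaries = [], [], {}
    for name in names:
        stratum = catalogue[name]
        if stratum.variable not in registry.data.columns:
            raise ValueError(f"stratum variable {stratum.variable!r} unknown")
        if registry.data[stratum.variable].isna().all():
            skipped.append({"stratum": name, "label": "(all)", "n": 0,
                            "reason": "variable entirely missing"})
            continue
        for label, sub in stratify(registry, stratum):
            if len(sub) < plan.min_stratum_size:
                logger.info("skipping stratum %s=%s with %d records (< %d)",
                            name, label, len(sub), plan.min_stratum_size)
                skipped.append({"stratum": name, "label": label, "n": len(sub),
                                "reason": "below minimum size"})
                continue
            spec = _spec_for(plan, f"scan:{name}:{label}")
            feats = default_features(sub) + [variable]
            res = OutcomeModel(sub, feats, spec).fit()
            imp = permutation_importance(
                res, variable, n_perm=plan.n_perm,
                seed=_stage_seed(plan, f"perm:scan:{name}:{label}"),
                scope=plan.scope)
            summaries[(name, label)] = imp
            rows.append({
                "stratum": name, "label": label, "n": len(sub),
                "variable": variable, "median_drop": imp.median,
                "q05": imp.q05, "q95": imp.q95,
                "baseline_auc": imp.baseline_perf,
            })
    table = pd.DataFrame(rows)
    if rct_reference is not None and len(table):
        table["rct_reference_median"] = rct_reference.median
        table["rct_reference_q05"] = rct_reference.q05
        table["rct_reference_q95"] = rct_reference.q95
    return {"table": table, "summaries": summaries, "skipped": skipped}


def run_vb_analysis(plan: AnalysisPlan, vb: Cohort | None = None,
                    anterior: Cohort | None = None) -> dict:
    """Analysis 3: vertebrobasilar stroke — reperfusion grade vs thrombolysis."""
    vb = vb if vb is not None else _load_role(plan, "registry_vb")
    anterior = (anterior if anterior is not None
                else _load_role(plan, "registry_anterior"))

    roc_rows, importances = [], {}
    comparison, imp = _added_value_one(vb, plan, "vb_full_mtici", "mtici")
    roc_rows.append(_roc_row("vb_full", comparison))
    importances["vb_full_mtici"] = imp

    filtered = apply_criteria(vb, plan.vb_criteria)
    comparison, imp = _added_value_one(filtered, plan, "vb_filtered_mtici", "mtici")
    roc_rows.append(_roc_row("vb_filtered", comparison))
    importances["vb_filtered_mtici"] = imp

    # full importance profile (includes IVT among the pre-puncture variables)
    from .importance import importance_profile

    spec = _spec_for(plan, "vb_profile")
    feats = default_features(vb) + ["mtici"]
    res = OutcomeModel(vb, feats, spec).fit()
    profile = importance_profile(res, n_perm=plan.n_perm,
                                 seed=_stage_seed(plan, "perm:vb_profile"),
                                 scope=plan.scope)

    # anterior vs vertebrobasilar: one row per variable per circulation
    comparison_rows = []
    for circulation, cohort in (("anterior", anterior), ("vertebrobasilar", vb)):
        spec = _spec_for(plan, f"circ:{circulation}")
        feats = default_features(cohort) + ["mtici"]
        res_c = OutcomeModel(cohort, feats, spec).fit()
        for var in ("mtici", "ivt"):
            imp_c = permutation_importance(
                res_c, var, n_perm=plan.n_perm,
                seed=_stage_seed(plan, f"perm:circ:{circulation}:{var}"),
                scope=plan.scope)
            comparison_rows.append({
                "circulation": circulation, "variable": var,
                "median_drop": imp_c.median, "q05": imp_c.q05,
                "q95": imp_c.q95,
            })

    scan = run_subgroup_scan(plan, registry=vb, strata_names=plan.vb_strata)

    return {
        "roc_comparisons": pd.DataFrame(roc_rows),
        "importance": importances,
        "profile": profile,
        "profile_table": importance_table(profile),
        "circulation_comparison": pd.DataFrame(comparison_rows),
        "stratum_scan": scan,
        "n_comparisons": len(roc_rows),
    }


def run_all(plan: AnalysisPlan) -> AnalysisReport:
    """Run the three analyses plus the adverse-event sensitivity check."""
    rct = _load_role(plan, "rct")
    registry = _load_role(plan, "registry_anterior")
    vb = _load_role(plan, "registry_vb")

    report = AnalysisReport(plan=plan)
    added = run_added_value(plan, rct=rct, registry=registry)
    report.sections["added_value"] = added
    report.sections["subgroup_scan"] = run_subgroup_scan(
        plan, registry=registry,
        rct_reference=added["importance"]["rct_allocation"])
    report.sections["vb"] = run_vb_analysis(plan, vb=vb, anterior=registry)
    report.sections["adverse_sensitivity"] = adverse_event_sensitivity(
        apply_criteria(registry, plan.anterior_criteria),
        _spec_for(plan, "adverse_sensitivity"),
        n_perm=plan.n_perm,
        seed=_stage_seed(plan, "perm:adverse_sensitivity"),
        scope=plan.scope,
    )
    report.sections["cohorts"] = {"rct": rct, "registry_anterior": registry,
                                  "registry_vb": vb}
    return report


def write_report(report: AnalysisReport, outdir) -> None:
    """Emit delimited tables plus a human-readable summary (report.txt)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for role, cohort in report.sections.get("cohorts", {}).items():
        write_cohort(cohort, outdir / f"cohort_{role}.csv")

    added = report.sections["added_value"]
    vb = report.sections["vb"]
    roc = pd.concat([added["roc_comparisons"], vb["roc_comparisons"]],
                    ignore_index=True)
    roc.to_csv(outdir / "roc_comparisons.csv", index=False)
    added["importance_table"].to_csv(outdir / "importance_added_value.csv",
                                     index=False)
    report.sections["subgroup_scan"]["table"].to_csv(
        outdir / "importance_subgroups.csv", index=False)
    vb["profile_table"].to_csv(outdir / "importance_vb_profile.csv", index=False)
    vb["circulation_comparison"].to_csv(
        outdir / "importance_circulation.csv", index=False)
    vb["stratum_scan"]["table"].to_csv(outdir / "importance_vb_subgroups.csv",
                                       index=False)

    sens = report.sections["adverse_sensitivity"]
    prov = report.provenance()
    lines = [
        "Registry treatment-benefit analysis",
        "===================================",
        f"plan hash: {prov['plan_hash']}   seed: {prov['seed']}   "
        f"version: {prov['version']}",
        "",
        "ROC comparisons (baseline vs + treatment variable); raw two-sided "
        f"DeLong p-values, {added['n_comparisons'] + vb['n_comparisons']} "
        "comparisons in total:",
        roc.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        "",
        "Treatment-variable importance (AUC drop; median [q05, q95]):",
    ]
    for name, imp in {**added["importance"], **vb["importance"]}.items():
        lines.append(
            f"  {name:28s} {imp.median:+.4f} [{imp.q05:+.4f}, {imp.q95:+.4f}]"
            f"  baseline AUC {imp.baseline_perf:.3f}"
        )
    lines += [
        "",
        "Adverse-event sensitivity (mTICI importance, RCT-like registry):",
        f"  full cohort:            {sens['full'].median:+.4f} "
        f"[{sens['full'].q05:+.4f}, {sens['full'].q95:+.4f}]",
        f"  without adverse events: {sens['without_adverse_events'].median:+.4f} "
        f"[{sens['without_adverse_events'].q05:+.4f}, "
        f"{sens['without_adverse_events'].q95:+.4f}]",
        f"  quantile bands overlap: {sens['bands_overlap']}",
        "",
        "Subgroup scan (mTICI importance per stratum):",
        report.sections["subgroup_scan"]["table"].to_string(
            index=False, float_format=lambda v: f"{v:.4f}"),
    ]
    skipped = report.sections["subgroup_scan"]["skipped"]
    if skipped:
        lines.append("skipped strata: " + "; ".join(
            f"{s['stratum']}={s['label']} (n={s['n']}, {s['reason']})"
            for s in skipped))
    (outdir / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
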