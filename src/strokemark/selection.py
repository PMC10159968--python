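"""RCT-style eligibility filtering and clinical subgroup stratification.

Boundary semantics follow the printed trial criteria: age ranges are inclusive
at both ends ("18-80 years"), onset-to-puncture limits are strict upper bounds
("< 12 h"), NIHSS minima are strict lower bounds ("> 9"), and premorbid-mRS
limits are inclusive maxima ("0 or 1", "< 3" -> at most 2).  Records missing a
criterion field are excluded (complete-case convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionCriteria:
    """Eligibility bounds in the style of thrombectomy RCT inclusion criteria."""

    name: str
    age_range: tuple | None = None        # (min, max), both inclusive
    otp_max_min: float | None = None      # strict upper bound, minutes
    pmrs_max: int | None = None           # inclusive maximum
    nihss_min: int | None = None          # strict lower bound ("greater than")
    vessel_allowed: frozenset | None = None

    def __post_init__(self):
        if self.age_range is not None:
            lo, hi = self.age_range
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError("age_range: need finite min <= max")


#: anterior-circulation trial eligibility proxy: age 18-80 years,
#: onset-to-puncture < 12 h, premorbid mRS 0 or 1
HERMES_LIKE = SelectionCriteria(
    name="hermes_like", age_range=(18, 80), otp_max_min=720.0, pmrs_max=1
)

#: basilar-occlusion trial eligibility proxy: age 18-85 years,
#: onset-to-puncture < 6 h, premorbid mRS < 3, NIHSS > 9
BASICS_LIKE = SelectionCriteria(
    name="basics_like", age_range=(18, 85), otp_max_min=360.0, pmrs_max=2,
    nihss_min=9,
)

BUILTIN_CRITERIA = {c.name: c for c in (HERMES_LIKE, BASICS_LIKE)}


def apply_criteria(cohort: Cohort, criteria: SelectionCriteria) -> Cohort:
    """Return the sub-cohort satisfying every bound; order preserved.

    The input cohort is not modified.  Records with a missing value in any
    field the criteria reference are excluded.
    """
    df = cohort.data
    keep = pd.Series(True, index=df.index)
    if criteria.age_range is not None:
        lo, hi = criteria.age_range
        keep &= df["age"].notna() & df["age"].between(lo, hi)
    if criteria.otp_max_min is not None:
        keep &= df["otp_min"].notna() & (df["otp_min"] < criteria.otp_max_min)
    if criteria.pmrs_max is not None:
        keep &= df["pmrs"].notna() & (df["pmrs"] <= criteria.pmrs_max)
    if criteria.nihss_min is not None:
        keep &= df["nihss"].notna() & (df["nihss"] > criteria.nihss_min)
    if criteria.vessel_allowed is not None:
        keep &= df["vessel"].notna() & df["vessel"].isin(criteria.vessel_allowed)
    return cohort.subset(keep.to_numpy(), label_suffix=f"|{criteria.name}")


@dataclass(frozen=True)
class StratumDefinition:
    """Partition of a covariate into labelled bins.

    Numeric bins are ``(label, lower, upper)`` with both bounds inclusive;
    categorical bins are ``(label, frozenset_of_levels)``.  Bins must be
    pairwise disjoint; at stratification time every observed non-missing value
    must fall into exactly one bin.
    """

    variable: str
    bins: tuple
    source: str = ""   # the clinical convention the cutpoints follow

    @property
    def categorical(self) -> bool:
        return isinstance(self.bins[0][1], frozenset)

    def __post_init__(self):
        if not self.bins:
            raise ValueError("bins: need at least one bin")
        if self.categorical:
            seen = set()
            for _, levels in self.bins:
                if levels & seen:
                    raise ValueError("bins: categorical bins overlap")
                seen |= levels
        else:
            ordered = sorted(self.bins, key=lambda b: b[1])
            for (l1, lo1, hi1), (l2, lo2, hi2) in zip(ordered, ordered[1:]):
                if hi1 >= lo2:
                    raise ValueError(f"bins: {l1!r} and {l2!r} overlap")
            for label, lo, hi in self.bins:
                if lo > hi:
                    raise ValueError(f"bins: {label!r} has lower > upper")

    def assign(self, values: pd.Series) -> pd.Series:
        """Bin label per record (None where the value is missing)."""
        labels = pd.Series([None] * len(values), index=values.index, dtype=object)
        if self.categorical:
            for label, levels in self.bins:
                labels[values.isin(levels)] = label
        else:
            v = pd.to_numeric(values, errors="coerce")
            for label, lo, hi in self.bins:
                labels[v.between(lo, hi)] = label
        uncovered = labels.isna() & values.notna()
        if uncovered.any():
            examples = sorted(set(values[uncovered].head(5)))
            raise ValueError(
                f"stratum {self.variable!r}: observed values not covered by "
                f"any bin: {examples}"
            )
        return labels


def stratify(cohort: Cohort, stratum: StratumDefinition) -> list:
    """Split a cohort into ``(label, sub_cohort)`` pairs, one per bin.

    Records with a missing stratification value are dropped with a logged
    count.  The returned sub-cohorts are pairwise disjoint and their
    concatenation equals the non-missing input.  Empty strata are returned
    (flagged by their zero length) so downstream fits can refuse explicitly.
    """
    if stratum.variable not in cohort.data.columns:
        raise ValueError(f"unknown stratification variable {stratum.variable!r}")
    values = cohort.data[stratum.variable]
    n_missing = int(values.isna().sum())
    if n_missing:
        logger.info(
            "stratify(%s): dropped %d records with missing %s",
            cohort.label, n_missing, stratum.variable,
        )
    labels = stratum.assign(values)
    out = []
    for bin_spec in stratum.bins:
        label = bin_spec[0]
        mask = (labels == label).to_numpy()
        out.append((label, cohort.subset(mask, label_suffix=f"|{label}")))
    return out


def builtin_strata() -> list:
    """The stratifications used in the subgroup importance scans.

    Each definition documents the clinical convention its cutpoints follow.
    Ages are capped at 120 and onset-to-puncture times at 10,000 min, beyond
    any observable value.
    """
    return [
        StratumDefinition(
            "age",
            (("<65", 0, 64), ("65+", 65, 120)),
            source="meta-analysis age subgroup: younger than 65 years",
        ),
        StratumDefinition(
            "age",
            (("<75", 0, 74), ("75+", 75, 120)),
            source="vertebrobasilar / M2 age subgroup: older than 75 years",
        ),
        StratumDefinition(
            "vessel",
            (
                ("M1", frozenset({"M1"})),
                ("M2", frozenset({"M2"})),
                ("ICA", frozenset({"ICA", "ICA_T"})),
            ),
            source="three-way vessel comparison; ICA and ICA-T collapsed",
        ),
        StratumDefinition(
            "nihss",
            (("0-10", 0, 10), ("11-20", 11, 20), ("21-42", 21, 42)),
            source=("severity bands: lower (0-10) vs higher (21-42); the "
                    "middle band 11-20 is an assumption, not a quoted cut"),
        ),
        StratumDefinition(
            "nihss",
            (("0-5", 0, 5), ("6-10", 6, 10), ("11-15", 11, 15), ("16-42", 16, 42)),
            source="fine NIHSS bands for the low-severity comparison",
        ),
        StratumDefinition(
            "otp_min",
            (("<=360", 1, 360), (">360", 361, 10000)),
            source="onset-to-puncture: longer than 360 min",
        ),
        StratumDefinition(
            "aspects_band",
            (
                ("9-10", frozenset({"high_9_10"})),
                ("6-8", frozenset({"mid_6_8"})),
                ("0-5", frozenset({"low_0_5"})),
            ),
            source="ASPECTS bands high/middle/low",
        ),
        StratumDefinition(
            "transfer",
            (("direct", frozenset({0})), ("transferred", frozenset({1}))),
            source="direct admission vs interhospital transfer",
        ),
    ]


def builtin_strata_by_name() -> dict:
    """Named lookup for configs and the command line."""
    defs = builtin_strata()
    names = ("age_65", "age_75", "vessel_group", "nihss_wide", "nihss_fine",
             "otp_360", "aspects_bands", "transfer")
    return dict(zip(names, defs))
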