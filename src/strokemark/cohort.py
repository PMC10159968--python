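"""Patient-level cohort container and delimited-text I/O.

A cohort is one row per patient undergoing (or randomised to) endovascular
thrombectomy, with pre-arterial-puncture covariates, the treatment variable
(RCT allocation or the final mTICI reperfusion grade), an adverse-event flag
and the 90-day modified Rankin Scale (mRS) outcome.  Two designs are
distinguished: ``registry`` (single-arm real-world data, every patient treated,
mTICI observed) and ``rct`` (two-arm trial data, allocation observed, mTICI
observed only in the treated arm).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# -- controlled vocabularies -------------------------------------------------

SEX_LEVELS = ("female", "male")
ASPECTS_LEVELS = ("high_9_10", "mid_6_8", "low_0_5")
VESSEL_LEVELS = ("M1", "M2", "ICA", "ICA_T", "basilar", "vertebral")
ANTERIOR_VESSELS = ("M1", "M2", "ICA", "ICA_T")
VB_VESSELS = ("basilar", "vertebral")
ALLOCATION_LEVELS = ("evt", "control")
MTICI_LEVELS = ("grade_0_2a", "grade_2b", "grade_3")

#: ordinal reperfusion step used throughout: no/minimal (0-2a) -> 0,
#: substantial (2b) -> 1, complete (3) -> 2.
TICI_STEP = {"grade_0_2a": 0, "grade_2b": 1, "grade_3": 2}

FLAG_FIELDS = (
    "hypertension",
    "diabetes",
    "dyslipidemia",
    "atrial_fibrillation",
    "smoking",
    "oac",
    "antiplatelet",
    "ivt",
    "general_anesthesia",
    "transfer",
    "high_volume_center",
    "symptom_onset_known",
    "adverse_event",
)

#: canonical column order of a patient record
COLUMNS = (
    "age",
    "sex",
    "nihss",
    "pmrs",
    "aspects_band",
    "vessel",
    "otp_min",
    "hypertension",
    "diabetes",
    "dyslipidemia",
    "atrial_fibrillation",
    "smoking",
    "oac",
    "antiplatelet",
    "ivt",
    "general_anesthesia",
    "transfer",
    "high_volume_center",
    "symptom_onset_known",
    "allocation",
    "mtici",
    "adverse_event",
    "mrs90",
)

#: covariates known before arterial puncture (candidate model features)
PRE_PUNCTURE_FEATURES = (
    "age",
    "sex",
    "nihss",
    "pmrs",
    "aspects_band",
    "vessel",
    "otp_min",
    "hypertension",
    "diabetes",
    "dyslipidemia",
    "atrial_fibrillation",
    "smoking",
    "oac",
    "antiplatelet",
    "ivt",
    "general_anesthesia",
    "transfer",
    "high_volume_center",
    "symptom_onset_known",
)


class CohortValidationError(ValueError):
    """Raised when a table violates the patient-record contract."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("\n".join(self.messages))


@dataclass
class Cohort:
    """An ordered collection of patient records plus design metadata.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per patient, columns as in :data:`COLUMNS`.  Missing values
        are ``NaN``/``None`` (written as ``"NA"`` on disk).
    design : {"registry", "rct"}
    circulation : {"anterior", "vertebrobasilar"}
    label : str
        Free-text provenance label.
    """

    data: pd.DataFrame
    design: str = "registry"
    circulation: str = "anterior"
    label: str = ""

    def __post_init__(self):
        if self.design not in ("registry", "rct"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.circulation not in ("anterior", "vertebrobasilar"):
            raise ValueError(f"unknown circulation {self.circulation!r}")
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise CohortValidationError(
                [f"missing required column: {c}" for c in missing]
            )

    def __len__(self):
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    def subset(self, mask, label_suffix: str = "") -> "Cohort":
        """Row-subset preserving order and metadata (copy, original untouched)."""
        sub = self.data.loc[mask].reset_index(drop=True)
        return replace(self, data=sub, label=self.label + label_suffix)

    def endpoint(self, which: str = "mrs_0_2") -> np.ndarray:
        """Binary functional endpoint from the 90-day mRS.

        ``mrs_0_2`` is functional independence (mRS 0-2), the primary
        endpoint; ``mrs_0_1`` is excellent outcome (mRS 0-1).
        """
        if which == "mrs_0_2":
            return (self.data["mrs90"].to_numpy() <= 2).astype(int)
        if which == "mrs_0_1":
            return (self.data["mrs90"].to_numpy() <= 1).astype(int)
        raise ValueError(f"unknown endpoint {which!r}")

    def tici_step(self) -> np.ndarray:
        """Numeric reperfusion step 0/1/2 (NaN where mTICI missing)."""
        return self.data["mtici"].map(TICI_STEP).to_numpy(dtype=float)

    def validate(self) -> None:
        """Check every record invariant; raise with row-numbered messages."""
        errs = collect_row_errors(self.data, self.design, self.circulation)
        if errs:
            raise CohortValidationError(errs)


def collect_row_errors(df: pd.DataFrame, design: str, circulation: str) -> list:
    """Return human-readable invariant violations, one per offending field.

    Row numbers are 0-based positions in the table (header excluded).
    """
    errs = []

    def bad(mask, msg):
        for i in np.flatnonzero(np.asarray(mask)):
            errs.append(f"row {i}: {msg}")

    num = {c: pd.to_numeric(df[c], errors="coerce") for c in
           ("age", "nihss", "pmrs", "otp_min", "mrs90")}
    bad(num["age"].notna() & (num["age"] < 18), "age below 18")
    bad(num["nihss"].notna() & ~num["nihss"].between(0, 42), "nihss outside [0, 42]")
    bad(num["pmrs"].notna() & ~num["pmrs"].between(0, 5), "pmrs outside [0, 5]")
    bad(num["otp_min"].notna() & (num["otp_min"] <= 0), "otp_min not positive")
    bad(num["mrs90"].notna() & ~num["mrs90"].between(0, 6), "mrs90 outside [0, 6]")
    bad(df["mrs90"].isna(), "mrs90 missing")

    bad(df["sex"].notna() & ~df["sex"].isin(SEX_LEVELS), "unknown sex level")
    bad(
        df["aspects_band"].notna() & ~df["aspects_band"].isin(ASPECTS_LEVELS),
        "unknown aspects_band level",
    )
    bad(df["vessel"].notna() & ~df["vessel"].isin(VESSEL_LEVELS), "unknown vessel code")
    bad(
        df["allocation"].notna() & ~df["allocation"].isin(ALLOCATION_LEVELS),
        "unknown allocation level",
    )
    bad(df["mtici"].notna() & ~df["mtici"].isin(MTICI_LEVELS), "unknown mtici level")

    if design == "registry":
        bad(df["allocation"].notna(), "registry record with non-NA allocation")
        bad(df["mtici"].isna(), "registry record with missing mtici")
    else:
        bad(df["allocation"].isna(), "rct record with missing allocation")
        bad(
            (df["allocation"] == "control") & df["mtici"].notna(),
            "rct control record with non-NA mtici",
        )
    if circulation == "vertebrobasilar":
        bad(df["aspects_band"].notna(), "vertebrobasilar record with non-NA aspects_band")
        bad(
            df["vessel"].notna() & ~df["vessel"].isin(VB_VESSELS),
            "vertebrobasilar record with anterior vessel code",
        )
    else:
        bad(
            df["vessel"].notna() & ~df["vessel"].isin(ANTERIOR_VESSELS),
            "anterior record with vertebrobasilar vessel code",
        )
    return errs


# -- delimited-text I/O ------------------------------------------------------

_META_PREFIX = "#"


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as UTF-8 CSV with ``NA`` for missing values.

    Design metadata travel in ``#key=value`` comment lines above the header.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{_META_PREFIX}design={cohort.design}\n")
        fh.write(f"{_META_PREFIX}circulation={cohort.circulation}\n")
        fh.write(f"{_META_PREFIX}label={cohort.label}\n")
        cohort.data.to_csv(fh, index=False, na_rep="NA")


def read_cohort(path, max_error_fraction: float = 0.0) -> Cohort:
    """Read a cohort CSV, validating every record invariant.

    Malformed rows are collected with their row numbers.  If the offending
    fraction exceeds ``max_error_fraction`` a :class:`CohortValidationError`
    listing every violation is raised; otherwise offending rows are dropped
    and the violations attached as ``cohort.read_errors``.
    """
    meta = {"design": "registry", "circulation": "anterior", "label": ""}
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if not line.startswith(_META_PREFIX):
            break
        body_start += 1
        key, _, value = line[len(_META_PREFIX):].strip().partition("=")
        if key in meta:
            meta[key] = value
    df = pd.read_csv(
        io.StringIO("".join(lines[body_start:])),
        na_values=["NA"],
        keep_default_na=False,
    )
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError([f"missing required column: {c}" for c in missing])
    errs = collect_row_errors(df, meta["design"], meta["circulation"])
    if errs:
        bad_rows = sorted({int(e.split(":")[0].split()[1]) for e in errs})
        if len(bad_rows) > max_error_fraction * len(df):
            raise CohortValidationError(errs)
        df = df.drop(index=bad_rows).reset_index(drop=True)
    cohort = Cohort(
        data=df,
        design=meta["design"],
        circulation=meta["circulation"],
        label=meta["label"],
    )
    cohort.read_errors = errs
    return cohort


def missingness_report(cohort: Cohort) -> pd.Series:
    """Per-field fraction of missing values."""
    return cohort.data[list(COLUMNS)].isna().mean()
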