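"""Synthetic stroke cohort simulator with known treatment-benefit structure.

Generates registry-style (single-arm, mTICI observed) and RCT-style (two-arm,
allocation observed) cohorts whose covariate marginals loosely emulate large
thrombectomy registries and trial archives, and whose 90-day outcome follows a
latent logistic model in which the benefit of reperfusion is injected per
mTICI step and may be restricted to clinically defined subgroups.  Because the
benefit structure is known exactly, every downstream stage — RCT-criteria
filtering, gradient-boosting / logistic outcome models, permutation variable
importance, correlated-ROC comparison — can be validated against ground truth
without access-restricted patient data.

Outcome model
-------------
For patient *i* with covariate vector ``x_i``, effective reperfusion step
``s_i`` in {0, 1, 2} (mTICI 0-2a, 2b, 3) and adverse-event flag ``a_i``::

    logit P(good outcome) = b0 + sum_k beta_k x_ik + benefit(x_i) * s_i
                            + penalty * a_i

``benefit(x_i)`` is the sum of the benefit-map coefficients whose subgroup
predicate matches the patient; a good outcome is functional independence
(mRS 0-2 at 90 days).  The full ordinal mRS is then spread over levels by a
fixed conditional multinomial so that the excellent-outcome endpoint
(mRS 0-1) is exercisable as well.

By default the mTICI grade is drawn independently of every baseline
covariate, mirroring real-world reports that pre-puncture variables carry no
information on the achieved reperfusion grade; an optional link re-introduces
dependence for robustness experiments while preserving the marginal grade
frequencies.

All randomness flows from a single seed through named
``numpy.random.SeedSequence`` child streams (one per generation stage), so a
config is a complete, bitwise-reproducible description of a cohort.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import (
    ANTERIOR_VESSELS,
    ASPECTS_LEVELS,
    COLUMNS,
    MTICI_LEVELS,
    TICI_STEP,
    VB_VESSELS,
    Cohort,
)

# IQR of a normal spans 2 * 0.6745 standard deviations
_IQR_TO_SD = 1.0 / (2 * 0.674489750196082)


@dataclass(frozen=True)
class BenefitRule:
    """Subgroup-specific reperfusion benefit.

    ``where`` is a pandas query expression over record columns (``None``
    applies to every patient); ``coef`` is the added log-odds of a good
    outcome per mTICI step for matching patients.
    """

    name: str
    where: str | None
    coef: float


def _registry_anterior_covariates() -> dict:
    # loosely calibrated to large German registry descriptive statistics
    return {
        "age": {"median": 76, "iqr": (66, 83), "lo": 18, "hi": 99},
        "nihss": {"median": 15, "iqr": (10, 18)},
        "pmrs_probs": (0.62, 0.20, 0.09, 0.05, 0.03, 0.01),
        "female_prob": 0.517,
        "aspects_probs": (0.528, 0.382, 0.090),  # high, mid, low
        "vessel_levels": ANTERIOR_VESSELS,
        # overlapping registry percentages renormalised to a partition
        "vessel_probs": (0.531, 0.205, 0.106, 0.158),
        "otp": {"median": 220, "iqr": (153, 334)},
        "flag_probs": {
            "hypertension": 0.776,
            "diabetes": 0.223,
            "dyslipidemia": 0.406,
            "atrial_fibrillation": 0.431,
            "smoking": 0.171,
            "oac": 0.215,
            "antiplatelet": 0.313,
            "ivt": 0.520,
            "general_anesthesia": 0.652,
            "transfer": 0.422,
            "high_volume_center": 0.616,
            "symptom_onset_known": 0.607,
        },
    }


def _registry_vb_covariates() -> dict:
    return {
        "age": {"median": 75, "iqr": (65, 82), "lo": 18, "hi": 99},
        "nihss": {"median": 16, "iqr": (7, 26)},
        "pmrs_probs": (0.62, 0.20, 0.09, 0.05, 0.03, 0.01),
        "female_prob": 0.430,
        "aspects_probs": None,  # not assessed in the posterior circulation
        "vessel_levels": VB_VESSELS,
        "vessel_probs": (0.935, 0.065),
        "otp": {"median": 252, "iqr": (164, 399)},
        "flag_probs": {
            "hypertension": 0.805,
            "diabetes": 0.211,
            "dyslipidemia": 0.391,
            "atrial_fibrillation": 0.338,
            "smoking": 0.130,
            "oac": 0.162,
            "antiplatelet": 0.372,
            "ivt": 0.456,
            "general_anesthesia": 0.892,
            "transfer": 0.413,
            "high_volume_center": 0.645,
            "symptom_onset_known": 0.606,
        },
    }


def _rct_anterior_covariates() -> dict:
    # trial-archive populations are younger, more severe, heavily thrombolysed
    cov = _registry_anterior_covariates()
    cov.update(
        {
            "age": {"median": 68, "iqr": (57, 76), "lo": 18, "hi": 99},
            "nihss": {"median": 17, "iqr": (14, 20)},
            "pmrs_probs": (0.80, 0.14, 0.04, 0.02, 0.0, 0.0),
            "female_prob": 0.453,
            "aspects_probs": (0.487, 0.420, 0.093),
            "otp": {"median": 181, "iqr": (142, 237)},
        }
    )
    cov["flag_probs"] = dict(cov["flag_probs"])
    cov["flag_probs"].update(
        {"hypertension": 0.532, "diabetes": 0.133, "dyslipidemia": 0.328,
         "smoking": 0.284, "ivt": 0.895}
    )
    return cov


def default_baseline_coefs() -> dict:
    """Log-odds coefficients of the latent good-outcome model.

    Continuous covariates are centred inside the linear predictor (age at 70
    years, NIHSS at 15, onset-to-puncture at 220 min) so the intercept stays
    interpretable; categorical covariates use M1 / high ASPECTS as reference.
    Signs and magnitudes follow the well-replicated directions of stroke
    outcome predictors (older age, higher NIHSS, premorbid disability, larger
    early-ischemia extent and longer delays are harmful; thrombolysis helps).
    """
    return {
        "intercept": 0.35,
        "age": -0.045,          # per year, centred at 70
        "nihss": -0.10,         # per point, centred at 15
        "pmrs": -0.45,          # per premorbid mRS point
        "aspects_ord": 0.35,    # per band (low=0, mid=1, high=2), centred at high
        "otp_min": -0.0008,     # per minute, centred at 220
        "sex_female": 0.0,
        "vessel": {"M1": 0.0, "M2": 0.20, "ICA": -0.15, "ICA_T": -0.30,
                   "basilar": -0.20, "vertebral": 0.0},
        "hypertension": -0.10,
        "diabetes": -0.20,
        "dyslipidemia": 0.0,
        "atrial_fibrillation": -0.10,
        "smoking": 0.0,
        "oac": -0.05,
        "antiplatelet": 0.0,
        "ivt": 0.25,
        "general_anesthesia": -0.15,
        "transfer": -0.05,
        "high_volume_center": 0.10,
        "symptom_onset_known": 0.0,
    }


#: conditional distribution of the ordinal mRS given the binary endpoint:
#: good outcomes spread over mRS 0-2, bad outcomes over mRS 3-6
MRS_SPREAD_GOOD = (0.30, 0.35, 0.35)
MRS_SPREAD_BAD = (0.35, 0.25, 0.20, 0.20)


@dataclass
class GeneratorConfig:
    """Full parametrisation of the synthetic cohort simulator."""

    n: int
    design: str = "registry"               # {"registry", "rct"}
    circulation: str = "anterior"          # {"anterior", "vertebrobasilar"}
    covariate_params: dict | None = None   # None -> defaults per design/circulation
    baseline_coefs: dict = field(default_factory=default_baseline_coefs)
    benefit_map: tuple = ()                # tuple of BenefitRule
    mtici_probs: tuple = (0.155, 0.349, 0.496)  # P(0-2a), P(2b), P(3)
    mtici_baseline_link: dict = field(default_factory=dict)
    adverse_event_prob: float = 0.05
    #: optional (p_0_2a, p_2b, p_3): adverse-event probability per achieved
    #: grade, overriding the independent rate — used only to construct
    #: counterexamples where adverse events track reperfusion
    adverse_event_probs_by_grade: tuple | None = None
    adverse_event_penalty: float = -1.0
    reperfusion_given_control: float = 0.0
    missing_rate: float = 0.0
    missing_fields: tuple = ("aspects_band", "otp_min")
    label: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n <= 0:
            raise ValueError("n: cohort size must be a positive integer")
        if self.design not in ("registry", "rct"):
            raise ValueError(f"design: unknown design {self.design!r}")
        if self.circulation not in ("anterior", "vertebrobasilar"):
            raise ValueError(f"circulation: unknown circulation {self.circulation!r}")
        p = np.asarray(self.mtici_probs, dtype=float)
        if p.shape != (3,) or (p < 0).any() or (p > 1).any():
            raise ValueError("mtici_probs: need three probabilities in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("mtici_probs: probabilities must sum to 1")
        for name, value in (
            ("adverse_event_prob", self.adverse_event_prob),
            ("reperfusion_given_control", self.reperfusion_given_control),
            ("missing_rate", self.missing_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}: probability must lie in [0, 1]")
        if self.adverse_event_probs_by_grade is not None:
            q = np.asarray(self.adverse_event_probs_by_grade, dtype=float)
            if q.shape != (3,) or (q < 0).any() or (q > 1).any():
                raise ValueError(
                    "adverse_event_probs_by_grade: need three probabilities in [0, 1]"
                )
        for rule in self.benefit_map:
            if not math.isfinite(rule.coef):
                raise ValueError(f"benefit_map: non-finite coefficient in {rule.name!r}")
        if not math.isfinite(self.adverse_event_penalty):
            raise ValueError("adverse_event_penalty: must be finite")

    def resolved_covariates(self) -> dict:
        if self.covariate_params is not None:
            return self.covariate_params
        if self.design == "rct":
            return _rct_anterior_covariates()
        if self.circulation == "vertebrobasilar":
            return _registry_vb_covariates()
        return _registry_anterior_covariates()


def _streams(seed: int) -> dict:
    """Named child RNG streams so stages cannot steal each other's draws."""
    names = ("covariates", "mtici", "allocation", "adverse", "outcome",
             "mrs_spread", "missing")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _truncated_normal_int(rng, n, median, iqr, lo, hi):
    sd = (iqr[1] - iqr[0]) * _IQR_TO_SD
    x = rng.normal(median, sd, size=n)
    x = np.clip(np.rint(x), lo, hi)
    return x.astype(int)


def _lognormal_minutes(rng, n, median, iqr):
    sigma = math.log(iqr[1] / iqr[0]) * _IQR_TO_SD
    x = rng.lognormal(mean=math.log(median), sigma=sigma, size=n)
    return np.maximum(np.rint(x), 1).astype(int)


def _draw_covariates(cov: dict, n: int, rng) -> pd.DataFrame:
    df = pd.DataFrame(index=range(n))
    df["age"] = _truncated_normal_int(rng, n, **{
        "median": cov["age"]["median"], "iqr": cov["age"]["iqr"],
        "lo": cov["age"]["lo"], "hi": cov["age"]["hi"]})
    df["sex"] = np.where(rng.random(n) < cov["female_prob"], "female", "male")
    df["nihss"] = _truncated_normal_int(
        rng, n, cov["nihss"]["median"], cov["nihss"]["iqr"], 0, 42)
    df["pmrs"] = rng.choice(6, size=n, p=cov["pmrs_probs"])
    if cov["aspects_probs"] is None:
        df["aspects_band"] = pd.Series([np.nan] * n, dtype=object)
    else:
        df["aspects_band"] = rng.choice(
            np.array(ASPECTS_LEVELS, dtype=object), size=n, p=cov["aspects_probs"])
    df["vessel"] = rng.choice(
        np.array(cov["vessel_levels"], dtype=object), size=n, p=cov["vessel_probs"])
    df["otp_min"] = _lognormal_minutes(rng, n, cov["otp"]["median"], cov["otp"]["iqr"])
    for flag, prob in cov["flag_probs"].items():
        df[flag] = (rng.random(n) < prob).astype(int)
    return df


def _covariate_link_score(df: pd.DataFrame, link: dict) -> np.ndarray:
    """Linear score of baseline covariates used to tilt the mTICI draw."""
    score = np.zeros(len(df))
    for name, coef in link.items():
        if coef == 0:
            continue
        if name not in df.columns:
            raise ValueError(f"mtici_baseline_link: unknown covariate {name!r}")
        col = df[name]
        if col.dtype == object:
            raise ValueError(
                f"mtici_baseline_link: covariate {name!r} is categorical; "
                "link coefficients apply to numeric covariates"
            )
        x = col.to_numpy(dtype=float)
        sd = x.std()
        if sd > 0:
            x = (x - x.mean()) / sd
        score += coef * x
    return score


def _draw_mtici(df: pd.DataFrame, config: GeneratorConfig, rng) -> np.ndarray:
    """mTICI grades with fixed marginals and optional baseline dependence.

    A latent score (standardised covariate link plus logistic noise) is cut at
    its empirical quantiles matching the configured grade frequencies, so a
    non-zero link changes who reperfuses but not how many.
    """
    n = len(df)
    probs = np.asarray(config.mtici_probs, dtype=float)
    if not config.mtici_baseline_link or all(
        v == 0 for v in config.mtici_baseline_link.values()
    ):
        return rng.choice(np.array(MTICI_LEVELS, dtype=object), size=n, p=probs)
    latent = _covariate_link_score(df, config.mtici_baseline_link)
    latent = latent + rng.logistic(size=n)
    order = np.argsort(latent, kind="stable")
    counts = np.rint(np.cumsum(probs) * n).astype(int)
    grades = np.empty(n, dtype=object)
    grades[order[: counts[0]]] = MTICI_LEVELS[0]
    grades[order[counts[0]: counts[1]]] = MTICI_LEVELS[1]
    grades[order[counts[1]:]] = MTICI_LEVELS[2]
    return grades


def benefit_per_step(df: pd.DataFrame, benefit_map) -> np.ndarray:
    """Per-patient reperfusion benefit (log-odds per mTICI step)."""
    out = np.zeros(len(df))
    for rule in benefit_map:
        if rule.where is None:
            out += rule.coef
        else:
            mask = df.eval(rule.where).to_numpy(dtype=bool)
            out[mask] += rule.coef
    return out


def _linear_predictor(df: pd.DataFrame, coefs: dict) -> np.ndarray:
    eta = np.full(len(df), coefs["intercept"], dtype=float)
    eta += coefs["age"] * (df["age"].to_numpy(float) - 70.0)
    eta += coefs["nihss"] * (df["nihss"].to_numpy(float) - 15.0)
    eta += coefs["pmrs"] * df["pmrs"].to_numpy(float)
    eta += coefs["otp_min"] * (df["otp_min"].to_numpy(float) - 220.0)
    eta += coefs["sex_female"] * (df["sex"] == "female").to_numpy(float)
    aspects_ord = df["aspects_band"].map(
        {"low_0_5": 0.0, "mid_6_8": 1.0, "high_9_10": 2.0})
    eta += coefs["aspects_ord"] * (aspects_ord.fillna(2.0).to_numpy(float) - 2.0)
    eta += df["vessel"].map(coefs["vessel"]).fillna(0.0).to_numpy(float)
    for flag in ("hypertension", "diabetes", "dyslipidemia", "atrial_fibrillation",
                 "smoking", "oac", "antiplatelet", "ivt", "general_anesthesia",
                 "transfer", "high_volume_center", "symptom_onset_known"):
        eta += coefs[flag] * df[flag].to_numpy(float)
    return eta


def good_outcome_probability(df: pd.DataFrame, config: GeneratorConfig,
                             effective_step: np.ndarray,
                             adverse: np.ndarray) -> np.ndarray:
    """P(mRS 0-2) under the latent logistic model, given reperfusion step."""
    eta = _linear_predictor(df, config.baseline_coefs)
    eta = eta + benefit_per_step(df, config.benefit_map) * effective_step
    eta = eta + config.adverse_event_penalty * adverse
    return 1.0 / (1.0 + np.exp(-eta))


def _spread_mrs(good: np.ndarray, rng) -> np.ndarray:
    """Ordinal 90-day mRS from the binary endpoint via fixed conditionals."""
    n = len(good)
    mrs = np.empty(n, dtype=int)
    g = good.astype(bool)
    mrs[g] = rng.choice(3, size=int(g.sum()), p=MRS_SPREAD_GOOD)
    mrs[~g] = 3 + rng.choice(4, size=int((~g).sum()), p=MRS_SPREAD_BAD)
    return mrs


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Simulate one cohort; identical config (incl. seed) gives identical rows."""
    config.validate()
    rngs = _streams(config.seed)
    cov = config.resolved_covariates()
    df = _draw_covariates(cov, config.n, rngs["covariates"])

    if config.design == "rct":
        alloc = np.where(
            rngs["allocation"].random(config.n) < 0.5, "evt", "control")
        df["allocation"] = alloc
        mtici = _draw_mtici(df, config, rngs["mtici"]).astype(object)
        is_control = alloc == "control"
        # control patients receive no thrombectomy: their achieved grade is
        # unobserved, and their outcome accrues no reperfusion benefit unless
        # spontaneous-equivalent reperfusion is configured
        effective_step = np.array([TICI_STEP[g] for g in mtici], dtype=float)
        spontaneous = (
            rngs["allocation"].random(config.n) < config.reperfusion_given_control
        )
        effective_step[is_control] = np.where(
            spontaneous[is_control], float(TICI_STEP["grade_3"]), 0.0)
        mtici[is_control] = np.nan
        df["mtici"] = mtici
    else:
        df["allocation"] = pd.Series([np.nan] * config.n, dtype=object)
        df["mtici"] = _draw_mtici(df, config, rngs["mtici"])
        effective_step = df["mtici"].map(TICI_STEP).to_numpy(dtype=float)

    if config.adverse_event_probs_by_grade is not None:
        by_grade = np.asarray(config.adverse_event_probs_by_grade, dtype=float)
        step_idx = np.nan_to_num(effective_step, nan=0.0).astype(int)
        p_adverse = by_grade[step_idx]
    else:
        p_adverse = config.adverse_event_prob
    adverse = (rngs["adverse"].random(config.n) < p_adverse).astype(int)
    df["adverse_event"] = adverse

    p_good = good_outcome_probability(df, config, effective_step, adverse)
    good = (rngs["outcome"].random(config.n) < p_good).astype(int)
    df["mrs90"] = _spread_mrs(good, rngs["mrs_spread"])

    if config.missing_rate > 0:
        for fieldname in config.missing_fields:
            mask = rngs["missing"].random(config.n) < config.missing_rate
            df.loc[mask, fieldname] = np.nan

    df = df[list(COLUMNS)]
    cohort = Cohort(
        data=df,
        design=config.design,
        circulation=config.circulation,
        label=config.label,
    )
    cohort.validate()
    return cohort


# -- scenario library ---------------------------------------------------------

def _scenario_configs() -> dict:
    benefit_uniform = (BenefitRule("uniform", None, 0.5),)
    benefit_m2_young = (
        BenefitRule("m2_young", "vessel == 'M2' and age < 65", 0.9),
    )
    vb_coefs = default_baseline_coefs()
    vb_coefs["ivt"] = 1.0
    return {
        # registry with no reperfusion benefit anywhere: mTICI carries no
        # outcome information beyond chance
        "null_benefit": GeneratorConfig(
            n=5000, design="registry", circulation="anterior",
            benefit_map=(), label="null_benefit"),
        # homogeneous benefit of 0.5 log-odds per mTICI step for everyone
        "uniform_benefit": GeneratorConfig(
            n=5000, design="registry", circulation="anterior",
            benefit_map=benefit_uniform, label="uniform_benefit"),
        # benefit confined to young patients with M2 occlusions
        "subgroup_benefit_m2_young": GeneratorConfig(
            n=5000, design="registry", circulation="anterior",
            benefit_map=benefit_m2_young, label="subgroup_benefit_m2_young"),
        # benefit confined to one sex: because sex is generated independently
        # of every other covariate and carries no direct outcome coefficient,
        # the two strata are exchangeable apart from the injected benefit —
        # the cleanest construction for heterogeneity-recovery calibration
        "subgroup_benefit_female": GeneratorConfig(
            n=5000, design="registry", circulation="anterior",
            benefit_map=(BenefitRule("female", "sex == 'female'", 0.5),),
            label="subgroup_benefit_female"),
        # benefit confined to the trial-eligible sub-population (age <= 80,
        # onset-to-puncture < 12 h, premorbid mRS 0-1): filtering a registry
        # to RCT-like criteria should then concentrate the detectable benefit
        "rct_like_benefit": GeneratorConfig(
            n=5000, design="registry", circulation="anterior",
            benefit_map=(
                BenefitRule(
                    "rct_like",
                    "age <= 80 and otp_min < 720 and pmrs <= 1",
                    0.5,
                ),
            ),
            label="rct_like_benefit"),
        # two-arm trial in which allocation acts on outcome only through the
        # achieved reperfusion grade (control arm: step 0)
        "rct_mediated": GeneratorConfig(
            n=5000, design="rct", circulation="anterior",
            benefit_map=benefit_uniform, reperfusion_given_control=0.0,
            label="rct_mediated"),
        # vertebrobasilar registry where thrombolysis dominates the small
        # reperfusion benefit
        "vb_ivt_dominant": GeneratorConfig(
            n=5000, design="registry", circulation="vertebrobasilar",
            baseline_coefs=vb_coefs,
            benefit_map=(BenefitRule("uniform_small", None, 0.15),),
            label="vb_ivt_dominant"),
        # counterexample: adverse events concentrate in reperfused patients,
        # so excluding them removes part of mTICI's apparent value
        "adverse_coupled": GeneratorConfig(
            n=5000, design="registry", circulation="anterior",
            benefit_map=(),
            adverse_event_probs_by_grade=(0.02, 0.25, 0.45),
            adverse_event_penalty=-2.5,
            label="adverse_coupled"),
    }


def available_scenarios() -> tuple:
    return tuple(sorted(_scenario_configs()))


def write_config(config: GeneratorConfig, path) -> None:
    """Serialise a generator config as YAML (nested key-value sections)."""
    import yaml

    d = dataclasses.asdict(config)
    d["benefit_map"] = [dataclasses.asdict(r) for r in config.benefit_map]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_config(path) -> GeneratorConfig:
    """Load a generator config written by :func:`write_config`."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    d["benefit_map"] = tuple(BenefitRule(**r) for r in d.get("benefit_map", ()))
    for key in ("mtici_probs", "missing_fields", "adverse_event_probs_by_grade"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    config = GeneratorConfig(**d)
    config.validate()
    return config


def make_scenario(name: str, n: int | None = None, seed: int | None = None,
                  **overrides) -> GeneratorConfig:
    """Return a fully specified config from the documented scenario library.

    ``n``, ``seed`` and any other :class:`GeneratorConfig` field may be
    overridden without touching the scenario's scientific content.
    """
    configs = _scenario_configs()
    if name not in configs:
        raise ValueError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(configs))}"
        )
    config = configs[name]
    if n is not None:
        overrides["n"] = n
    if seed is not None:
        overrides["seed"] = seed
    return replace(config, **overrides) if overrides else config
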