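"""Generator contracts: determinism, validation, and ground-truth recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as smapi
from scipy import stats

from strokemark import (
    BenefitRule,
    GeneratorConfig,
    available_scenarios,
    generate_cohort,
    make_scenario,
)
from strokemark.simulate import good_outcome_probability


class TestContracts:
    def test_seeded_determinism(self):
        config = make_scenario("uniform_benefit", n=500, seed=42)
        a = generate_cohort(config).data
        b = generate_cohort(config).data
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_cohort(make_scenario("uniform_benefit", n=500, seed=1)).data
        b = generate_cohort(make_scenario("uniform_benefit", n=500, seed=2)).data
        assert not a.equals(b)

    @pytest.mark.parametrize(
        "field,value,fragment",
        [
            ("n", 0, "n"),
            ("design", "cohort", "design"),
            ("mtici_probs", (0.5, 0.5, 0.5), "mtici_probs"),
            ("adverse_event_prob", 1.5, "adverse_event_prob"),
            ("missing_rate", -0.1, "missing_rate"),
            ("benefit_map", (BenefitRule("bad", None, float("nan")),),
             "benefit_map"),
        ],
    )
    def test_invalid_config_names_field(self, field, value, fragment):
        config = dataclasses.replace(
            make_scenario("null_benefit", n=100), **{field: value})
        with pytest.raises(ValueError, match=fragment):
            generate_cohort(config)

    def test_unknown_scenario_lists_available(self):
        with pytest.raises(ValueError, match="null_benefit"):
            make_scenario("no_such_scenario")

    def test_scenario_library_contains_documented_names(self):
        required = {"null_benefit", "uniform_benefit", "subgroup_benefit_m2_young",
                    "rct_mediated", "vb_ivt_dominant"}
        assert required <= set(available_scenarios())

    def test_null_benefit_has_all_zero_coefficients(self):
        config = make_scenario("null_benefit")
        assert all(rule.coef == 0 for rule in config.benefit_map) or \
            not config.benefit_map

    def test_subgroup_scenario_restricts_benefit_to_m2_young(self):
        cohort = generate_cohort(
            make_scenario("subgroup_benefit_m2_young", n=4000, seed=3))
        from strokemark.simulate import benefit_per_step

        config = make_scenario("subgroup_benefit_m2_young")
        b = benefit_per_step(cohort.data, config.benefit_map)
        in_s = ((cohort.data["vessel"] == "M2") & (cohort.data["age"] < 65)).to_numpy()
        assert (b[in_s] > 0).all()
        assert (b[~in_s] == 0).all()

    def test_record_invariants_hold(self):
        for name in ("uniform_benefit", "rct_mediated", "vb_ivt_dominant"):
            cohort = generate_cohort(make_scenario(name, n=800, seed=5))
            cohort.validate()
            df = cohort.data
            assert df["nihss"].between(0, 42).all()
            assert df["pmrs"].between(0, 5).all()
            assert df["mrs90"].between(0, 6).all()
            assert (df["otp_min"] > 0).all()
            if cohort.design == "rct":
                assert df["allocation"].notna().all()
                control = df["allocation"] == "control"
                assert df.loc[control, "mtici"].isna().all()
                assert df.loc[~control, "mtici"].notna().all()
            else:
                assert df["allocation"].isna().all()
                assert df["mtici"].notna().all()
            if cohort.circulation == "vertebrobasilar":
                assert df["aspects_band"].isna().all()
                assert df["vessel"].isin(["basilar", "vertebral"]).all()


class TestGroundTruth:
    def test_null_benefit_refit_recovers_zero_tici_coefficient(self):
        """ML refit of the generator's own logistic link: benefit 0 -> coef ~ 0."""
        cohort = generate_cohort(make_scenario("null_benefit", n=50_000, seed=11))
        y = cohort.endpoint()
        step = cohort.tici_step()
        fit = smapi.Logit(y, np.column_stack([np.ones_like(step), step])).fit(disp=0)
        assert abs(fit.params[1]) < 0.05

    def test_uniform_benefit_refit_recovers_injected_coefficient(self):
        """Adjusted logistic refit recovers the injected 0.5 per-step benefit."""
        cohort = generate_cohort(make_scenario("uniform_benefit", n=50_000, seed=12))
        df = cohort.data
        X = np.column_stack([
            np.ones(len(df)),
            cohort.tici_step(),
            df["age"], df["nihss"], df["pmrs"], df["otp_min"],
            df["ivt"], df["general_anesthesia"], df["diabetes"],
            df["atrial_fibrillation"], df["hypertension"],
            df["high_volume_center"], df["transfer"],
            df["aspects_band"].map({"low_0_5": 0, "mid_6_8": 1, "high_9_10": 2}),
            (df["vessel"] == "M2").astype(float),
            (df["vessel"] == "ICA").astype(float),
            (df["vessel"] == "ICA_T").astype(float),
        ]).astype(float)
        fit = smapi.Logit(cohort.endpoint(), X).fit(disp=0)
        se = fit.bse[1]
        assert fit.params[1] == pytest.approx(0.5, abs=3 * se)

    def test_marginal_outcome_matches_analytic_expectation(self):
        """Monte-Carlo P(mRS 0-2) matches the model's integrated probability."""
        config = make_scenario("uniform_benefit", n=50_000, seed=13)
        cohort = generate_cohort(config)
        step = cohort.tici_step()
        adverse = cohort.data["adverse_event"].to_numpy()
        expected = good_outcome_probability(cohort.data, config, step, adverse)
        assert cohort.endpoint().mean() == pytest.approx(expected.mean(), abs=0.01)

    def test_mtici_independent_of_baseline_by_default(self):
        """With a zero link, no baseline covariate predicts the grade."""
        cohort = generate_cohort(make_scenario("null_benefit", n=20_000, seed=14))
        df = cohort.data
        grade3 = (df["mtici"] == "grade_3").astype(int)
        for col in ("age", "nihss", "otp_min"):
            rho = stats.pearsonr(df[col], grade3).statistic
            assert abs(rho) < 0.02

    def test_mtici_link_induces_dependence_but_keeps_marginals(self):
        config = dataclasses.replace(
            make_scenario("null_benefit", n=20_000, seed=15),
            mtici_baseline_link={"age": 1.0},
        )
        cohort = generate_cohort(config)
        df = cohort.data
        grade3 = (df["mtici"] == "grade_3").astype(int)
        assert stats.pearsonr(df["age"], grade3).statistic > 0.1
        observed = df["mtici"].value_counts(normalize=True)
        for level, p in zip(("grade_0_2a", "grade_2b", "grade_3"),
                            config.mtici_probs):
            assert observed[level] == pytest.approx(p, abs=0.01)

    def test_missingness_rate_within_binomial_bounds(self):
        rate = 0.12
        config = dataclasses.replace(
            make_scenario("null_benefit", n=20_000, seed=16), missing_rate=rate)
        cohort = generate_cohort(config)
        half_width = 2.576 * np.sqrt(rate * (1 - rate) / len(cohort))
        for fieldname in config.missing_fields:
            frac = cohort.data[fieldname].isna().mean()
            assert abs(frac - rate) < half_width

    def test_rct_mediated_evt_arm_matches_registry_conditional_on_mtici(self):
        """Among treated RCT patients, outcome given mTICI equals the registry's
        under the same benefit map (two-sample z at large n)."""
        n = 40_000
        rct = generate_cohort(make_scenario("rct_mediated", n=n, seed=17))
        registry_cfg = dataclasses.replace(
            make_scenario("uniform_benefit", n=n, seed=18),
            covariate_params=make_scenario("rct_mediated").resolved_covariates(),
        )
        registry = generate_cohort(registry_cfg)
        evt = rct.data[rct.data["allocation"] == "evt"]
        for grade in ("grade_0_2a", "grade_2b", "grade_3"):
            p1 = (evt.loc[evt["mtici"] == grade, "mrs90"] <= 2).mean()
            sub = registry.data[registry.data["mtici"] == grade]
            p2 = (sub["mrs90"] <= 2).mean()
            n1 = (evt["mtici"] == grade).sum()
            n2 = len(sub)
            se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
            assert abs(p1 - p2) < 4 * se

    def test_rct_control_arm_accrues_no_benefit(self):
        """Control outcomes match a zero-step registry population."""
        n = 40_000
        rct = generate_cohort(make_scenario("rct_mediated", n=n, seed=19))
        control = rct.data[rct.data["allocation"] == "control"]
        evt = rct.data[rct.data["allocation"] == "evt"]
        # treated patients mostly reperfuse, so their good-outcome rate is higher
        assert (evt["mrs90"] <= 2).mean() > (control["mrs90"] <= 2).mean() + 0.05
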