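"""Tests for trend tests, change-predictor models, endpoint extraction,
follow-up construction, and proportional-hazards analyses."""

import numpy as np
import pandas as pd
import pytest

from telotrack import association, cohort, longitudinal
from tests.conftest import make_exam


class TestCovariateDefinitions:
    @pytest.mark.parametrize(
        "sex,g,expected",
        [("female", 88, True), ("male", 88, False), ("female", 87.5, False),
         ("male", 175.0, False), ("male", 176, True)],
    )
    def test_heavy_alcohol_thresholds(self, sex, g, expected):
        assert association.classify_heavy_alcohol(sex, g) is expected

    @pytest.mark.parametrize("h,expected", [(3.9, True), (4.0, False), (0, True)])
    def test_physical_inactivity_threshold(self, h, expected):
        assert association.classify_physical_inactivity(h) is expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            association.classify_heavy_alcohol("female", -1)
        with pytest.raises(ValueError):
            association.classify_physical_inactivity(-0.1)


class TestImputeCovariates:
    def test_no_missing_is_identity(self):
        df = make_exam(["a", "b", "c", "d"], ["1992-01-01"] * 4,
                       [45.0, 55.0, 65.0, 75.0], [5000.0] * 4)
        out = association.impute_covariates(df)
        pd.testing.assert_frame_equal(
            out[df.columns], df, check_dtype=False
        )

    def test_exact_linear_rule_recovered(self):
        # weight = 50 + 0.3*age + 10*male exactly; one missing cell
        age = np.array([40.0, 50, 60, 70, 55, 45])
        male = np.array([0, 1, 0, 1, 0, 1])
        weight = 50 + 0.3 * age + 10 * male
        df = make_exam([f"p{i}" for i in range(6)], ["1992-01-01"] * 6, age, 5000.0,
                       sex=np.where(male == 1, "male", "female"), weight_kg=weight)
        df.loc[2, "weight_kg"] = np.nan
        out = association.impute_covariates(df)
        assert out.loc[2, "weight_kg"] == pytest.approx(50 + 0.3 * 60)
        assert out.loc[2, "weight_kg_imputed"]
        assert not out.loc[0, "weight_kg_imputed"]

    def test_missing_categorical_gets_explicit_level(self):
        df = make_exam(["a", "b", "c", "d"], ["1992-01-01"] * 4,
                       [45.0, 55.0, 65.0, 75.0], 5000.0)
        df.loc[1, "current_smoking"] = np.nan
        out = association.impute_covariates(df)
        assert out.loc[1, "current_smoking"] == "missing"
        assert len(out) == 4  # never dropped

    def test_all_missing_covariate_rejected(self):
        df = make_exam(["a", "b", "c", "d"], ["1992-01-01"] * 4,
                       [45.0, 55.0, 65.0, 75.0], 5000.0, weight_kg=np.nan)
        with pytest.raises(ValueError, match="no complete cases"):
            association.impute_covariates(df)


class TestTrendTest:
    def test_separated_continuous_trend(self, rng):
        q = np.repeat([1, 2, 3, 4], 500)
        y = q * 2.0 + rng.normal(0, 0.5, q.size)
        res = association.trend_test_quartiles(y, q)
        assert res["estimate"] > 0
        assert res["p_value"] < 1e-6

    def test_binary_trend_cochran_armitage(self, rng):
        q = np.repeat([1, 2, 3, 4], 2000)
        p = 0.1 + 0.05 * (q - 1)
        y = (rng.random(q.size) < p).astype(float)
        res = association.trend_test_quartiles(y, q)
        assert res["p_value"] < 1e-6

    def test_constant_covariate_gives_null(self):
        q = np.repeat([1, 2, 3, 4], 10)
        res = association.trend_test_quartiles(np.ones(40), q)
        assert res == {"estimate": 0.0, "p_value": 1.0}

    def test_null_rejection_rate_near_alpha(self, rng):
        """Permutation-style null: a covariate independent of the quartile
        labels rejects at ~5% for both the OLS and Cochran-Armitage branches."""
        q = np.repeat([1, 2, 3, 4], 250)
        rej_c = rej_b = 0
        n_rep = 400
        for _ in range(n_rep):
            y = rng.normal(0, 1, q.size)
            rej_c += association.trend_test_quartiles(y, q)["p_value"] < 0.05
            yb = (rng.random(q.size) < 0.3).astype(float)
            rej_b += association.trend_test_quartiles(yb, q)["p_value"] < 0.05
        assert rej_c / n_rep == pytest.approx(0.05, abs=0.03)
        assert rej_b / n_rep == pytest.approx(0.05, abs=0.03)


class TestChangePredictors:
    def _cohort_predictors(self, n=1500, seed=33):
        cfg = cohort.GeneratorConfig(n_participants=n, seed=seed)
        tabs = cohort.generate_cohort(cfg)
        ch = longitudinal.build_change_table(tabs["exam1"], tabs["exam2"])
        pred = association.build_predictor_table(tabs["exam1"], tabs["exam2"])
        y = ch.set_index("participant_id").loc[pred["participant_id"], "change_bp_10y"]
        return y.to_numpy(), pred

    def test_noiseless_linear_outcome_recovered(self):
        _, pred = self._cohort_predictors()
        y = -0.5 * pred["baseline_tl_bp"].to_numpy() + 100.0
        out = association.fit_change_predictors(y, pred[["baseline_tl_bp"]], "univariable")
        row = out[out["term"] == "baseline_tl_bp"].iloc[0]
        assert row["beta"] == pytest.approx(-0.5, abs=1e-10)
        assert row["ci_high"] - row["ci_low"] == pytest.approx(0.0, abs=1e-8)

    def test_ts_scale_coefficient_is_anchor_multiple(self):
        y, pred = self._cohort_predictors()
        out = association.fit_change_predictors(y, pred, "multivariable")
        bp = out[out["term"] == "baseline_tl_bp"].iloc[0]
        ts = out[out["term"] == "baseline_ts_ratio"].iloc[0]
        assert ts["beta"] == pytest.approx(bp["beta"] * 5290.0)
        assert ts["p_value"] == bp["p_value"]

    def test_baseline_tl_dominates_and_lifestyle_null(self):
        """RTM makes baseline TL the only strong predictor; the age-confounded
        lifestyle terms stay null because true attrition ignores them."""
        y, pred = self._cohort_predictors(n=4576, seed=34)
        out = association.fit_change_predictors(y, pred, "univariable")
        base = out[out["term"] == "baseline_tl_bp"].iloc[0]
        assert base["beta"] < -0.3
        assert base["p_value"] < 1e-50
        life = out[out["term"].isin(association.LIFESTYLE_TERMS)]
        assert (life["p_value"] > 1e-3).all()

    def test_collinear_design_names_offender(self):
        y, pred = self._cohort_predictors()
        bad = pred[["baseline_tl_bp", "age_baseline"]].copy()
        bad["age_twice"] = 2.0 * bad["age_baseline"]
        bad_terms = association.CHANGE_PREDICTOR_TERMS + ["age_twice"]
        with pytest.raises(ValueError, match="collinear"):
            association._check_design(bad)

    def test_unknown_mode_rejected(self):
        y, pred = self._cohort_predictors()
        with pytest.raises(ValueError):
            association.fit_change_predictors(y, pred, "bivariable")


class TestEndpointExtraction:
    @pytest.mark.parametrize(
        "code,version,endpoint,expected",
        [
            ("C50", "ICD10", "cancer", True),
            ("D05", "ICD10", "cancer", True),
            ("D10", "ICD10", "cancer", False),
            ("412", "ICD8", "ihd", True),
            ("J40", "ICD10", "copd", False),
            ("J41", "ICD10", "copd", True),
            ("G45", "ICD10", "icvd", True),
            ("E14", "ICD10", "dm2", True),
            ("249", "ICD8", "dm2", True),
            ("I26", "ICD10", "ihd", False),
        ],
    )
    def test_category_range_matching(self, code, version, endpoint, expected):
        assert association.code_matches(code, version, association.ENDPOINTS[endpoint]) is expected

    def test_subcodes_inherit_category(self):
        assert association.code_matches("C50.9", "ICD10", association.ENDPOINTS["cancer"])
        assert association.code_matches("J449", "ICD10", association.ENDPOINTS["copd"])

    def test_earliest_event_and_rejects(self):
        reg = pd.DataFrame(
            {
                "participant_id": ["a", "a", "b", "c"],
                "event_date": pd.to_datetime(["2005-01-01", "2003-06-01", "2004-01-01", "2004-01-01"]),
                "event_type": ["diagnosis"] * 4,
                "icd_version": ["ICD10", "ICD10", "ICD10", "ICD10"],
                "icd_code": ["C50", "C61", "??", "J44"],
            }
        )
        events, rejects = association.extract_endpoint_events(reg, association.ENDPOINTS["cancer"])
        assert events.set_index("participant_id").loc["a", "event_date"] == pd.Timestamp("2003-06-01")
        assert "b" not in set(events["participant_id"])
        assert len(rejects) == 1

    def test_order_independent(self, registry):
        d = association.ENDPOINTS["ihd"]
        a, _ = association.extract_endpoint_events(registry, d)
        b, _ = association.extract_endpoint_events(registry.sample(frac=1, random_state=1), d)
        pd.testing.assert_frame_equal(a, b)


class TestBuildFollowup:
    def _mini(self):
        coh = make_exam(["a", "b", "c"], ["2002-03-01"] * 3,
                        [60.0, 65.0, 70.0], 4300.0, exam_id="exam2")
        reg = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c"],
                "event_date": pd.to_datetime(["1995-05-01", "2010-01-01", "2030-01-01"]),
                "event_type": ["diagnosis", "death", "death"],
                "icd_version": ["ICD10", "", ""],
                "icd_code": ["C50", "", ""],
            }
        )
        return coh, reg

    def test_prevalent_cases_excluded(self):
        coh, reg = self._mini()
        fu = association.build_followup(coh, reg, association.ENDPOINTS["cancer"])
        assert "a" not in set(fu["participant_id"])
        assert fu.attrs["n_prevalent_excluded"] == 1

    def test_death_censors_disease_analysis(self):
        coh, reg = self._mini()
        reg = reg.copy()
        reg.loc[reg["participant_id"] == "b", "event_date"] = pd.Timestamp("2008-01-01")
        fu = association.build_followup(coh, reg, association.ENDPOINTS["cancer"])
        b = fu.set_index("participant_id").loc["b"]
        assert b["exit_date"] == pd.Timestamp("2008-01-01")
        assert not b["event_indicator"]

    def test_event_free_exit_at_censor_date(self):
        coh, reg = self._mini()
        fu = association.build_followup(coh, reg, association.ENDPOINTS["cancer"])
        c = fu.set_index("participant_id").loc["c"]
        assert c["exit_date"] == pd.Timestamp("2009-12-31")
        assert not c["event_indicator"]

    def test_mortality_uses_death_as_event(self):
        coh, reg = self._mini()
        fu = association.build_followup(coh, reg, association.ENDPOINTS["all_cause_mortality"])
        b = fu.set_index("participant_id").loc["b"]
        assert b["event_indicator"]
        c = fu.set_index("participant_id").loc["c"]
        assert c["exit_date"] == pd.Timestamp("2011-06-07") and not c["event_indicator"]

    def test_accounting_identity(self, small_cohort, registry):
        """Included participants plus prevalent exclusions reconstitute the
        cohort for every endpoint."""
        _, tabs = small_cohort
        for d in association.ENDPOINTS.values():
            fu = association.build_followup(tabs["exam2"], registry, d)
            assert len(fu) + fu.attrs["n_prevalent_excluded"] == len(tabs["exam2"])
            assert (fu["exit_date"] >= fu["entry_date"]).all()


class TestCoxQuartiles:
    def test_reference_quartile_hr_is_one(self, small_cohort, registry):
        _, tabs = small_cohort
        ch = longitudinal.build_change_table(tabs["exam1"], tabs["exam2"])
        base = tabs["exam2"].merge(ch[["participant_id", "change_quartile"]], on="participant_id")
        fu = association.build_followup(base, registry, association.ENDPOINTS["all_cause_mortality"])
        fit = association.fit_cox_quartiles(fu, "change_quartile")
        q1 = fit["table"][fit["table"]["quartile"] == 1].iloc[0]
        assert q1["hr"] == 1.0 and q1["ci_low"] == 1.0 and q1["ci_high"] == 1.0
        assert 0 <= fit["trend_p"] <= 1

    def test_injected_trend_recovered(self, rng):
        """A per-quartile-step log-HR of 0.2 is recovered by the trend fit."""
        n = 20000
        q = rng.integers(1, 5, n)
        lam = 0.05 * np.exp(0.2 * (q - 1))
        T = rng.exponential(1 / lam)
        E = T < 10
        fu = pd.DataFrame(
            {"followup_years": np.minimum(T, 10), "event_indicator": E, "change_quartile": q}
        )
        fit = association.fit_cox_quartiles(fu, "change_quartile")
        assert fit["trend_log_hr"] == pytest.approx(0.2, abs=0.05)

    def test_no_events_rejected(self):
        fu = pd.DataFrame(
            {"followup_years": [1.0] * 8, "event_indicator": [False] * 8,
             "change_quartile": [1, 2, 3, 4] * 2}
        )
        with pytest.raises(ValueError, match="no events"):
            association.fit_cox_quartiles(fu, "change_quartile")


class TestPhDiagnostic:
    def _weibull_group(self, rng, n, scale, shape=1.5, label="g"):
        T = scale * rng.weibull(shape, n)
        E = T < 8
        return pd.DataFrame(
            {"followup_years": np.minimum(T, 8), "event_indicator": E, "group": label}
        )

    def test_proportional_hazards_curves_parallel(self, rng):
        """Weibull groups with shared shape have proportional hazards: the
        log-minus-log curves differ by a constant."""
        a = self._weibull_group(rng, 4000, 6.0, label="a")
        b = self._weibull_group(rng, 4000, 9.0, label="b")
        res = association.ph_diagnostic(pd.concat([a, b]), "group")
        assert res["distance"] < 0.25

    def test_identical_groups_near_zero_distance(self, rng):
        a = self._weibull_group(rng, 3000, 6.0, label="a")
        b = a.assign(group="b")
        res = association.ph_diagnostic(pd.concat([a, b]), "group")
        assert res["distance"] == pytest.approx(0.0, abs=1e-9)

    def test_crossing_hazards_flagged(self, rng):
        a = self._weibull_group(rng, 4000, 6.0, shape=0.6, label="a")
        b = self._weibull_group(rng, 4000, 6.0, shape=3.0, label="b")
        res = association.ph_diagnostic(pd.concat([a, b]), "group")
        assert res["distance"] > 0.5
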