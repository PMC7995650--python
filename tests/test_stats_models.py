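import numpy as np
import pandas as pd
import pytest

from wmh_subclass.phantom import generate_cohort
from wmh_subclass.stats_models import (
    COVARIATES,
    CollinearityError,
    DegenerateOutcomeError,
    bonferroni_adjust,
    fit_glm_type3,
    pearson_correlations,
    run_model_family,
)

from _oracles import glh_term_f, normal_equations_ols


def _random_cohort_frame(rng, n=120):
    df = pd.DataFrame(
        {
            "age": rng.uniform(60, 83, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.uniform(13, 28, n),
            "systolic": rng.normal(141, 17, n),
            "diastolic": rng.normal(77, 10, n),
        }
    )
    df["score"] = (
        2.0 - 0.05 * df["age"] + 0.3 * df["sex"] + rng.standard_normal(n)
    )
    return df


class TestFitGlmType3:
    def test_single_predictor_f_equals_t_squared(self, rng):
        n = 80
        df = pd.DataFrame({"x": rng.standard_normal(n)})
        df["y"] = 1.0 + 0.5 * df["x"] + rng.standard_normal(n)
        res = fit_glm_type3(df, "y", ["x"])
        t_sq = (res.terms["x"].beta / res.terms["x"].se) ** 2
        assert res.terms["x"].f_type3 == pytest.approx(t_sq, rel=1e-10)

    def test_exact_linear_outcome(self, rng):
        df = pd.DataFrame({"age": rng.uniform(60, 80, 30)})
        df["y"] = 2.0 * df["age"]
        res = fit_glm_type3(df, "y", ["age"])
        assert res.terms["age"].beta == pytest.approx(2.0, rel=1e-10)
        assert res.r2 == pytest.approx(1.0)
        assert np.isinf(res.model_f) and res.model_p == 0.0

    def test_beta_se_match_normal_equations(self, rng):
        df = _random_cohort_frame(rng)
        res = fit_glm_type3(df, "score", list(COVARIATES))
        X = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy() for c in COVARIATES]
        )
        beta, se = normal_equations_ols(X, df["score"].to_numpy())
        for j, term in enumerate(COVARIATES):
            assert res.terms[term].beta == pytest.approx(beta[j + 1], rel=1e-8)
            assert res.terms[term].se == pytest.approx(se[j + 1], rel=1e-8)

    def test_type3_matches_general_linear_hypothesis(self, rng):
        df = _random_cohort_frame(rng)
        res = fit_glm_type3(df, "score", list(COVARIATES))
        X = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy() for c in COVARIATES]
        )
        y = df["score"].to_numpy()
        for j, term in enumerate(COVARIATES):
            assert res.terms[term].f_type3 == pytest.approx(
                glh_term_f(X, y, j + 1), rel=1e-10
            )

    def test_string_sex_coding_matches_numeric(self, rng):
        df = _random_cohort_frame(rng)
        df2 = df.copy()
        df2["sex"] = np.where(df["sex"] > 0, "M", "F")
        r1 = fit_glm_type3(df, "score", list(COVARIATES))
        r2 = fit_glm_type3(df2, "score", list(COVARIATES))
        for term in COVARIATES:
            assert r1.terms[term].f_type3 == pytest.approx(
                r2.terms[term].f_type3, rel=1e-10
            )

    def test_listwise_deletion_reports_n(self, rng):
        df = _random_cohort_frame(rng, n=50)
        df.loc[3, "age"] = np.nan
        df.loc[7, "score"] = np.nan
        res = fit_glm_type3(df, "score", list(COVARIATES))
        assert res.n_used == 48

    def test_collinearity_named(self, rng):
        df = _random_cohort_frame(rng)
        df["age2"] = df["age"] * 2.0
        with pytest.raises(CollinearityError, match="age2"):
            fit_glm_type3(df, "score", ["age", "age2"])

    def test_constant_outcome_rejected(self, rng):
        df = _random_cohort_frame(rng)
        df["score"] = 5.0
        with pytest.raises(DegenerateOutcomeError):
            fit_glm_type3(df, "score", ["age"])

    def test_missing_column_rejected(self, rng):
        df = _random_cohort_frame(rng)
        with pytest.raises(ValueError, match="nope"):
            fit_glm_type3(df, "score", ["nope"])


class TestModelFamily:
    def test_one_result_per_outcome(self):
        table, _ = generate_cohort(60, seed=11)
        results = run_model_family(table, mode="total")
        assert len(results) == 12
        assert set(results) == set(
            c for c in table.df.columns if c in results
        )

    def test_subclass_mode_has_nine_terms(self):
        table, _ = generate_cohort(60, seed=11)
        results = run_model_family(table, mode="subclass", outcomes=["moca"])
        assert len(results["moca"].terms) == 9

    def test_total_mode_has_six_terms(self):
        table, _ = generate_cohort(60, seed=11)
        results = run_model_family(table, mode="total", outcomes=["moca"])
        assert len(results["moca"].terms) == 6

    def test_bonferroni_family_defaults_to_outcome_count(self):
        table, _ = generate_cohort(60, seed=11)
        results = run_model_family(table, mode="total")
        assert results["moca"].m_bonferroni == 12

    def test_unknown_mode(self):
        table, _ = generate_cohort(20, seed=1)
        with pytest.raises(ValueError, match="mode"):
            run_model_family(table, mode="bogus")

    def test_missing_predictor_column(self):
        table, _ = generate_cohort(20, seed=1)
        df = table.df.drop(columns=["log_total"])
        with pytest.raises(ValueError, match="log_total"):
            run_model_family(df, mode="total")


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(20)})
        res = pearson_correlations(df, ["x"])
        assert res.r.loc["x", "x"] == 1.0

    def test_negated_variable(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(20)})
        df["neg"] = -df["x"]
        res = pearson_correlations(df, ["x", "neg"])
        assert res.r.loc["x", "neg"] == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        """x=(1,2,3,4), y=(1,3,2,4): r = 4/5 with p from t on df 2."""
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        res = pearson_correlations(df, ["x", "y"])
        assert res.r.loc["x", "y"] == pytest.approx(0.8, rel=1e-12)
        from scipy import stats

        t = 0.8 * np.sqrt(2 / (1 - 0.64))
        assert res.p.loc["x", "y"] == pytest.approx(2 * stats.t.sf(t, 2), rel=1e-9)

    def test_zero_variance_flagged_not_nan_propagated(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(10), "c": np.ones(10)})
        res = pearson_correlations(df, ["x", "c"])
        assert res.flagged.loc["x", "c"]
        assert not res.flagged.loc["x", "x"]

    def test_pairwise_complete(self, rng):
        df = pd.DataFrame(
            {"x": rng.standard_normal(10), "y": rng.standard_normal(10)}
        )
        df.loc[0, "y"] = np.nan
        res = pearson_correlations(df, ["x", "y"])
        assert res.n.loc["x", "y"] == 9


class TestBonferroni:
    def test_multiplication(self):
        assert bonferroni_adjust([0.004], 12) == pytest.approx([0.048])

    def test_cap_at_one(self):
        assert bonferroni_adjust([0.5], 3) == [1.0]

    def test_identity_at_m_one(self):
        assert bonferroni_adjust([0.2, 0.7], 1) == [0.2, 0.7]

    def test_invalid_family_size(self):
        with pytest.raises(ValueError, match=">= 1"):
            bonferroni_adjust([0.1], 0)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5], 2)
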