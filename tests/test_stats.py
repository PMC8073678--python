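"""Statistical battery: ANOVA, MANOVA, assumptions, partial correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from smiletrace.exceptions import InputError, ParameterError
from smiletrace.stats import (
    anova_two_group,
    bonferroni_threshold,
    check_assumptions,
    compare_demographics,
    partial_spearman,
    run_anova,
    run_manova,
)

from _reference import hotelling_t2_f, pearson_chi2


def two_group_frame(x, y, dv="dv"):
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(len(x) + len(y))],
        "group": ["ASD"] * len(x) + ["TD"] * len(y),
        dv: np.concatenate([x, y]),
    })


class TestBonferroni:
    def test_seven_test_family_threshold(self):
        assert round(bonferroni_threshold(0.05, 7), 5) == 0.00714

    def test_single_test_identity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_arithmetic(self):
        assert bonferroni_threshold(0.01, 5) == pytest.approx(0.002)

    def test_threshold_times_m_recovers_alpha(self):
        for m in (1, 3, 7, 20):
            assert bonferroni_threshold(0.05, m) * m == pytest.approx(0.05)

    def test_invalid_m(self):
        with pytest.raises(ParameterError):
            bonferroni_threshold(0.05, 0)


class TestAnova:
    def test_hand_computed_sums_of_squares(self):
        # {1,2,3} vs {4,5,6}: SSB = 13.5, SSW = 4 -> F(1,4) = 13.5
        res = run_anova(two_group_frame([1, 2, 3], [4, 5, 6]), "dv")
        assert res.F == pytest.approx(13.5)
        assert (res.df1, res.df2) == (1, 4)
        assert res.partial_eta2 == pytest.approx(13.5 / 17.5)

    def test_identical_groups_zero_f(self):
        res = run_anova(two_group_frame([1, 2, 3], [1, 2, 3]), "dv")
        assert res.F == 0.0
        assert res.partial_eta2 == 0.0

    def test_degenerate_zero_variance_unequal_means(self):
        f, *_ , eta2 = anova_two_group(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        assert np.isinf(f) and eta2 == 1.0

    def test_matches_scipy_f_oneway(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        res = run_anova(two_group_frame(x, y), "dv")
        f_ref, p_ref = sps.f_oneway(x, y)
        assert res.F == pytest.approx(f_ref)
        assert res.p_raw == pytest.approx(p_ref)

    def test_f_equals_squared_t(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 14)
        res = run_anova(two_group_frame(x, y), "dv")
        t, _ = sps.ttest_ind(x, y, equal_var=True)
        assert res.F == pytest.approx(t ** 2)

    def test_partial_eta2_affine_invariant(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        e1 = run_anova(two_group_frame(x, y), "dv").partial_eta2
        e2 = run_anova(two_group_frame(3 * x + 7, 3 * y + 7), "dv").partial_eta2
        assert e1 == pytest.approx(e2)

    def test_single_group_rejected(self):
        df = two_group_frame([1, 2], [])
        with pytest.raises(InputError):
            run_anova(df, "dv")

    def test_type_one_error_near_nominal(self, rng):
        # both groups from the same normal: rejection rate at alpha = 0.05
        # must fall in the exact binomial 99% band over 1000 replicates
        reps = 1000
        hits = 0
        for _ in range(reps):
            f, _, df2, p, _ = anova_two_group(rng.normal(size=18), rng.normal(size=15))
            hits += p < 0.05
        lo, hi = sps.binom.interval(0.99, reps, 0.05)
        assert lo <= hits <= hi


def manova_frame(X, labels, dvs):
    df = pd.DataFrame(X, columns=dvs)
    df["group"] = labels
    df["subject_id"] = [f"s{i}" for i in range(len(df))]
    return df


class TestManova:
    def test_identical_group_means_zero_pillai(self):
        block = np.array([[1.0, 2.0], [3.0, 1.0], [2.0, 2.5], [0.5, 1.5]])
        X = np.vstack([block, block])  # exact copies -> no between-group variance
        df = manova_frame(X, ["ASD"] * 4 + ["TD"] * 4, ["a", "b"])
        res = run_manova(df, ["a", "b"])
        assert res.statistic_value == pytest.approx(0.0, abs=1e-12)
        assert res.F_approx == pytest.approx(0.0, abs=1e-12)

    def test_single_dv_reduces_to_anova(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 8)
        df = two_group_frame(x, y)
        man = run_manova(df, ["dv"])
        an = run_anova(df, "dv")
        assert man.F_approx == pytest.approx(an.F)
        assert (man.df_between, man.df_error) == (an.df1, an.df2)
        assert man.p_value == pytest.approx(an.p_raw)

    def test_two_group_pillai_equals_hotelling_transform(self, rng):
        for _ in range(50):
            p = int(rng.integers(1, 5))
            n1, n2 = int(rng.integers(p + 3, 15)), int(rng.integers(p + 3, 15))
            X1 = rng.normal(0, 1, (n1, p))
            X2 = rng.normal(0.4, 1, (n2, p))
            df = manova_frame(np.vstack([X1, X2]),
                              ["ASD"] * n1 + ["TD"] * n2, [f"v{i}" for i in range(p)])
            res = run_manova(df, [f"v{i}" for i in range(p)])
            _, f_ref, df1_ref, df2_ref = hotelling_t2_f(X1, X2)
            assert res.F_approx == pytest.approx(f_ref, rel=1e-9)
            assert (res.df_between, res.df_error) == (df1_ref, df2_ref)

    def test_matches_statsmodels_pillai(self, rng):
        sm = pytest.importorskip("statsmodels.multivariate.manova")
        X = np.vstack([rng.normal(0, 1, (12, 3)), rng.normal(0.7, 1, (10, 3))])
        labels = ["ASD"] * 12 + ["TD"] * 10
        df = manova_frame(X, labels, ["a", "b", "c"])
        res = run_manova(df, ["a", "b", "c"])
        exog = np.column_stack([np.ones(22), [1.0 if g == "ASD" else 0.0 for g in labels]])
        mv = sm.MANOVA(X, exog).mv_test(
            hypotheses=[("group", np.array([[0.0, 1.0]]), None)])
        table = mv.results["group"]["stat"]
        assert res.statistic_value == pytest.approx(
            float(table.loc["Pillai's trace", "Value"]), rel=1e-8)
        assert res.F_approx == pytest.approx(
            float(table.loc["Pillai's trace", "F Value"]), rel=1e-8)

    def test_collinear_dvs_informative_error(self):
        x = np.arange(10, dtype=float)
        df = manova_frame(np.column_stack([x, 2 * x]),
                          ["ASD"] * 5 + ["TD"] * 5, ["a", "b"])
        with pytest.raises(InputError, match="DV"):
            run_manova(df, ["a", "b"])

    def test_too_few_cases_rejected(self):
        df = manova_frame(np.ones((3, 2)) + np.arange(3)[:, None],
                          ["ASD", "ASD", "TD"], ["a", "b"])
        with pytest.raises(InputError):
            run_manova(df, ["a", "b"])


class TestAssumptions:
    def _frame(self, rng, n=30, p=3):
        X = rng.normal(0, 1, (n, p))
        return manova_frame(X, ["ASD"] * (n // 2) + ["TD"] * (n - n // 2),
                            [f"v{i}" for i in range(p)])

    def test_case_at_centroid_has_zero_distance(self, rng):
        df = self._frame(rng)
        dvs = ["v0", "v1", "v2"]
        df.loc[len(df) - 1, dvs] = df[dvs].iloc[:-1].mean()  # ~centroid
        rep = check_assumptions(df, dvs)
        # the centroid case has (nearly) the smallest distance
        assert rep.mahalanobis_d2[-1] == pytest.approx(rep.mahalanobis_d2.min(), abs=0.5)

    def test_identity_covariance_reduces_to_euclidean(self, rng):
        # large sample, unit covariance by construction: Mahalanobis ~ Euclidean
        n = 4000
        X = rng.normal(0, 1.0, (n, 2))
        X = (X - X.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(X.T))).T
        df = manova_frame(X, ["ASD"] * (n // 2) + ["TD"] * (n // 2), ["a", "b"])
        rep = check_assumptions(df, ["a", "b"])
        eucl2 = ((X - X.mean(0)) ** 2).sum(axis=1)
        np.testing.assert_allclose(rep.mahalanobis_d2, eucl2, rtol=1e-6, atol=1e-8)

    def test_duplicated_dv_flags_multicollinearity(self, rng):
        df = self._frame(rng)
        df["v2"] = df["v0"]
        rep = check_assumptions(df, ["v0", "v1", "v2"])
        assert rep.max_abs_pearson_r == pytest.approx(1.0)
        assert rep.multicollinearity_flag

    def test_small_cell_skips_shapiro_with_note(self, rng):
        df = self._frame(rng, n=5)  # ASD cell has n = 2
        rep = check_assumptions(df, ["v0", "v1", "v2"])
        assert any("Shapiro" in note for note in rep.notes)

    def test_levene_matches_scipy(self, rng):
        df = self._frame(rng)
        rep = check_assumptions(df, ["v0", "v1", "v2"])
        a = df.loc[df.group == "ASD", "v0"]
        b = df.loc[df.group == "TD", "v0"]
        f_ref, p_ref = sps.levene(a, b, center="mean")
        assert rep.levene["v0"] == (pytest.approx(f_ref), pytest.approx(p_ref))


class TestPartialSpearman:
    def _frame(self, rng, n=40):
        return pd.DataFrame({
            "x": rng.normal(0, 1, n),
            "y": rng.normal(0, 1, n),
            "iq": rng.normal(100, 15, n),
            "sex_code": rng.integers(0, 2, n).astype(float),
        })

    def test_orthogonal_covariates_recover_plain_spearman(self, rng):
        df = self._frame(rng, n=200)
        df["y"] = df["x"] * 0.7 + rng.normal(0, 0.5, 200)
        res = partial_spearman(df, "x", "y")
        rho_plain = sps.spearmanr(df["x"], df["y"]).statistic
        assert res.rho == pytest.approx(rho_plain, abs=0.05)

    def test_identical_columns_give_rho_one(self, rng):
        df = self._frame(rng)
        df["y"] = df["x"]
        res = partial_spearman(df, "x", "y")
        assert res.rho == pytest.approx(1.0)

    def test_constant_variable_missing_with_note(self, rng):
        df = self._frame(rng)
        df["x"] = 1.0
        res = partial_spearman(df, "x", "y")
        assert np.isnan(res.rho)
        assert "constant" in res.note

    def test_invariant_under_monotone_transforms(self, rng):
        df = self._frame(rng)
        df["y"] = df["x"] ** 3 + rng.normal(0, 0.5, len(df))
        r1 = partial_spearman(df, "x", "y").rho
        df2 = df.assign(x=np.exp(df["x"]), y=df["y"] ** 3)  # strictly monotone
        r2 = partial_spearman(df2, "x", "y").rho
        assert r1 == pytest.approx(r2)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = self._frame(rng)
        df["y"] = 0.5 * df["x"] + 0.01 * df["iq"] + rng.normal(0, 1, len(df))
        res = partial_spearman(df, "x", "y", ("iq", "sex_code"))
        ref = pg.partial_corr(df, x="x", y="y", covar=["iq", "sex_code"],
                              method="spearman")
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.p_value == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-10)

    def test_too_few_rows_noted(self, rng):
        df = self._frame(rng, n=3)
        res = partial_spearman(df, "x", "y")
        assert np.isnan(res.rho) and "few" in res.note


class TestDemographics:
    def _cohort(self, sex_asd, sex_td, age_asd=None, age_td=None):
        n1, n2 = len(sex_asd), len(sex_td)
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n1 + n2)],
            "group": ["ASD"] * n1 + ["TD"] * n2,
            "sex": sex_asd + sex_td,
            "age_months": (age_asd or [8.0] * n1) + (age_td or [9.0] * n2),
        })

    def test_identical_continuous_samples_t_zero(self):
        df = self._cohort(["M"] * 3, ["M"] * 3, [7, 8, 9], [7, 8, 9])
        out = compare_demographics(df, continuous=("age_months",))
        t = out.loc[out.variable == "age_months", "statistic"].iloc[0]
        assert t == pytest.approx(0.0)

    def test_sex_chi2_matches_hand_computation(self):
        df = self._cohort(["M"] * 17 + ["F"], ["M"] * 13 + ["F"] * 2)
        out = compare_demographics(df, continuous=())
        chi2 = out.loc[out.variable == "sex", "statistic"].iloc[0]
        assert chi2 == pytest.approx(pearson_chi2([[17, 1], [13, 2]]))

    def test_empty_group_rejected(self):
        df = self._cohort(["M"] * 4, [])
        with pytest.raises(InputError):
            compare_demographics(df)

    def test_single_category_skipped_with_note(self):
        df = self._cohort(["M"] * 4, ["M"] * 4)
        out = compare_demographics(df, continuous=())
        assert "absent" in out.loc[out.variable == "sex", "note"].iloc[0]
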