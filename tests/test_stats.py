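"""Statistics layer tests: gated comparisons, TOST, power, models."""
import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.weightstats import ttost_ind

from cardiovagal import stats as st


class TestCompareGroups:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        r = st.compare_groups(a, a.copy())
        assert r.cohens_d == 0.0
        assert r.p == pytest.approx(1.0)

    def test_cohens_d_matches_hand_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 2, 30), rng.normal(0, 2, 45)
        r = st.compare_groups(a, b)
        sp = np.sqrt(((29 * a.var(ddof=1)) + (44 * b.var(ddof=1))) / 73)
        assert r.cohens_d == pytest.approx((a.mean() - b.mean()) / sp)

    def test_normality_gate_switches_test(self):
        rng = np.random.default_rng(2)
        normal_a, normal_b = rng.normal(size=50), rng.normal(size=50)
        skewed = rng.exponential(size=200)
        assert st.compare_groups(normal_a, normal_b).test == "t-test"
        assert st.compare_groups(skewed, rng.exponential(size=200)).test == \
            "mann-whitney"

    def test_rejection_rate_matches_analytic_power(self):
        # d = 0.5 at n = 94/95: analytic power 0.93
        rng = np.random.default_rng(3)
        hits = 0
        reps = 300
        for _ in range(reps):
            a = rng.normal(0.5, 1, 94)
            b = rng.normal(0.0, 1, 95)
            hits += st.compare_groups(a, b).p < 0.05
        assert hits / reps == pytest.approx(0.93, abs=0.05)

    def test_bonferroni_attached(self):
        rng = np.random.default_rng(4)
        r = st.compare_groups(rng.normal(size=20), rng.normal(size=20),
                              bonferroni_factor=6)
        assert r.p_corrected == pytest.approx(min(1.0, r.p * 6))

    def test_zero_variance_both_groups(self):
        with pytest.raises(ValueError):
            st.compare_groups([1.0] * 5, [2.0] * 5)
        r = st.compare_groups([1.0] * 5, [1.0] * 5)
        assert r.p == 1.0

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            st.compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSignedRank:
    def test_all_positive_strongly_significant(self):
        r = st.signed_rank_vs_zero(np.linspace(0.5, 2.0, 20))
        assert r.p < 0.001

    def test_symmetric_deltas_not_significant(self):
        d = np.array([1.0, -1.0] * 10 + [0.5, -0.5] * 10)
        r = st.signed_rank_vs_zero(d)
        assert r.p > 0.5

    def test_zeros_dropped(self):
        d = np.array([0.0] * 10 + [1.0, 2.0, 3.0, 4.0, 5.0])
        r = st.signed_rank_vs_zero(d)
        assert r.p < 0.1  # only the 5 nonzero values enter

    def test_all_zeros_undefined(self):
        with pytest.raises(ValueError):
            st.signed_rank_vs_zero(np.zeros(10))


class TestTost:
    def test_identical_large_samples_equivalent(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 100)
        b = rng.normal(0, 1, 100)
        assert st.tost_equivalence(a, b, margin=2.0).equivalent

    def test_difference_at_margin_not_equivalent(self):
        rng = np.random.default_rng(6)
        b = rng.normal(0.0, 1, 200)
        a = b + 2.0  # sample mean difference exactly at the margin
        r = st.tost_equivalence(a, b, margin=2.0)
        assert not r.equivalent
        assert r.p_upper == pytest.approx(0.5)

    def test_icp_like_margins(self):
        # true difference 0, SD ~2 mmHg, margin 2 mmHg, n ~95/group
        rng = np.random.default_rng(7)
        a = rng.normal(0, 2, 95)
        b = rng.normal(0, 2, 94)
        r = st.tost_equivalence(a, b, margin=2.0)
        assert r.p_lower < 1e-5 and r.p_upper < 1e-5

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0.4, 1.5, 60)
        b = rng.normal(0.0, 1.5, 70)
        r = st.tost_equivalence(a, b, margin=1.0)
        _, (tl, pl, _), (tu, pu, _) = ttost_ind(a, b, -1.0, 1.0,
                                                usevar="pooled")
        assert r.t_lower == pytest.approx(tl)
        assert r.p_lower == pytest.approx(pl)
        assert r.t_upper == pytest.approx(tu)
        assert r.p_upper == pytest.approx(pu)

    def test_nonpositive_margin_rejected(self):
        with pytest.raises(ValueError):
            st.tost_equivalence([1.0, 2.0], [1.0, 2.0], margin=0.0)


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        assert st.power_two_sample_t(50, 50, 0.0, 0.05) == pytest.approx(0.05)

    def test_monotone_in_n_and_d(self):
        p_n = [st.power_two_sample_t(n, n, 0.5) for n in (10, 20, 40, 80)]
        assert all(np.diff(p_n) > 0)
        p_d = [st.power_two_sample_t(30, 30, d) for d in (0.2, 0.5, 0.8)]
        assert all(np.diff(p_d) > 0)

    def test_required_n_round_trip(self):
        for d in (0.3, 0.5, 0.8):
            n = st.required_n(0.80, d)
            assert st.power_two_sample_t(n, n, d) >= 0.80
            assert st.power_two_sample_t(n - 1, n - 1, d) < 0.80

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            st.power_two_sample_t(1, 50, 0.5)
        with pytest.raises(ValueError):
            st.required_n(1.5, 0.5)


class TestInteractionRegression:
    @staticmethod
    def _table(slope_diff=2.0, n_per_arm=400, noise=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for arm, extra in (("Sham", 0.0), ("taVNS", slope_diff)):
            days = rng.integers(2, 13, n_per_arm)
            y = -3.0 * days + extra * days + rng.normal(0, noise, n_per_arm)
            rows.append(pd.DataFrame({"day": days, "arm": arm,
                                      "rmssd_change": y}))
        return pd.concat(rows, ignore_index=True)

    def test_known_slope_difference_recovered(self):
        out = st.interaction_regression(self._table(slope_diff=2.0))
        assert out.loc["day:treat", "coef"] == pytest.approx(2.0, abs=0.1)

    def test_identical_arms_null_interaction(self):
        out = st.interaction_regression(self._table(slope_diff=0.0, seed=1))
        assert abs(out.loc["day:treat", "coef"]) < 0.1
        assert out.loc["day:treat", "p"] > 0.05

    def test_matches_normal_equations(self):
        df = self._table(n_per_arm=5, seed=2)
        out = st.interaction_regression(df)
        x = np.column_stack([
            np.ones(len(df)), df.day,
            (df.arm == "taVNS").astype(float),
            df.day * (df.arm == "taVNS").astype(float),
        ])
        beta = np.linalg.solve(x.T @ x, x.T @ df.rmssd_change)
        np.testing.assert_allclose(out.coef.to_numpy(), beta, rtol=1e-8)

    def test_rank_deficiency_rejected(self):
        df = self._table(n_per_arm=10, seed=3)
        df["day"] = 5  # constant day -> day:treat collinear with treat
        with pytest.raises(ValueError):
            st.interaction_regression(df)


class TestMixedModel:
    @staticmethod
    def _sessions(beta_int=-1.85, subject_sd=1.0, seed=0, n_subjects=24,
                  n_sessions=8):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            arm = "taVNS" if s < n_subjects // 2 else "Sham"
            mrs = int(rng.integers(-3, 3))
            u = rng.normal(0, subject_sd)
            t = 1.0 if arm == "taVNS" else 0.0
            for _ in range(n_sessions):
                y = 0.73 - 0.29 * t + 1.47 * mrs + beta_int * t * mrs + u \
                    + rng.normal(0, 2.0)
                rows.append(dict(subject=f"s{s}", arm=arm, mrs_change=mrs,
                                 hr_delta=y))
        return pd.DataFrame(rows)

    def test_interaction_recovered_on_average(self):
        ests = [st.fit_mixed_model(self._sessions(seed=s)).params["treat:mrs"]
                for s in range(30)]
        assert np.mean(ests) == pytest.approx(-1.85, rel=0.1)

    def test_zero_random_variance_matches_ols(self):
        import statsmodels.formula.api as smf
        df = self._sessions(subject_sd=0.0, seed=5)
        mm = st.fit_mixed_model(df)
        df2 = df.rename(columns={"hr_delta": "y", "mrs_change": "mrs"})
        df2["treat"] = (df2.arm == "taVNS").astype(float)
        ols = smf.ols("y ~ treat + mrs + treat:mrs", df2).fit()
        for name in ("treat", "mrs", "treat:mrs"):
            key = name if name in mm.params.index else name
            assert mm.params[key] == pytest.approx(ols.params[name], abs=0.05)

    def test_all_zero_response_zero_coefficients(self):
        df = self._sessions(seed=6)
        df["hr_delta"] = 0.0
        mm = st.fit_mixed_model(df)
        np.testing.assert_allclose(mm.params.to_numpy(), 0.0, atol=1e-8)

    def test_ci_contains_point_estimate(self):
        mm = st.fit_mixed_model(self._sessions(seed=7))
        for name in mm.params.index:
            lo, hi = mm.conf_int.loc[name]
            assert lo <= mm.params[name] <= hi


class TestAncovaAge:
    def test_age_effect_recovered_no_arm_effect(self):
        rng = np.random.default_rng(9)
        age = rng.choice([35, 45, 55, 65, 75], 300).astype(float)
        y = -0.5 * age + rng.normal(0, 2, 300)
        df = pd.DataFrame({"rmssd_change": y, "age": age,
                           "arm": rng.choice(["taVNS", "Sham"], 300)})
        out = st.ancova_age(df, response="rmssd_change")
        assert out.loc["age", "coef"] == pytest.approx(-0.5, abs=0.05)
        assert abs(out.loc["treat", "coef"]) < 0.5

    def test_uncorrelated_age_leaves_arm_effect(self):
        rng = np.random.default_rng(10)
        arm = np.repeat(["taVNS", "Sham"], 150)
        y = 2.0 * (arm == "taVNS") + rng.normal(0, 1, 300)
        df = pd.DataFrame({"rmssd_change": y, "arm": arm,
                           "age": rng.choice([40, 60, 80], 300).astype(float)})
        out = st.ancova_age(df, response="rmssd_change")
        unadj = y[arm == "taVNS"].mean() - y[arm == "Sham"].mean()
        assert out.loc["treat", "coef"] == pytest.approx(unadj, abs=0.2)

    def test_constant_age_dropped(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"rmssd_change": rng.normal(size=40),
                           "arm": ["taVNS", "Sham"] * 20,
                           "age": [60.0] * 40})
        out = st.ancova_age(df, response="rmssd_change")
        assert "age" not in out.index


class TestPearson:
    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, p = st.pearson_corr(x, -x)
        assert r == pytest.approx(-1.0)
        assert p < 1e-9

    def test_null_type_one_error(self):
        rng = np.random.default_rng(12)
        hits = sum(st.pearson_corr(rng.normal(size=30),
                                   rng.normal(size=30))[1] < 0.05
                   for _ in range(400))
        assert hits / 400 == pytest.approx(0.05, abs=0.03)

    def test_population_rho_recovered(self):
        rng = np.random.default_rng(13)
        rhos = []
        for _ in range(50):
            cov = [[1, -0.37], [-0.37, 1]]
            xy = rng.multivariate_normal([0, 0], cov, size=130)
            rhos.append(st.pearson_corr(xy[:, 0], xy[:, 1])[0])
        assert np.mean(rhos) == pytest.approx(-0.37, abs=0.03)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            st.pearson_corr([1.0] * 10, np.arange(10.0))
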