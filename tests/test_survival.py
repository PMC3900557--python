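"""KM/log-rank and Cox fits against permutation and partial-likelihood oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import ionsig as isg


def breslow_partial_loglik(beta, times, events, x):
    """Explicit Cox partial log-likelihood (no tied event times)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


@pytest.fixture
def two_group_exponential():
    """Binary covariate with true hazard ratio 2, n = 2000."""
    rng = np.random.default_rng(100)
    n = 2000
    x = rng.integers(0, 2, n)
    rate = 3e-4 * np.exp(np.log(2.0) * x)
    event_time = rng.exponential(1.0 / rate)
    censor = rng.uniform(0, 3650, n)
    t = np.minimum(event_time, censor)
    e = (event_time <= censor).astype(int)
    return t, e, x


class TestKMLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([5.0, 10.0, 15.0, 20.0] * 2)
        e = np.array([1, 0, 1, 1] * 2)
        g = np.array(["a"] * 4 + ["b"] * 4)
        km = isg.km_logrank(t, e, g)
        assert km.logrank_stat == pytest.approx(0.0, abs=1e-12)
        assert km.logrank_p == pytest.approx(1.0)

    def test_no_censoring_equals_empirical_survival(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 20.0])
        e = np.ones(6, dtype=int)
        g = np.array(["a"] * 3 + ["b"] * 3)
        km = isg.km_logrank(t, e, g)
        curve = km.curves["a"]
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[2.0] == pytest.approx(1 / 3)
        assert surv[3.0] == pytest.approx(0.0)

    def test_curve_flat_beyond_last_event(self):
        t = np.array([1.0, 2.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 0])
        g = np.array(["a", "a", "b", "b"])
        km = isg.km_logrank(t, e, g)
        assert km.survival_at("a", 100.0) == km.survival_at("a", 2.0)

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(0)
        t = np.array([3.0, 5.0, 7.0, 2.0, 12.0, 9.0, 4.0, 8.0, 6.0, 11.0,
                      1.0, 10.0])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0, 1, 1])
        g = np.array(["a"] * 6 + ["b"] * 6)
        observed = isg.km_logrank(t, e, g)
        B = 1500
        exceed = 0
        for _ in range(B):
            perm = rng.permutation(g)
            stat = isg.km_logrank(t, e, perm).logrank_stat
            exceed += stat >= observed.logrank_stat - 1e-12
        p_perm = (1 + exceed) / (B + 1)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(observed.logrank_p - p_perm) < mc_err + 0.05

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            isg.km_logrank([1.0, 2.0], [1, 1], ["a", "a"])

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            isg.km_logrank([1.0, 2.0], [0, 0], ["a", "b"])


class TestCoxUnivariate:
    def test_recovers_true_hazard_ratio(self, two_group_exponential):
        t, e, x = two_group_exponential
        fit = isg.cox_univariate(t, e, x, name="group")
        assert 1.8 <= fit.hr("group") <= 2.2
        lo, hi = fit.table.loc["group", ["ci_low", "ci_high"]]
        assert lo < fit.hr("group") < hi

    def test_null_calibration_type_one_error(self):
        rng = np.random.default_rng(7)
        n, reps = 120, 300
        rejections = 0
        for _ in range(reps):
            x = rng.integers(0, 2, n)
            event_time = rng.exponential(1000.0, n)
            censor = rng.uniform(0, 2000, n)
            t = np.minimum(event_time, censor)
            e = (event_time <= censor).astype(int)
            fit = isg.cox_univariate(t, e, x)
            rejections += fit.p("covariate") < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_coefficient_matches_brute_force_partial_likelihood(self):
        t = np.array([2.0, 5.0, 7.0, 11.0])
        e = np.array([1, 1, 1, 1])
        x = np.array([0.5, -0.3, 1.2, 0.1])
        fit = isg.cox_univariate(t, e, x)
        opt = minimize_scalar(
            lambda b: -breslow_partial_loglik(b, t, e, x),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10})
        assert fit.coef("covariate") == pytest.approx(opt.x, abs=1e-6)
        assert isg.cox_coef_fast(t, e, x) == pytest.approx(opt.x, abs=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            isg.cox_univariate([1.0, 2.0], [1, 1], [3.0, 3.0])

    def test_sign_matches_simulated_direction(self):
        rng = np.random.default_rng(30)
        agree = 0
        reps = 60
        for _ in range(reps):
            n = 150
            x = rng.integers(0, 2, n)
            event_time = rng.exponential(1.0 / (1e-3 * np.exp(0.7 * x)))
            censor = rng.uniform(0, 2000, n)
            t = np.minimum(event_time, censor)
            e = (event_time <= censor).astype(int)
            agree += isg.cox_coef_fast(t, e, x) > 0
        assert agree / reps >= 0.95


class TestCoxFastSolver:
    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(44)
        for trial in range(5):
            n = 80
            x = rng.normal(size=n)
            # integer times force ties; Efron handling must match lifelines
            t = np.ceil(rng.exponential(20, n))
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            fit = isg.cox_univariate(t, e, x)
            fast = isg.cox_coef_fast(t, e, x)
            assert fast == pytest.approx(fit.coef("covariate"), abs=1e-6)


class TestCoxMultivariate:
    def test_joint_recovery_with_null_covariates(self):
        rng = np.random.default_rng(60)
        n = 1000
        status = rng.integers(0, 2, n)
        age = rng.normal(65, 8, n)
        stage = rng.choice([1, 2, 3], n)
        rate = 3e-4 * np.exp(np.log(2.0) * status)
        event_time = rng.exponential(1.0 / rate)
        censor = rng.uniform(0, 3650, n)
        t = np.minimum(event_time, censor)
        e = (event_time <= censor).astype(int)
        X = pd.DataFrame({"status": status, "age": age, "stage": stage})
        fit = isg.cox_multivariate(t, e, X)
        assert 1.7 <= fit.hr("status") <= 2.3
        assert 0.8 <= fit.hr("stage") <= 1.25

    def test_duplicated_column_rank_error(self):
        rng = np.random.default_rng(1)
        n = 50
        x = rng.normal(size=n)
        X = pd.DataFrame({"a": x, "b": x})
        t = rng.exponential(10, n)
        e = np.ones(n, dtype=int)
        with pytest.raises(ValueError, match="collinear.*b"):
            isg.cox_multivariate(t, e, X)

    def test_single_covariate_equals_univariate(self, two_group_exponential):
        t, e, x = two_group_exponential
        uni = isg.cox_univariate(t, e, x, name="g")
        multi = isg.cox_multivariate(t, e, pd.DataFrame({"g": x}))
        assert multi.coef("g") == pytest.approx(uni.coef("g"), abs=1e-8)
        assert multi.p("g") == pytest.approx(uni.p("g"), abs=1e-8)

    def test_encode_clinical_mapping(self):
        df = pd.DataFrame({
            "age": [60, 70], "gender": ["M", "F"], "stage": [1, 3],
            "smoking": ["ever", "never"], "myc": ["high", "low"],
            "mutation": ["+", "-"],
        }, index=["S1", "S2"])
        enc = isg.encode_clinical(df)
        assert enc.loc["S1"].tolist() == [60.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        assert enc.loc["S2"].tolist() == [70.0, 0.0, 3.0, 0.0, 0.0, 0.0]


class TestCoxContinuousScore:
    def test_per_point_increase_identity(self, two_group_exponential):
        t, e, x = two_group_exponential
        fit = isg.cox_continuous_score(t, e, x.astype(float))
        assert fit.per_point_increase("score") == pytest.approx(
            np.exp(fit.coef("score")) - 1.0, abs=1e-12)

    def test_recovers_small_per_point_effect(self):
        rng = np.random.default_rng(90)
        n = 2000
        scores = rng.normal(0, 6, n)
        rate = 3e-4 * np.exp(0.03 * scores)
        event_time = rng.exponential(1.0 / rate)
        censor = rng.uniform(0, 3650, n)
        t = np.minimum(event_time, censor)
        e = (event_time <= censor).astype(int)
        fit = isg.cox_continuous_score(t, e, scores)
        assert 0.01 <= fit.per_point_increase("score") <= 0.05

    def test_permuted_scores_near_null(self):
        rng = np.random.default_rng(91)
        n = 1500
        scores = rng.normal(0, 6, n)
        rate = 3e-4 * np.exp(0.05 * scores)
        event_time = rng.exponential(1.0 / rate)
        t = np.minimum(event_time, rng.uniform(0, 3650, n))
        e = (event_time <= np.maximum(t, event_time) * 0 + t).astype(int)
        permuted = rng.permutation(scores)
        fit = isg.cox_continuous_score(t, e, permuted)
        assert abs(fit.per_point_increase("score")) < 0.02

    def test_halving_score_doubles_coefficient(self, two_group_exponential):
        t, e, x = two_group_exponential
        full = isg.cox_continuous_score(t, e, x.astype(float))
        half = isg.cox_continuous_score(t, e, x / 2.0)
        assert half.coef("score") == pytest.approx(2 * full.coef("score"),
                                                   rel=1e-6)
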