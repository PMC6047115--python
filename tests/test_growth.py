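import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magicqtl.growth import (FourPLParams, GompertzParams, LogisticParams,
                             eval_4pl, eval_gompertz, eval_logistic,
                             fit_growth_model, fit_polynomial, r_squared,
                             select_model)

DAS = np.arange(90.0, 201.0, 2.0)


class TestEvaluation:
    def test_logistic_midpoint_and_limit(self):
        p = LogisticParams(L=100.0, k=0.2, t0=120.0)
        assert eval_logistic(p, 120.0) == pytest.approx(50.0, abs=1e-12)
        # k -> 0 flattens the curve at L/2
        flat = LogisticParams(L=100.0, k=0.0, t0=120.0)
        assert eval_logistic(flat, 500.0) == pytest.approx(50.0, abs=1e-12)

    def test_logistic_scalar_arithmetic(self):
        p = LogisticParams(L=100.0, k=0.2, t0=120.0)
        expected = 100.0 / (1.0 + math.exp(-6.0))
        assert eval_logistic(p, 150.0) == pytest.approx(expected, rel=1e-14)

    def test_4pl_halfway_identities(self):
        p = FourPLParams(A=10.0, B=11.0, C=130.0, D=90.0)
        assert eval_4pl(p, 130.0) == pytest.approx(50.0, abs=1e-12)
        # B = 0 gives (A+D)/2 everywhere
        p0 = FourPLParams(A=10.0, B=0.0, C=130.0, D=90.0)
        assert eval_4pl(p0, 95.0) == pytest.approx(50.0, abs=1e-12)

    def test_4pl_scalar_arithmetic(self):
        p = FourPLParams(A=0.0, B=11.0, C=130.0, D=100.0)
        expected = 100.0 + (0.0 - 100.0) / (1.0 + 2.0**11)
        assert eval_4pl(p, 260.0) == pytest.approx(expected, rel=1e-12)

    def test_4pl_rejects_nonpositive_time(self):
        p = FourPLParams(A=0.0, B=11.0, C=130.0, D=100.0)
        with pytest.raises(ValueError):
            eval_4pl(p, 0.0)

    def test_gompertz_limits_and_value(self):
        p = GompertzParams(a=100.0, b=5.0, c=0.05)
        assert eval_gompertz(p, 1e9) == pytest.approx(100.0, rel=1e-12)
        assert eval_gompertz(p, 0.0) == pytest.approx(100.0 * math.exp(-5.0),
                                                      rel=1e-12)
        expected = 100.0 * math.exp(-5.0 * math.exp(-2.0))
        assert eval_gompertz(p, 40.0) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(-1e6, 1e6), st.floats(-50, 50), st.floats(-1e4, 1e4),
           st.floats(-1e4, 1e4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_logistic_finite_for_finite_inputs(self, L, k, t0, t):
        assert np.isfinite(eval_logistic(LogisticParams(L, k, t0), t))

    @given(st.floats(-1e6, 1e6), st.floats(0.001, 1e6), st.floats(0, 10),
           st.floats(0.001, 1e4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gompertz_finite_for_finite_inputs(self, a, b, c, t):
        assert np.isfinite(eval_gompertz(GompertzParams(a, b, c), t))


class TestRSquared:
    def test_perfect_null_and_hand_example(self):
        y = [1.0, 2.0, 3.0]
        assert r_squared(y, y) == pytest.approx(1.0, abs=1e-15)
        assert r_squared(y, [2.0, 2.0, 2.0]) == pytest.approx(0.0, abs=1e-15)
        assert r_squared(y, [1.0, 2.0, 4.0]) == pytest.approx(0.5, rel=1e-14)

    def test_constant_observations_rejected(self):
        with pytest.raises(ValueError):
            r_squared([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


class TestFitting:
    @pytest.mark.parametrize("model,true_params", [
        ("logistic", (95000.0, 0.15, 128.0)),
        ("4pl", (1500.0, 11.0, 130.0, 85000.0)),
        ("gompertz", (85000.0, 40.0, 0.03)),
    ])
    def test_noiseless_round_trip(self, model, true_params):
        from magicqtl.growth import _eval_model
        theta = np.array(true_params)
        y = _eval_model(model, theta, DAS)
        fit = fit_growth_model(DAS, y, model)
        assert fit.converged
        rel = np.abs(np.array(list(fit.param_dict().values())) - theta) / \
            np.maximum(np.abs(theta), 1.0)
        assert rel.max() < 1e-4
        assert fit.r_squared > 1 - 1e-10

    def test_constant_series_never_crashes(self):
        y = np.full(DAS.size, 42.0)
        fit = fit_growth_model(DAS, y, "4pl")
        # degenerate: either flagged or asymptotes collapse; R2 is NaN
        assert math.isnan(fit.r_squared) or not fit.converged

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            fit_growth_model([100.0, 110.0, 120.0], [1.0, 2.0, 3.0], "4pl")

    def test_slope_unbiased_under_noise(self):
        # 2% observation noise on D should not bias the recovered slope B
        rng = np.random.default_rng(42)
        true = FourPLParams(A=0.0, B=11.0, C=130.0, D=100.0)
        clean = np.asarray(eval_4pl(true, DAS))
        est = []
        for _ in range(60):
            y = clean + 2.0 * rng.standard_normal(DAS.size)
            fit = fit_growth_model(DAS, y, "4pl")
            if fit.converged:
                est.append(fit.params.B)
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - 11.0) < 2 * se + 1e-6


class TestPolynomial:
    def test_exact_parabola(self):
        t = np.arange(10.0)
        y = 3.0 - 2.0 * t + 0.5 * t**2
        fit = fit_polynomial(t, y, 2)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.params.coefficients == pytest.approx((3.0, -2.0, 0.5),
                                                        abs=1e-9)

    def test_nested_degrees_monotone_r2(self):
        rng = np.random.default_rng(0)
        t = np.arange(20.0)
        y = np.sin(t / 3.0) + 0.1 * rng.standard_normal(20)
        r2 = {d: fit_polynomial(t, y, d).r_squared for d in (2, 3, 4)}
        assert r2[4] >= r2[3] - 1e-12 >= r2[2] - 2e-12

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 5, 10)
        y = rng.standard_normal(10)
        fit = fit_polynomial(t, y, 3)
        X = np.vander(t, 4, increasing=True)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.params.coefficients, beta, atol=1e-8)

    def test_rank_deficiency_rejected(self):
        t = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            fit_polynomial(t, t, 2)


class TestModelSelection:
    def test_best_r2_wins_and_nesting(self):
        true = FourPLParams(A=5000.0, B=9.0, C=130.0, D=90000.0)
        y = np.asarray(eval_4pl(true, DAS))
        fits = [fit_growth_model(DAS, y, m)
                for m in ("logistic", "4pl", "gompertz")]
        best = select_model(fits)
        assert best.model == "4pl"
        by_name = {f.model: f for f in fits}
        # 4PL nests the 3-parameter logistic shape (free bottom asymptote)
        assert by_name["4pl"].r_squared >= by_name["logistic"].r_squared - 1e-9

    def test_tie_prefers_fewer_parameters(self):
        from magicqtl.growth import FitResult
        a = FitResult("4pl", None, 0.9, 1.0, True, 10, n_params=4)
        b = FitResult("logistic", None, 0.9, 1.0, True, 10, n_params=3)
        assert select_model([a, b]).model == "logistic"

    def test_no_converged_fit_raises(self):
        from magicqtl.growth import FitResult
        bad = FitResult("4pl", None, -np.inf, np.inf, False, 10, 4)
        with pytest.raises(ValueError):
            select_model([bad])
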