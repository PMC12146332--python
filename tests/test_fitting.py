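import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from seedlapse.fitting import (
    FitResult,
    PolyCoeffs,
    differentiate,
    evaluate_poly,
    fit_family,
    potential_curve,
    r_squared,
    r_squared_residual,
    select_best,
)
from seedlapse.morphometry import GrowthSeries

# Printed growth cubics and their printed first derivatives, dishes 1-5.
# Dishes 6-8 carry typographical slips in the published derivative and are
# checked against exact differentiation instead (see test below).
TABLE7 = {
    1: ((0.062, -4.9082, 147.9527, 2144.1588), (0.186, -9.8164, 147.9527)),
    2: ((0.0603, -2.2675, -9.5724, 3729.579), (0.1809, -4.535, -9.5724)),
    3: ((0.0046, 1.0051, -57.4411, 4141.1599), (0.0138, 2.0102, -57.4411)),
    4: ((-0.0712, 8.3181, -277.671, 6509.3051), (-0.2136, 16.6362, -277.671)),
    5: ((-0.0886, 9.7247, -314.9538, 7424.7836), (-0.2658, 19.4494, -314.9538)),
}


def naive_poly_eval(coeffs, x):
    """Power-sum oracle, independent of the Horner path."""
    k = len(coeffs) - 1
    return sum(c * x ** (k - i) for i, c in enumerate(coeffs))


class TestPolyCoeffs:
    def test_leading_zero_rejected(self):
        with pytest.raises(ValueError):
            PolyCoeffs((0.0, 1.0, 2.0))

    def test_constant_allowed(self):
        assert PolyCoeffs((0.0,)).degree == 0


class TestEvaluatePoly:
    def test_square(self):
        assert evaluate_poly(PolyCoeffs((1.0, 0.0, 0.0)), 3) == 9

    def test_dish1_constant_term(self):
        p = PolyCoeffs(TABLE7[1][0])
        assert evaluate_poly(p, 0.0) == 2144.1588

    def test_matches_naive_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(0, 6))
            coeffs = rng.uniform(-5, 5, k + 1)
            if coeffs[0] == 0:
                coeffs[0] = 1.0
            p = PolyCoeffs(tuple(coeffs))
            x = float(rng.uniform(-3, 3))
            assert evaluate_poly(p, x) == pytest.approx(naive_poly_eval(coeffs, x), rel=1e-9, abs=1e-9)

    def test_vectorized(self):
        p = PolyCoeffs((2.0, 1.0))
        assert np.allclose(evaluate_poly(p, np.array([0.0, 1.0, 2.0])), [1.0, 3.0, 5.0])


class TestDifferentiate:
    @pytest.mark.parametrize("dish", sorted(TABLE7))
    def test_table7_printed_derivatives(self, dish):
        cubic, printed = TABLE7[dish]
        derived = differentiate(PolyCoeffs(cubic)).coeffs
        assert derived == pytest.approx(printed, abs=1e-12)

    def test_constant_to_zero(self):
        assert differentiate(PolyCoeffs((5.0,))).coeffs == (0.0,)

    def test_degree_drops_by_one(self):
        p = PolyCoeffs((1.0, 2.0, 3.0, 4.0))
        assert differentiate(p).degree == 2

    @given(
        p_coeffs=st.lists(st.floats(-100, 100), min_size=1, max_size=6),
        q_offsets=st.lists(st.floats(-100, 100), min_size=6, max_size=6),
        alpha=st.floats(-10, 10),
        beta=st.floats(-10, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_linearity(self, p_coeffs, q_offsets, alpha, beta):
        # differentiate(a*p + b*q) == a*differentiate(p) + b*differentiate(q),
        # checked pointwise so coefficient-trimming bookkeeping is irrelevant.
        q_coeffs = [c + o for c, o in zip(p_coeffs, q_offsets)]
        combo = [alpha * a + beta * b for a, b in zip(p_coeffs, q_coeffs)]
        for cs in (p_coeffs, q_coeffs, combo):
            assume(len(cs) == 1 or cs[0] != 0)
        p, q, combo_p = PolyCoeffs(tuple(p_coeffs)), PolyCoeffs(tuple(q_coeffs)), PolyCoeffs(tuple(combo))
        for x in (-1.7, 0.0, 2.3):
            lhs = evaluate_poly(differentiate(combo_p), x)
            rhs = alpha * evaluate_poly(differentiate(p), x) + beta * evaluate_poly(differentiate(q), x)
            assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-6)


class TestRSquared:
    def test_perfect_fit(self):
        y = [1.0, 2.0, 4.0]
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared_residual(y, y) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        yhat = np.full_like(y, y.mean())
        assert r_squared(y, yhat) == 0.0
        assert r_squared_residual(y, yhat) == 0.0

    def test_forms_agree_for_least_squares_line(self):
        # Hand least squares on y = [1,2,3,5] at x = [0,1,2,3].
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        assert r_squared(y, yhat) == pytest.approx(r_squared_residual(y, yhat), abs=1e-10)

    def test_forms_agree_generally_for_ls_with_intercept(self, rng):
        for _ in range(25):
            x = np.sort(rng.uniform(1, 50, 20))
            y = rng.uniform(10, 1000, 20)
            for deg in (1, 2, 3):
                yhat = np.polyval(np.polyfit(x, y, deg), x)
                assert r_squared(y, yhat) == pytest.approx(r_squared_residual(y, yhat), abs=1e-10)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def _series(x, y):
    return GrowthSeries("d", tuple(float(v) for v in x), tuple(int(round(v)) for v in y))


class TestFitFamily:
    def test_exponential_exact_recovery(self):
        x = np.arange(1.0, 11.0)
        y = 2.0 * np.exp(0.5 * x)
        fit = fit_family(_series_float(x, y), "exponential")
        a, b = fit.params
        assert a == pytest.approx(2.0, rel=1e-12)
        assert b == pytest.approx(0.5, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0, rel=1e-9)

    def test_cubic_interpolation_exact(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = 0.5 * x**3 - x**2 + 2 * x + 10
        fit = fit_family(_series_float(x, y), "polynomial", order=3)
        assert fit.params == pytest.approx((0.5, -1.0, 2.0, 10.0), abs=1e-8)

    def test_noisy_cubic_recovery_within_3se(self):
        rng = np.random.default_rng(42)
        x = np.arange(24.0, 49.0)
        truth = np.array([0.05, -2.0, 60.0, 1500.0])
        y0 = np.polyval(truth, x)
        y = y0 + rng.normal(0, 0.01 * (y0.max() - y0.min()), x.size)
        fit = fit_family(_series_float(x, y), "polynomial", order=3)
        se = _poly_se(x, y, 3)
        assert np.all(np.abs(np.array(fit.params) - truth) <= 3 * se)

    def test_nonpositive_y_rejected_for_log_families(self):
        x = np.arange(1.0, 6.0)
        y = np.array([1.0, 2.0, 0.0, 4.0, 5.0])
        for fam in ("exponential", "power"):
            with pytest.raises(ValueError):
                fit_family(_series_float(x, y), fam)

    def test_nonpositive_x_rejected_for_log_x_families(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        for fam in ("logarithmic", "power"):
            with pytest.raises(ValueError):
                fit_family(_series_float(x, y), fam)

    def test_too_few_points(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_family(_series_float(x, y), "polynomial", order=3)

    def test_unknown_family(self, cubic_series):
        with pytest.raises(ValueError):
            fit_family(cubic_series, "spline")


def _series_float(x, y):
    """Series facade with float samples for exact-recovery tests."""
    s = GrowthSeries.__new__(GrowthSeries)
    object.__setattr__(s, "dish_id", "d")
    object.__setattr__(s, "times", tuple(float(v) for v in x))
    object.__setattr__(s, "counts", tuple(float(v) for v in y))
    return s


def _poly_se(x, y, deg):
    """Standard errors of OLS polynomial coefficients (descending order)."""
    X = np.vander(x, deg + 1)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(x) - (deg + 1)
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return np.sqrt(np.diag(cov))


class TestSelectBest:
    def test_planted_cubic_selects_poly3(self):
        rng = np.random.default_rng(7)
        x = np.arange(24.0, 49.0)
        y0 = np.polyval([0.08, -4.0, 80.0, 2000.0], x - 20.0)
        y = y0 + rng.normal(0, 0.01 * (y0.max() - y0.min()), x.size)
        best = select_best(_series(x, np.maximum(y, 1.0)))
        assert best.family == "polynomial" and best.order == 3

    def test_nested_model_tie_prefers_linear(self):
        x = np.arange(1.0, 11.0)
        y = 3.0 * x + 7.0
        best = select_best(_series_float(x, y), candidates=("linear", "polynomial"), monotone_check=False)
        assert best.family == "linear"

    def test_planted_downturn_disqualifies_poly4(self):
        # A quartic whose fit turns downward at the right edge.
        x = np.arange(24.0, 49.0)
        y = -0.05 * (x - 24.0) ** 4 + 4.0 * (x - 24.0) ** 2 + 3000.0
        series = _series_float(x, y)
        fit4 = fit_family(series, "polynomial", order=4)
        assert fit4.derivative_at(48.0) < 0
        with pytest.raises(ValueError, match="decreasing"):
            select_best(series, candidates=(("polynomial", 4),))
        # With the check off the quartic is accepted.
        assert select_best(series, candidates=(("polynomial", 4),), monotone_check=False).order == 4

    def test_all_disqualified_reports_reasons(self):
        x = np.arange(1.0, 6.0)
        y = np.array([10.0, 8.0, 6.0, 4.0, 2.0])  # strictly decreasing
        with pytest.raises(ValueError, match="linear"):
            select_best(_series_float(x, y), candidates=("linear",))


class TestPotentialCurve:
    def test_dish4_vertex_peak(self):
        cubic, deriv = TABLE7[4]
        fit = fit_family(_series_float(np.arange(25.0, 49.0), np.polyval(cubic, np.arange(25.0, 49.0))), "polynomial")
        curve = potential_curve(fit, (25.0, 48.0))
        # Concave quadratic derivative: vertex at -b/(2a) = 16.6362 / (2*0.2136).
        t_star = deriv[1] / (2.0 * -deriv[0])
        assert curve.peak[0] == pytest.approx(t_star, abs=1e-6)
        assert curve.peak[0] == pytest.approx(38.94, abs=0.01)

    def test_dish1_convex_boundary_peak(self):
        cubic, _ = TABLE7[1]
        x = np.arange(25.0, 49.0)
        fit = fit_family(_series_float(x, np.polyval(cubic, x)), "polynomial")
        curve = potential_curve(fit, (25.0, 48.0))
        assert curve.peak[0] == pytest.approx(48.0)

    def test_grid_peak_on_hour_grid(self):
        cubic, _ = TABLE7[4]
        x = np.arange(25.0, 49.0)
        fit = fit_family(_series_float(x, np.polyval(cubic, x)), "polynomial")
        curve = potential_curve(fit, (25.0, 48.0))
        assert curve.grid_peak[0] == pytest.approx(39.0)  # nearest hour to the vertex

    def test_degenerate_domain(self, cubic_series):
        fit = fit_family(cubic_series, "polynomial")
        with pytest.raises(ValueError):
            potential_curve(fit, (30.0, 30.0))

    def test_degree_below_two_rejected(self):
        x = np.arange(1.0, 6.0)
        fit = fit_family(_series_float(x, 2 * x + 1), "polynomial", order=1)
        with pytest.raises(ValueError):
            potential_curve(fit, (1.0, 5.0))


def test_table7_dishes_6_to_8_exact_differentiation_is_authoritative():
    # The published derivative rows for dishes 6-8 disagree slightly with
    # exact differentiation of their own cubics; exact math wins here.
    printed_cubics = {
        6: (-0.1153, 15.6859, -559.5365, 10383.6654),
        7: (0.1096, -10.9386, 387.634, -719.1204),
        8: (-0.2138, 24.1921, -836.4996, 12029.3196),
    }
    for cubic in printed_cubics.values():
        c3, c2, c1, _ = cubic
        derived = differentiate(PolyCoeffs(cubic)).coeffs
        assert derived == pytest.approx((3 * c3, 2 * c2, c1), abs=1e-12)
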