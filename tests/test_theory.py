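import math

import numpy as np
import pytest

from auxmean.estimators import EstimatorSpec
from auxmean.moments import design_constants, summary_from_config
from auxmean.theory import (ErrorMoments, TruncatedPoly,
                            UnsupportedPrintedFormula, cramer_optimal_k,
                            derived_optimal_k, efficiency_margin,
                            error_moments, expand_estimator, expectation, pre,
                            printed_bias_mse, printed_min_mse,
                            printed_optimal_k, series_bias_mse,
                            series_mse_gradient, solve2x2_cramer,
                            theory_constants)

from conftest import random_summary


def make_summary(lam=0.1, C_y2=1.0, C_x2=1.0, C_yx=0.0, mu_y=40.0, mu_x=50.0,
                 N=1000):
    """Summary/design pair with a prescribed lam (n chosen to match)."""
    # lam = (N-n)/(Nn)  =>  n = N/(1 + N*lam)
    n = round(N / (1 + N * lam))
    design = design_constants(n, N)
    rho = C_yx / math.sqrt(C_y2 * C_x2)
    s = summary_from_config(N=N, mu_y=mu_y, mu_x=mu_x,
                            C_y=math.sqrt(C_y2), C_x=math.sqrt(C_x2), rho=rho)
    return s, design


class TestErrorMoments:
    def test_census_has_zero_second_moments(self):
        s = summary_from_config(N=50, mu_y=10, mu_x=20, C_y=0.3, C_x=0.2,
                                rho=0.5)
        m = error_moments(s, design_constants(50, 50))
        assert m.E_e0sq == 0 and m.E_e1sq == 0 and m.E_e0e1 == 0

    def test_direct_products(self):
        s = summary_from_config(N=1000, mu_y=10, mu_x=20, C_y=1.0, C_x=1.0,
                                rho=0.5)
        d = design_constants(round(1000 / (1 + 100)), 1000)  # lam ~ 0.1
        m = error_moments(s, d)
        assert m.E_e0sq == pytest.approx(d.lam)
        assert m.E_e1sq == pytest.approx(d.lam)
        assert m.E_e0e1 == pytest.approx(0.5 * d.lam)

    def test_zero_mean_rejected(self):
        s = summary_from_config(N=10, mu_y=10, mu_x=20, C_y=0.1, C_x=0.1,
                                rho=0.0)
        bad = type(s)(**{**s.__dict__, "mu_y": 0.0})
        with pytest.raises(ValueError):
            error_moments(bad, design_constants(5, 10))


class TestTruncatedPoly:
    def test_expectation_of_monomials(self):
        m = ErrorMoments(E_e0sq=0.1, E_e1sq=0.2, E_e0e1=0.05)
        assert expectation(TruncatedPoly(c00=1.0), m) == 1.0
        assert expectation(TruncatedPoly(c11=1.0), m) == 0.05
        assert expectation(TruncatedPoly(c10=1.0, c01=1.0), m) == 0.0

    def test_multiplication_drops_high_degrees(self):
        e1 = TruncatedPoly(c01=1.0)
        p = (1.0 + e1) * (1.0 + e1) * (1.0 + e1)
        assert (p.c00, p.c01, p.c02) == (1.0, 3.0, 3.0)

    def test_compose_requires_zero_constant(self):
        with pytest.raises(ValueError):
            TruncatedPoly(c00=1.0).compose_series(0.0, 1.0, -0.5)


class TestExpansions:
    def test_tp1_adjustment_series(self):
        p = expand_estimator(EstimatorSpec("TP1", {"k1": 1.0, "k2": 0.0}),
                             mu_y=1.0, mu_x=50.0)
        # (1+e0)(1 - e1/2 + e1^2/3)
        assert p.c00 == 1.0 and p.c10 == 1.0
        assert p.c01 == pytest.approx(-0.5)
        assert p.c02 == pytest.approx(1 / 3)
        assert p.c11 == pytest.approx(-0.5)

    def test_t3_exponential_factor(self):
        p = expand_estimator(EstimatorSpec("T3"), mu_y=1.0, mu_x=50.0)
        assert p.c01 == pytest.approx(-0.5)
        assert p.c02 == pytest.approx(3 / 8)

    def test_tp2_factor_has_no_quadratic_e1_term(self):
        p = expand_estimator(EstimatorSpec("TP2", {"k3": 0.0, "k4": 1.0}),
                             mu_y=1.0, mu_x=50.0)
        # k4 * [Ln(1+e1) exp(e1/(2+e1))] = e1 + 0*e1^2
        assert p.c01 == pytest.approx(1.0)
        assert p.c02 == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("name,consts", [
        ("T1", {}),
        ("T3", {}),
        ("T5", {}),
        ("T8", {"K1": 1.7, "K2": 0.4, "Md": 13.0}),
        ("TP1", {"k1": 1.2, "k2": 3.0}),
        ("TP2", {"k3": 0.8, "k4": -2.0}),
    ])
    def test_expansion_against_symbolic_oracle(self, name, consts):
        """Independent route: sympy bivariate Taylor expansion of the exact
        estimator formula must reproduce every retained coefficient."""
        import sympy as sp

        mu_y, mu_x = 37.0, 21.0
        e0, e1, t = sp.symbols("e0 e1 t")
        ybar = mu_y * (1 + e0)
        xbar = mu_x * (1 + e1)
        if name == "T1":
            expr = mu_x * ybar / xbar
        elif name == "T3":
            expr = ybar * sp.exp((mu_x - xbar) / (mu_x + xbar))
        elif name == "T5":
            expr = ybar * sp.log(mu_x) / sp.log(xbar)
        elif name == "T8":
            md = consts["Md"]
            lr = sp.log((mu_x + md) / (xbar + md))
            expr = consts["K1"] * lr - consts["K2"] * lr
        elif name == "TP1":
            expr = ((consts["k1"] * ybar + consts["k2"])
                    * mu_x * sp.log(xbar / mu_x) / (xbar - mu_x))
        elif name == "TP2":
            expr = ((consts["k3"] * ybar + consts["k4"])
                    * sp.log(xbar / mu_x)
                    * sp.exp((xbar - mu_x) / (xbar + mu_x)))
        a0, a1 = sp.symbols("a0 a1")
        series = sp.series(expr.subs({e0: t * a0, e1: t * a1}), t, 0, 3
                           ).removeO().expand()
        coeff = {
            "c00": series.coeff(t, 0),
            "c10": series.coeff(t, 1).coeff(a0, 1),
            "c01": series.coeff(t, 1).coeff(a1, 1),
            "c20": series.coeff(t, 2).coeff(a0, 2),
            "c11": series.coeff(t, 2).coeff(a0, 1).coeff(a1, 1),
            "c02": series.coeff(t, 2).coeff(a1, 2),
        }
        p = expand_estimator(EstimatorSpec(name, consts), mu_y, mu_x)
        for key, val in coeff.items():
            assert getattr(p, key) == pytest.approx(float(val), abs=1e-10), key


class TestSeriesVsPrintedClassics:
    """The mechanical series path must reproduce the classical closed forms
    (standard-variant printed path) to machine precision."""

    def test_t0_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s, d = random_summary(rng)
            r = series_bias_mse(EstimatorSpec("T0"), s, d)
            assert r.mse == pytest.approx(d.lam * s.mu_y**2 * s.C_y**2,
                                          rel=1e-12)
            assert r.bias == pytest.approx(0.0, abs=1e-15)

    def test_t1_classical_ratio_mse(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            s, d = random_summary(rng)
            r = series_bias_mse(EstimatorSpec("T1"), s, d)
            R = s.mu_y / s.mu_x
            expected = d.lam * (s.S2_y + R**2 * s.S2_x - 2 * R * s.S_yx)
            assert r.mse == pytest.approx(expected, rel=1e-12)
            assert r.mse == pytest.approx(
                printed_bias_mse(EstimatorSpec("T1"), s, d).mse, rel=1e-12)

    def test_t3_exponential_structure(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            s, d = random_summary(rng)
            r = series_bias_mse(EstimatorSpec("T3"), s, d)
            R = s.mu_y / s.mu_x
            expected = d.lam * (s.S2_y + 0.25 * R**2 * s.S2_x - R * s.S_yx)
            assert r.mse == pytest.approx(expected, rel=1e-12)

    def test_regression_estimator_one_minus_rho_sq(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            s, d = random_summary(rng)
            r = series_bias_mse(EstimatorSpec("T4"), s, d)
            expected = d.lam * s.mu_y**2 * s.C_y**2 * (1 - s.rho**2)
            assert r.mse == pytest.approx(expected, rel=1e-11)

    def test_t6_at_optimal_alpha_matches_regression_bound(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            s, d = random_summary(rng)
            r = series_bias_mse(EstimatorSpec("T6"), s, d)  # default alpha
            expected = d.lam * s.mu_y**2 * s.C_y**2 * (1 - s.rho**2)
            assert r.mse == pytest.approx(expected, rel=1e-11)

    def test_perfect_correlation_zeroes_regression_mse(self):
        s = summary_from_config(N=100, mu_y=8, mu_x=4, C_y=0.25, C_x=0.25,
                                rho=1.0)
        d = design_constants(20, 100)
        assert series_bias_mse(EstimatorSpec("T4"), s, d).mse == pytest.approx(
            0.0, abs=1e-12)

    def test_tp1_surface_at_unit_constants_no_covariance(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s, d = random_summary(rng)
            s = summary_from_config(N=s.N, mu_y=s.mu_y, mu_x=s.mu_x,
                                    C_y=s.C_y, C_x=s.C_x, rho=0.0)
            spec = EstimatorSpec("TP1", {"k1": 1.0, "k2": 0.0})
            expected = s.mu_y**2 * d.lam * (s.C_y**2 + 0.25 * s.C_x**2)
            assert series_bias_mse(spec, s, d).mse == pytest.approx(
                expected, rel=1e-12)
            # the printed surface subtracts order-1 constants, so float
            # agreement is asserted at its natural mu_y^2 scale
            assert printed_bias_mse(spec, s, d).mse == pytest.approx(
                expected, rel=1e-12, abs=1e-12 * s.mu_y**2)


class TestPrintedPath:
    def test_t4_printed_lacks_mean_square_scale(self):
        # the published regression-estimator MSE omits the mu_y^2 factor;
        # transcribed literally, so series/printed differ by exactly mu_y^2
        s, d = make_summary(C_yx=0.3)
        p = printed_bias_mse(EstimatorSpec("T4"), s, d).mse
        r = series_bias_mse(EstimatorSpec("T4"), s, d).mse
        assert r == pytest.approx(p * s.mu_y**2, rel=1e-12)

    def test_t5_printed_at_euler_mean_reduces(self):
        # mu_x = e gives k = 1; the T5 MSE collapses to the ratio form
        s, d = make_summary(mu_x=math.e, C_yx=0.4)
        p = printed_bias_mse(EstimatorSpec("T5"), s, d).mse
        R = s.mu_y / s.mu_x
        assert p == pytest.approx(
            d.lam * (s.S2_y + R**2 * s.S2_x - 2 * R * s.S_yx), rel=1e-12)

    def test_t8_printed_unsupported(self):
        s, d = make_summary()
        with pytest.raises(UnsupportedPrintedFormula):
            printed_bias_mse(EstimatorSpec("T8", {"K1": 1, "K2": 0}), s, d)

    def test_paper_literal_t1_uses_inverted_ratio(self):
        s, d = make_summary(C_yx=0.2)
        lit = printed_bias_mse(EstimatorSpec("T1", variant="paper-literal"),
                               s, d).mse
        D = s.mu_x / s.mu_y
        assert lit == pytest.approx(
            d.lam * (s.S2_y + D * s.S2_x - 2 * D * s.S_yx), rel=1e-12)


class TestTheoryConstants:
    def test_census_collapses_constants(self):
        s, _ = make_summary()
        d = design_constants(s.N, s.N)
        c = theory_constants("P1", s, d)
        assert (c.A1, c.B1, c.C1, c.D1, c.E1) == (1, 1, 1, 1, 1)
        assert c.Delta1 == 0

    def test_p1_arithmetic(self):
        s, d = make_summary(lam=0.1, C_y2=1.0, C_x2=1.0, C_yx=0.0)
        lam = d.lam
        c = theory_constants("P1", s, d)
        assert c.A1 == pytest.approx(1 + lam + 11 / 12 * lam, rel=1e-12)
        assert c.B1 == pytest.approx(1 + 11 / 12 * lam, rel=1e-12)
        assert c.C1 == pytest.approx(1 + lam / 3, rel=1e-12)
        assert c.D1 == c.C1 and c.E1 == c.B1
        assert c.Delta1 == pytest.approx(c.A1 * c.B1 - c.E1**2, rel=1e-12)

    def test_p2_arithmetic(self):
        s, d = make_summary(lam=0.1, C_y2=1.0, C_x2=1.0)
        a = d.lam
        c = theory_constants("P2", s, d)
        assert c.alpha == pytest.approx(a) and c.beta == pytest.approx(a)
        assert c.A2 == pytest.approx((a * (1 + a) + a**2) / 64, rel=1e-12)
        assert c.B2 == pytest.approx((a + a**2) / 64, rel=1e-12)
        assert c.E2 == pytest.approx(2 * c.B2, rel=1e-14)
        assert c.C2 == pytest.approx(a / 4, rel=1e-14)
        assert c.D2 == c.C2


class TestOptimalConstants:
    def test_printed_k1_vanishes_without_covariance(self):
        s, d = make_summary(C_yx=0.0)
        c = theory_constants("P1", s, d)
        k1, _ = printed_optimal_k("P1", c, s.mu_y)
        assert k1 == 0.0

    def test_census_degenerate_raises(self):
        s, _ = make_summary()
        d = design_constants(s.N, s.N)
        with pytest.raises(ZeroDivisionError):
            printed_optimal_k("P1", theory_constants("P1", s, d), s.mu_y)

    def test_printed_k3_negative_for_positive_alpha(self):
        s, d = make_summary(lam=0.1)
        c = theory_constants("P2", s, d)
        k3, _ = printed_optimal_k("P2", c, s.mu_y)
        # E2 = 2 B2 makes B2 C2 - C2 E2 = -B2 C2 < 0; Delta2 < 0 as well,
        # so the printed k3 is positive -- pin the computed sign chain
        assert c.B2 * c.C2 - c.C2 * c.E2 < 0
        assert c.Delta2 < 0
        assert k3 > 0

    def test_cramer_path_matches_generic_solver(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            A = rng.uniform(-2, 2, (2, 2))
            A = A @ A.T + np.eye(2)  # well-conditioned SPD
            b = rng.uniform(-3, 3, 2)
            x = solve2x2_cramer(A[0, 0], A[0, 1], A[1, 0], A[1, 1], b[0], b[1])
            ref = np.linalg.solve(A, b)
            assert np.allclose(x, ref, rtol=1e-12, atol=1e-12)

    def test_printed_vs_cramer_k1_sign_discrepancy_is_pinned(self):
        # the published k1 carries -D1*E1; the literal Cramer solution of the
        # published normal equations carries +D1*E1; k2 agrees
        s, d = make_summary(C_yx=0.3)
        c = theory_constants("P1", s, d)
        k1p, k2p = printed_optimal_k("P1", c, s.mu_y)
        k1c, k2c = cramer_optimal_k("P1", c, s.mu_y)
        assert k1c - k1p == pytest.approx(2 * c.D1 * c.E1 / c.Delta1, rel=1e-9)
        assert k2c == pytest.approx(k2p, rel=1e-9)

    def test_derived_optimum_is_stationary_and_minimal(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            s, d = random_summary(rng)
            (k1, k2), status = derived_optimal_k("P1", s, d)
            assert status == "ok"
            g = series_mse_gradient("P1", s, d, (k1, k2))
            assert np.linalg.norm(g) <= 1e-8
            opt = series_bias_mse(
                EstimatorSpec("TP1", {"k1": k1, "k2": k2}), s, d).mse
            ref = series_bias_mse(
                EstimatorSpec("TP1", {"k1": 1.0, "k2": 0.0}), s, d).mse
            assert opt <= ref + 1e-12

    def test_derived_k1_small_without_covariance(self):
        s, d = make_summary(lam=0.01, C_y2=0.05, C_x2=0.05, C_yx=0.0)
        (k1, k2), status = derived_optimal_k("P1", s, d)
        assert status == "ok"
        assert abs(k1) < 1e-6
        assert k2 == pytest.approx(s.mu_y * (1 - k1), rel=1e-2)

    def test_tp2_surface_is_degenerate(self):
        s, d = make_summary(C_yx=0.3)
        (_, _), status = derived_optimal_k("P2", s, d)
        assert status == "degenerate"


class TestPrintedMinMse:
    def test_arithmetic_example(self):
        s, d = make_summary(lam=0.1, C_y2=1.0, C_x2=1.0, C_yx=0.0)
        c = theory_constants("P1", s, d)
        num = c.A1 * c.D1**2 + c.B1 * c.C1**2 - 2 * c.C1 * c.D1 * c.E1
        expected = s.mu_y**2 * (1 - num / c.Delta1)
        assert printed_min_mse("P1", c, s.mu_y) == pytest.approx(expected,
                                                                 rel=1e-14)

    def test_p2_vanishing_correction_as_alpha_to_zero(self):
        s, d = make_summary(lam=0.1, C_x2=1e-8)
        c = theory_constants("P2", s, d)
        # C2^2 (A2+B2-2E2)/Delta2 -> O(alpha), so min MSE -> mu_y^2
        assert printed_min_mse("P2", c, s.mu_y) == pytest.approx(
            s.mu_y**2, rel=1e-6)

    def test_min_formula_disagrees_with_surface_at_printed_optimum(self):
        # documented internal inconsistency of the published algebra
        s, d = make_summary(lam=0.1, C_y2=1.0, C_x2=1.0, C_yx=0.0)
        c = theory_constants("P1", s, d)
        k1, k2 = printed_optimal_k("P1", c, s.mu_y)
        surface = printed_bias_mse(
            EstimatorSpec("TP1", {"k1": k1, "k2": k2}), s, d).mse
        formula = printed_min_mse("P1", c, s.mu_y)
        assert abs(surface - formula) > 1e-3 * abs(formula)


class TestSeriesNonnegativity:
    def test_series_mse_nonnegative_except_tp2(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            s, d = random_summary(rng)
            name = rng.choice(["T0", "T1", "T2", "T3", "T4", "T5", "T6",
                               "T7", "T8", "TP1"])
            consts = {}
            if name == "T7":
                consts = {"w1": rng.uniform(-1, 1), "w2": rng.uniform(-3, 3)}
            elif name == "T8":
                consts = {"K1": rng.uniform(-3, 3), "K2": rng.uniform(-3, 3),
                          "Md": rng.uniform(1, 50)}
            elif name == "TP1":
                consts = {"k1": rng.uniform(-2, 2),
                          "k2": rng.uniform(-2, 2) * s.mu_y}
            mse = series_bias_mse(EstimatorSpec(str(name), consts), s, d).mse
            assert mse >= -1e-10 * s.mu_y**2, (name, consts)

    def test_tp2_exception_region_exists(self):
        # at first order the TP2 surface is unbounded below along
        # k4 = -k3 mu_y; a large k3 on that ray drives the mse negative
        s, d = make_summary(lam=0.1, C_yx=0.5)
        k3 = 1e4
        mse = series_bias_mse(
            EstimatorSpec("TP2", {"k3": k3, "k4": -k3 * s.mu_y}), s, d).mse
        assert mse < 0


class TestEfficiency:
    def test_pre_identity_and_ratio(self):
        assert pre(2.5, 2.5) == 100.0
        assert pre(2.0, 1.0) == 200.0
        with pytest.raises(ValueError):
            pre(1.0, 0.0)

    def test_margin_zero_against_self(self):
        s, d = make_summary(C_yx=0.3)
        spec = EstimatorSpec("T1")
        assert efficiency_margin(spec, spec, s, d) == 0.0

    def test_optimal_tp1_dominates_classical_mean(self):
        # dominance over T0 is condition-dependent (the x-adjustment carries
        # a fixed -e1/2 term, costing ~ lam C_x^2 (1-rho^2)/4); with matched
        # coefficients of variation the condition holds for every rho
        rng = np.random.default_rng(13)
        for _ in range(25):
            s, d = random_summary(rng)
            s = summary_from_config(N=s.N, mu_y=s.mu_y, mu_x=s.mu_x,
                                    C_y=s.C_y, C_x=s.C_y, rho=s.rho)
            (k1, k2), _ = derived_optimal_k("P1", s, d)
            m = efficiency_margin(EstimatorSpec("TP1", {"k1": k1, "k2": k2}),
                                  EstimatorSpec("T0"), s, d)
            assert m > 0

    def test_margin_sign_agrees_with_direct_inequality(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            s, d = random_summary(rng)
            a, b = EstimatorSpec("T1"), EstimatorSpec("T3")
            m = efficiency_margin(a, b, s, d)
            direct = (series_bias_mse(b, s, d).mse
                      - series_bias_mse(a, s, d).mse)
            assert m == direct
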