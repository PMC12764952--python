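"""First-order (degree-2) bias and MSE theory for the estimator family.

Two parallel paths are provided and kept deliberately distinct:

``printed``
    Literal transcriptions of the published closed-form bias/MSE
    expressions, optimal tuning constants and minimum MSEs.  The published
    algebra for the log-ratio estimators is internally inconsistent in a few
    places (sign of one term in the optimal ``k1``, a minimum-MSE expression
    that does not equal the MSE surface evaluated at the published optimum);
    this path reproduces the printed expressions verbatim and the
    discrepancies are pinned by regression tests.

``series``
    A mechanical derivation: each estimator is expanded to total degree 2 in
    the sampling errors ``e0 = (ybar - mu_y)/mu_y`` and
    ``e1 = (xbar - mu_x)/mu_x`` by composing primitive scalar series
    (``log(1+u)``, ``1/(1+u)``, ``exp(u)``, ``log(1+u)/u``) in a truncated
    polynomial ring, and the bias/MSE follow from the SRSWOR moment contract
    ``E[e0] = E[e1] = 0``, ``E[e0^2] = lam*C_y^2``, ``E[e1^2] = lam*C_x^2``,
    ``E[e0 e1] = lam*C_yx``.

The ``series`` path is the default for user-facing efficiency tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .estimators import ESTIMATOR_NAMES, EstimatorSpec, default_t6_alpha
from .moments import DesignSpec, PopulationSummary

__all__ = [
    "ErrorMoments",
    "TruncatedPoly",
    "P1Constants",
    "P2Constants",
    "TheoryResult",
    "UnsupportedPrintedFormula",
    "error_moments",
    "expand_estimator",
    "expectation",
    "series_bias_mse",
    "printed_bias_mse",
    "theory_constants",
    "printed_optimal_k",
    "cramer_optimal_k",
    "derived_optimal_k",
    "printed_min_mse",
    "pre",
    "efficiency_margin",
    "solve2x2_cramer",
]


class UnsupportedPrintedFormula(ValueError):
    """Raised when no usable printed bias/MSE formula exists (T8)."""


# ---------------------------------------------------------------------------
# sampling-error moments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorMoments:
    """Second-order SRSWOR moments of the relative sampling errors.

    First moments vanish by design unbiasedness of the sample means; the
    second moments all carry the common factor ``lam = (1-f)/n``.
    """

    E_e0sq: float
    E_e1sq: float
    E_e0e1: float

    def __post_init__(self) -> None:
        if self.E_e0sq < 0 or self.E_e1sq < 0:
            raise ValueError("second moments must be nonnegative")


def error_moments(summary: PopulationSummary, design: DesignSpec) -> ErrorMoments:
    """Moments of ``(e0, e1)`` implied by a population and a design."""
    if summary.mu_y == 0 or summary.mu_x == 0:
        raise ValueError("error moments undefined for zero means")
    lam = design.lam
    return ErrorMoments(
        E_e0sq=lam * summary.C_y**2,
        E_e1sq=lam * summary.C_x**2,
        E_e0e1=lam * summary.C_yx,
    )


# ---------------------------------------------------------------------------
# truncated bivariate polynomial ring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncatedPoly:
    """Bivariate polynomial in ``(e0, e1)`` truncated at total degree 2.

    Closed under addition, scalar multiplication and truncated
    multiplication (degree > 2 terms are dropped); primitive scalar series
    are composed via :meth:`compose_series`.
    """

    c00: float = 0.0
    c10: float = 0.0
    c01: float = 0.0
    c20: float = 0.0
    c11: float = 0.0
    c02: float = 0.0

    def __add__(self, other: "TruncatedPoly | float") -> "TruncatedPoly":
        o = _as_poly(other)
        return TruncatedPoly(self.c00 + o.c00, self.c10 + o.c10, self.c01 + o.c01,
                             self.c20 + o.c20, self.c11 + o.c11, self.c02 + o.c02)

    __radd__ = __add__

    def __neg__(self) -> "TruncatedPoly":
        return self.scale(-1.0)

    def __sub__(self, other: "TruncatedPoly | float") -> "TruncatedPoly":
        return self + (-_as_poly(other))

    def __rsub__(self, other: float) -> "TruncatedPoly":
        return _as_poly(other) - self

    def scale(self, a: float) -> "TruncatedPoly":
        return TruncatedPoly(a * self.c00, a * self.c10, a * self.c01,
                             a * self.c20, a * self.c11, a * self.c02)

    def __mul__(self, other: "TruncatedPoly | float") -> "TruncatedPoly":
        if isinstance(other, (int, float)):
            return self.scale(float(other))
        a, b = self, other
        return TruncatedPoly(
            c00=a.c00 * b.c00,
            c10=a.c00 * b.c10 + a.c10 * b.c00,
            c01=a.c00 * b.c01 + a.c01 * b.c00,
            c20=a.c00 * b.c20 + a.c10 * b.c10 + a.c20 * b.c00,
            c11=a.c00 * b.c11 + a.c10 * b.c01 + a.c01 * b.c10 + a.c11 * b.c00,
            c02=a.c00 * b.c02 + a.c01 * b.c01 + a.c02 * b.c00,
        )

    __rmul__ = __mul__

    @property
    def constant(self) -> float:
        return self.c00

    def compose_series(self, f0: float, f1: float, f2: float) -> "TruncatedPoly":
        """Compose a scalar series ``f(u) = f0 + f1 u + f2 u^2`` with this
        polynomial, which must have zero constant term."""
        if self.c00 != 0.0:
            raise ValueError("series composition requires a zero constant term")
        return _as_poly(f0) + self.scale(f1) + (self * self).scale(f2)


def _as_poly(v: "TruncatedPoly | float") -> TruncatedPoly:
    if isinstance(v, TruncatedPoly):
        return v
    return TruncatedPoly(c00=float(v))


E0 = TruncatedPoly(c10=1.0)
E1 = TruncatedPoly(c01=1.0)
ONE = TruncatedPoly(c00=1.0)

# primitive scalar series, all about u = 0, to degree 2
_LOG1P = (0.0, 1.0, -0.5)          # log(1+u)
_RECIP1P = (1.0, -1.0, 1.0)        # 1/(1+u)
_EXP = (1.0, 1.0, 0.5)             # exp(u)
_LOG1P_OVER_U = (1.0, -0.5, 1.0 / 3.0)  # log(1+u)/u


def expectation(poly: TruncatedPoly, moments: ErrorMoments) -> float:
    """Expectation of a truncated polynomial under the (e0, e1) moment
    contract; linear terms vanish."""
    return (poly.c00
            + poly.c20 * moments.E_e0sq
            + poly.c11 * moments.E_e0e1
            + poly.c02 * moments.E_e1sq)


# ---------------------------------------------------------------------------
# estimator expansions
# ---------------------------------------------------------------------------

def _resolved_constants(
    spec: EstimatorSpec, summary: PopulationSummary | None
) -> dict[str, float]:
    c = dict(spec.constants)
    if spec.name == "T4" and "phi1" not in c:
        if summary is None:
            raise ValueError("T4 expansion requires phi1 or a PopulationSummary")
        c["phi1"] = summary.S_yx / summary.S2_x
    if spec.name == "T6" and "alpha" not in c:
        if summary is None:
            raise ValueError("T6 expansion requires alpha or a PopulationSummary")
        c["alpha"] = default_t6_alpha(summary)
    if spec.name == "T8" and "Md" not in c:
        if summary is None:
            raise ValueError("T8 expansion requires Md or a PopulationSummary")
        c["Md"] = summary.median_x
    return c


def expand_estimator(
    spec: EstimatorSpec,
    mu_y: float,
    mu_x: float,
    summary: PopulationSummary | None = None,
) -> TruncatedPoly:
    """Degree-2 expansion of the estimator in the sampling errors (e0, e1).

    Substitutes ``ybar = mu_y (1+e0)`` and ``xbar = mu_x (1+e1)`` and
    composes primitive series; no estimator-specific hand expansion rules.
    """
    if mu_x <= 0:
        raise ValueError("expansion requires mu_x > 0")
    name = spec.name
    if name not in ESTIMATOR_NAMES:
        raise ValueError(f"unknown estimator {name!r}")
    c = _resolved_constants(spec, summary)
    ybar = (ONE + E0).scale(mu_y)          # mu_y (1 + e0)
    log_x_ratio = E1.compose_series(*_LOG1P)   # log(xbar/mu_x) = log(1+e1)

    if name == "T0":
        return ybar
    if name == "T1":
        return ybar * E1.compose_series(*_RECIP1P)
    if name == "T2":
        return ybar * (ONE + E1)
    if name == "T3":
        # exp((mu_x - xbar)/(mu_x + xbar)) = exp(-e1/(2+e1))
        u = (E1.scale(0.5) * E1.scale(0.5).compose_series(*_RECIP1P)).scale(-1.0)
        return ybar * u.compose_series(*_EXP)
    if name == "T4":
        return ybar - E1.scale(c["phi1"] * mu_x)
    if name == "T5":
        k = 1.0 / math.log(mu_x)
        if spec.variant == "paper-literal":
            if mu_y <= 0:
                raise ValueError("paper-literal T5 expansion requires mu_y > 0")
            num = _as_poly(math.log(mu_y)) + E0.compose_series(*_LOG1P)
            den_rel = log_x_ratio.scale(k)   # log(xbar)/log(mu_x) - 1
            return num * den_rel.compose_series(*_RECIP1P).scale(mu_y * k)
        # standard: ybar * log(mu_x)/log(xbar)
        return ybar * log_x_ratio.scale(k).compose_series(*_RECIP1P)
    if name == "T6":
        return ybar + log_x_ratio.scale(c["alpha"])
    if name == "T7":
        return ybar.scale(c["w1"] + 1.0) + log_x_ratio.scale(c["w2"])
    if name == "T8":
        # log((mu_x+Md)/(xbar+Md)) = -log(1 + r e1), r = mu_x/(mu_x+Md)
        r = mu_x / (mu_x + c["Md"])
        lr = E1.scale(r).compose_series(*_LOG1P).scale(-1.0)
        return lr.scale(c["K1"] - c["K2"])
    if name == "TP1":
        g = E1.compose_series(*_LOG1P_OVER_U)   # mu_x log(xbar/mu_x)/(xbar-mu_x)
        return (ybar.scale(c["k1"]) + _as_poly(c["k2"])) * g
    if name == "TP2":
        u = E1.scale(0.5) * E1.scale(0.5).compose_series(*_RECIP1P)  # e1/(2+e1)
        factor = log_x_ratio * u.compose_series(*_EXP)
        return (ybar.scale(c["k3"]) + _as_poly(c["k4"])) * factor
    raise AssertionError(name)  # pragma: no cover


# ---------------------------------------------------------------------------
# series-mode bias and MSE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TheoryResult:
    estimator: str
    mode: str                      # "printed" | "series"
    mse: float
    bias: float | None = None
    constants_used: dict | None = None


def series_bias_mse(
    spec: EstimatorSpec,
    summary: PopulationSummary,
    design: DesignSpec,
) -> TheoryResult:
    """Mechanical first-order bias and MSE from the truncated expansion.

    ``bias = E[T - mu_y]`` and ``mse = E[(T - mu_y)^2]`` where the square is
    itself truncated at total degree 2 (constant^2, constant x linear,
    linear^2 and constant x quadratic cross terms are retained).
    """
    mom = error_moments(summary, design)
    dev = expand_estimator(spec, summary.mu_y, summary.mu_x, summary) - summary.mu_y
    bias = expectation(dev, mom)
    mse = expectation(dev * dev, mom)
    return TheoryResult(estimator=spec.name, mode="series", mse=mse, bias=bias,
                        constants_used=_resolved_constants(spec, summary))


# ---------------------------------------------------------------------------
# printed-formula path
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class P1Constants:
    """Published auxiliary constants entering the TP1 MSE surface; the
    ``C_x C_y`` factor in the source is read as ``C_yx = rho C_y C_x``."""

    A1: float
    B1: float
    C1: float
    D1: float
    E1: float
    Delta1: float


@dataclass(frozen=True)
class P2Constants:
    """Published auxiliary constants entering the TP2 MSE surface.

    ``D2`` is never defined in the source; it is set equal to ``C2``, the
    only assignment consistent with the linear ``k4`` term of the MSE.
    """

    alpha: float
    beta: float
    A2: float
    B2: float
    C2: float
    D2: float
    E2: float
    Delta2: float


def theory_constants(which, summary: PopulationSummary, design: DesignSpec):
    """The published constant sets for TP1 (``which='P1'``) or TP2 (``'P2'``)."""
    lam = design.lam
    cy2, cx2, cyx = summary.C_y**2, summary.C_x**2, summary.C_yx
    if which == "P1":
        A1 = 1 + lam * cy2 + (11 / 12) * lam * cx2 - 2 * lam * cyx
        B1 = 1 + (11 / 12) * lam * cx2
        C1 = 1 + (1 / 3) * lam * cx2 - lam * cyx
        D1 = 1 + (1 / 3) * lam * cx2
        E1_ = 1 + (11 / 12) * lam * cx2 - lam * cyx
        return P1Constants(A1, B1, C1, D1, E1_, A1 * B1 - E1_**2)
    if which == "P2":
        a = lam * cx2
        b = lam * cy2
        A2 = (a * (1 + b) + a**2) / 64
        B2 = (a + a**2) / 64
        E2 = (a + a**2) / 32
        C2 = a / 4
        return P2Constants(a, b, A2, B2, C2, C2, E2, A2 * B2 - E2**2)
    raise ValueError(f"which must be 'P1' or 'P2', got {which!r}")


def _check_delta(delta: float, scale: float) -> None:
    if abs(delta) < 1e-12 * max(abs(scale), 1e-300):
        raise ZeroDivisionError(
            "degenerate normal-equation system (Delta ~ 0; census design?)")


def printed_optimal_k(which, constants, mu_y: float) -> tuple[float, float]:
    """The optimal tuning constants exactly as published.

    Note the published ``k1`` carries ``-D1 E1`` where the literal Cramer
    solution of the published normal equations carries ``+D1 E1``; see
    :func:`cramer_optimal_k` for the latter.
    """
    if which == "P1":
        c = constants
        _check_delta(c.Delta1, c.A1 * c.B1)
        k1 = (c.B1 * c.C1 - c.D1 * c.E1) / c.Delta1
        k2 = mu_y * (c.A1 * c.D1 + c.C1 * c.E1) / c.Delta1
        return k1, k2
    if which == "P2":
        c = constants
        _check_delta(c.Delta2, c.A2 * c.B2)
        k3 = (c.B2 * c.C2 - c.C2 * c.E2) / c.Delta2
        k4 = c.C2 * mu_y * (c.A2 + c.E2) / c.Delta2
        return k3, k4
    raise ValueError(f"which must be 'P1' or 'P2', got {which!r}")


def solve2x2_cramer(a11, a12, a21, a22, b1, b2) -> tuple[float, float]:
    """Cramer's rule for a 2x2 linear system."""
    det = a11 * a22 - a12 * a21
    _check_delta(det, max(abs(a11 * a22), abs(a12 * a21)))
    return (b1 * a22 - a12 * b2) / det, (a11 * b2 - b1 * a21) / det


def cramer_optimal_k(which, constants, mu_y: float) -> tuple[float, float]:
    """Literal Cramer's-rule solution of the published normal equations.

    For P1 the system is ``[[mu_y^2 A1, -mu_y E1], [-mu_y E1, B1]] k =
    [mu_y^2 C1, mu_y D1]``, whose solution is ``k1 = (B1 C1 + D1 E1)/Delta1``
    -- differing from :func:`printed_optimal_k` in the sign of the
    ``D1 E1`` term.  The ``k2`` component agrees with the published one.
    """
    if which == "P1":
        c = constants
        return solve2x2_cramer(mu_y**2 * c.A1, -mu_y * c.E1,
                               -mu_y * c.E1, c.B1,
                               mu_y**2 * c.C1, mu_y * c.D1)
    if which == "P2":
        c = constants
        return solve2x2_cramer(mu_y**2 * c.A2, -mu_y * c.E2,
                               -mu_y * c.E2, c.B2,
                               mu_y**2 * c.C2, mu_y * c.D2)
    raise ValueError(f"which must be 'P1' or 'P2', got {which!r}")


def printed_min_mse(which, constants, mu_y: float) -> float:
    """Published minimum-MSE expressions for TP1 / TP2, verbatim.

    These do not coincide with the published MSE surfaces evaluated at the
    published optima; both are preserved and the gap is regression-tested.
    """
    if which == "P1":
        c = constants
        _check_delta(c.Delta1, c.A1 * c.B1)
        num = c.A1 * c.D1**2 + c.B1 * c.C1**2 - 2 * c.C1 * c.D1 * c.E1
        return mu_y**2 * (1 - num / c.Delta1)
    if which == "P2":
        c = constants
        _check_delta(c.Delta2, c.A2 * c.B2)
        return mu_y**2 * (1 - c.C2**2 * (c.A2 + c.B2 - 2 * c.E2) / c.Delta2)
    raise ValueError(f"which must be 'P1' or 'P2', got {which!r}")


def printed_bias_mse(
    spec: EstimatorSpec,
    summary: PopulationSummary,
    design: DesignSpec,
) -> TheoryResult:
    """Published first-order bias/MSE, transcribed literally.

    ``variant='paper-literal'`` keeps the published ratio constant
    ``D = mu_x/mu_y`` in the T1/T3/T5 formulas (dimensionally inconsistent
    for T1); the default ``'standard'`` variant uses the classical
    ``R = mu_y/mu_x`` with ``R^2`` on ``S_x^2``.  T8's published MSE is
    under-specified and raises :class:`UnsupportedPrintedFormula`.
    """
    s, lam = summary, design.lam
    name = spec.name
    bias: float | None = None
    used = dict(spec.constants)
    literal = spec.variant == "paper-literal"

    if name == "T0":
        mse = lam * s.mu_y**2 * s.C_y**2
        bias = 0.0
    elif name == "T1":
        if literal:
            D = s.mu_x / s.mu_y
            bias = lam * (D * s.S2_x - s.S_yx) / s.mu_x
            mse = lam * (s.S2_y + D * s.S2_x - 2 * D * s.S_yx)
        else:
            R = s.mu_y / s.mu_x
            bias = lam * (R * s.S2_x - s.S_yx) / s.mu_x
            mse = lam * (s.S2_y + R**2 * s.S2_x - 2 * R * s.S_yx)
    elif name == "T2":
        mse = lam * s.mu_y**2 * (s.C_y**2 + s.C_x**2 + 2 * s.rho * s.C_y * s.C_x)
    elif name == "T3":
        D = (s.mu_x / s.mu_y) if literal else (s.mu_y / s.mu_x)
        mse = lam * (s.S2_y + 0.25 * D**2 * s.S2_x - D * s.S_yx)
    elif name == "T4":
        # published without the mu_y^2 scale; transcribed as printed
        mse = lam * s.C_y**2 * (1 - s.rho**2)
    elif name == "T5":
        if s.mu_x == 1.0:
            raise ValueError("T5 printed MSE undefined at mu_x = 1")
        k = 1.0 / math.log(s.mu_x)
        D = (s.mu_x / s.mu_y) if literal else (s.mu_y / s.mu_x)
        mse = lam * (s.S2_y + k**2 * D**2 * s.S2_x - 2 * k * D * s.S_yx)
        used["k"] = k
    elif name == "T6":
        mse = s.mu_y**2 * lam * s.C_y**2 * (1 - s.rho**2)
    elif name == "T7":
        # published minimum MSE; A and C are both given as mu_y^2 lam C_y^2
        A = s.mu_y**2 * lam * s.C_y**2
        B = lam * s.C_x**2
        C = s.mu_y**2 * lam * s.C_y**2
        D = s.mu_y * lam * s.rho * s.C_y * s.C_x
        E = s.mu_y * lam * (s.rho * s.C_y * s.C_x - s.C_x**2 / 2)
        mse = C + (B * C**2 + A * D**2 - 2 * C * D * E) / (E**2 - A * B)
    elif name == "T8":
        raise UnsupportedPrintedFormula(
            "T8's published MSE is under-specified (undefined constants); "
            "use series mode or empirical tuning")
    elif name == "TP1":
        if not {"k1", "k2"} <= spec.constants.keys():
            raise ValueError("printed TP1 MSE requires constants k1, k2")
        k1, k2 = spec.constants["k1"], spec.constants["k2"]
        c = theory_constants("P1", summary, design)
        mu = s.mu_y
        mse = (k1**2 * mu**2 * c.A1 - 2 * k1 * mu**2 * c.C1
               - 2 * k1 * k2 * mu * c.E1 + k2**2 * c.B1
               - 2 * k2 * mu * c.D1 + mu**2)
        bias = (lam * s.C_x**2 * (k1 * mu - k2) / 3
                - 0.5 * k1 * mu * lam * s.C_yx)
    elif name == "TP2":
        if not {"k3", "k4"} <= spec.constants.keys():
            raise ValueError("printed TP2 MSE requires constants k3, k4")
        k3, k4 = spec.constants["k3"], spec.constants["k4"]
        c = theory_constants("P2", summary, design)
        mu = s.mu_y
        mse = (k3**2 * mu**2 * c.A2 - 2 * k3 * mu**2 * c.C2
               - 2 * k3 * k4 * mu * c.E2 + k4**2 * c.B2
               - 2 * k4 * mu * c.C2 + mu**2)
        bias = -lam * s.C_x**2 * (k3 * mu - k4) / 8
    else:
        raise ValueError(f"unknown estimator {name!r}")

    return TheoryResult(estimator=name, mode="printed", mse=float(mse),
                        bias=bias, constants_used=used)


# ---------------------------------------------------------------------------
# series-mode optimal constants
# ---------------------------------------------------------------------------

_FREE_CONSTANTS = {"P1": ("k1", "k2"), "P2": ("k3", "k4")}
_WHICH_NAME = {"P1": "TP1", "P2": "TP2"}


def _series_mse_fn(which, summary, design):
    names = _FREE_CONSTANTS[which]
    est = _WHICH_NAME[which]

    def f(ka: float, kb: float) -> float:
        spec = EstimatorSpec(est, {names[0]: ka, names[1]: kb})
        return series_bias_mse(spec, summary, design).mse

    return f


def _quadratic_form(f):
    """Recover (H, b, c) of the exact quadratic f(k) = c + b.k + k.H.k/2
    from six evaluations."""
    m00 = f(0, 0)
    m10, m01 = f(1, 0), f(0, 1)
    m20, m02 = f(2, 0), f(0, 2)
    m11 = f(1, 1)
    q11 = (m20 - 2 * m10 + m00) / 2
    q22 = (m02 - 2 * m01 + m00) / 2
    q1 = m10 - m00 - q11
    q2 = m01 - m00 - q22
    q12 = m11 - (m00 + q1 + q2 + q11 + q22)
    H = np.array([[2 * q11, q12], [q12, 2 * q22]])
    b = np.array([q1, q2])
    return H, b, m00


def derived_optimal_k(
    which,
    summary: PopulationSummary,
    design: DesignSpec,
    *,
    box: float = 100.0,
) -> tuple[tuple[float, float], str]:
    """Constants minimizing the series-mode MSE; the package's own optimum.

    The series MSE is an exact quadratic in the two constants.  When its
    Hessian is positive definite the closed-form solution (one Newton
    refinement) is returned with status ``"ok"``.  Otherwise -- the TP2
    surface is unbounded below along ``k4 = -k3 mu_y`` at first order -- a
    bounded search over ``[-box, box]^2`` is run and status
    ``"degenerate"`` is returned.
    """
    from scipy.optimize import minimize

    f = _series_mse_fn(which, summary, design)
    H, b, _ = _quadratic_form(f)
    det = H[0, 0] * H[1, 1] - H[0, 1] ** 2
    scale = max(abs(H[0, 0] * H[1, 1]), abs(H[0, 1] ** 2), 1e-300)
    if H[0, 0] > 0 and det > 1e-12 * scale:
        k = np.linalg.solve(H, -b)
        k = k + np.linalg.solve(H, -(H @ k + b))  # one refinement step
        return (float(k[0]), float(k[1])), "ok"
    # degenerate: search the box
    best = None
    for x0 in ([0.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [box / 2, -box / 2]):
        res = minimize(lambda k: f(k[0], k[1]), x0, method="L-BFGS-B",
                       bounds=[(-box, box), (-box, box)])
        if best is None or res.fun < best.fun:
            best = res
    return (float(best.x[0]), float(best.x[1])), "degenerate"


def series_mse_gradient(which, summary, design, k: tuple[float, float]) -> np.ndarray:
    """Exact gradient of the series-mode MSE quadratic at ``k``."""
    H, b, _ = _quadratic_form(_series_mse_fn(which, summary, design))
    return H @ np.asarray(k, dtype=float) + b


# ---------------------------------------------------------------------------
# efficiency
# ---------------------------------------------------------------------------

def pre(reference_mse: float, mse: float) -> float:
    """Percent relative efficiency ``100 * reference / mse``; > 100 means
    the candidate beats the reference."""
    if reference_mse <= 0:
        raise ValueError("reference MSE must be positive")
    if mse <= 0:
        raise ValueError("MSE must be positive")
    return 100.0 * reference_mse / mse


def _mode_mse(spec, summary, design, mode):
    if mode == "series":
        return series_bias_mse(spec, summary, design).mse
    if mode == "printed":
        return printed_bias_mse(spec, summary, design).mse
    raise ValueError(f"mode must be 'series' or 'printed', got {mode!r}")


def efficiency_margin(
    proposed: EstimatorSpec,
    competitor: EstimatorSpec,
    summary: PopulationSummary,
    design: DesignSpec,
    mode: str = "series",
) -> float:
    """``MSE(competitor) - MSE(proposed)`` in the chosen theory mode;
    positive means the proposed estimator dominates."""
    return (_mode_mse(competitor, summary, design, mode)
            - _mode_mse(proposed, summary, design, mode))
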