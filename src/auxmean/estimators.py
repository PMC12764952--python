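"""Point estimators of a finite-population mean using a known auxiliary mean.

The family covers the classical sample mean ``T0``, the ratio (``T1``),
product (``T2``), exponential-ratio (``T3``) and regression (``T4``)
estimators, several log-transformed-auxiliary estimators (``T5``--``T8``),
and two log-ratio-type estimators ``TP1`` and ``TP2`` that carry free tuning
constants:

.. math::

    T_{P1} = (k_1 \\bar y + k_2)\\,
             \\frac{\\mu_x \\ln(\\bar x/\\mu_x)}{\\bar x - \\mu_x},
    \\qquad
    T_{P2} = (k_3 \\bar y + k_4)\\,
             \\ln(\\bar x/\\mu_x)\\,
             e^{(\\bar x - \\mu_x)/(\\bar x + \\mu_x)} .

The ``TP1`` adjustment factor is extended continuously to 1 at
``xbar == mu_x``; ``TP2`` vanishes there by construction and is returned as 0
with a degeneracy flag rather than an error so Monte-Carlo replication never
aborts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .moments import PopulationSummary, SampleMoments

__all__ = [
    "ESTIMATOR_NAMES",
    "EstimatorSpec",
    "EstimateResult",
    "estimate",
    "tp1_adjustment",
    "tp2_adjustment",
    "default_t6_alpha",
]

ESTIMATOR_NAMES = (
    "T0", "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "TP1", "TP2",
)

#: constants each estimator needs beyond the sample and mu_x; None means
#: "resolvable from a PopulationSummary" rather than strictly required.
_REQUIRED_CONSTANTS: dict[str, tuple[str, ...]] = {
    "T7": ("w1", "w2"),
    "T8": ("K1", "K2"),
    "TP1": ("k1", "k2"),
    "TP2": ("k3", "k4"),
}


@dataclass(frozen=True)
class EstimatorSpec:
    """An estimator name plus the free constants / variant it is run with.

    ``variant`` selects between the literature form exactly as published
    (``"paper-literal"``) and the standard textbook form (``"standard"``)
    for the estimators where the two differ (``T5``).  ``constants`` holds
    k1/k2 (TP1), k3/k4 (TP2), w1/w2 (T7), K1/K2 and optionally Md (T8),
    alpha (T6), phi1 (T4 override).
    """

    name: str
    constants: dict[str, float] = field(default_factory=dict)
    variant: str = "standard"

    def __post_init__(self) -> None:
        if self.name not in ESTIMATOR_NAMES:
            raise ValueError(f"unknown estimator {self.name!r}")
        if self.variant not in ("standard", "paper-literal"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class EstimateResult:
    name: str
    value: float
    constants_used: dict[str, float]
    notes: tuple[str, ...] = ()


def tp1_adjustment(xbar: float, mu_x: float) -> float:
    """The TP1 multiplier ``mu_x * ln(xbar/mu_x) / (xbar - mu_x)``.

    Continuously extended to 1 at ``xbar == mu_x`` (the limit of
    ``log(1+u)/u`` as ``u -> 0``); always positive for positive arguments.
    """
    if xbar <= 0 or mu_x <= 0:
        raise ValueError("tp1_adjustment requires xbar > 0 and mu_x > 0")
    u = (xbar - mu_x) / mu_x
    if u == 0.0:
        return 1.0
    return math.log1p(u) / u


def tp2_adjustment(xbar: float, mu_x: float) -> float:
    """The TP2 multiplier ``ln(xbar/mu_x) * exp((xbar-mu_x)/(xbar+mu_x))``.

    Zero at ``xbar == mu_x``; shares the sign of ``xbar - mu_x``.
    """
    if xbar <= 0 or mu_x <= 0:
        raise ValueError("tp2_adjustment requires xbar > 0 and mu_x > 0")
    u = (xbar - mu_x) / mu_x
    return math.log1p(u) * math.exp((xbar - mu_x) / (xbar + mu_x))


def default_t6_alpha(summary: PopulationSummary) -> float:
    """MSE-optimal T6 constant ``alpha = -mu_y * rho * C_y / C_x``."""
    if summary.C_x == 0 or math.isnan(summary.rho):
        raise ValueError("T6 optimal alpha undefined: C_x = 0 or rho undefined")
    return -summary.mu_y * summary.rho * summary.C_y / summary.C_x


def _require(constants: dict[str, float], name: str) -> None:
    missing = [k for k in _REQUIRED_CONSTANTS.get(name, ()) if k not in constants]
    if missing:
        raise ValueError(f"{name} requires constants {missing}")


def estimate(
    spec: EstimatorSpec,
    sample: SampleMoments,
    mu_x: float,
    summary: PopulationSummary | None = None,
) -> EstimateResult:
    """Evaluate the named estimator on a sample given the known ``mu_x``.

    ``summary`` is consulted only for plug-in constants: T4's theoretical
    slope ``beta1 = S_yx/S_x^2`` under the ``paper-literal`` variant is not a
    thing -- T4 always uses the sample slope unless ``phi1`` is supplied or
    ``theoretical=1`` is set in ``constants``; T6's default ``alpha`` and
    T8's default ``Md`` (population median of x) come from ``summary``.
    """
    if mu_x <= 0:
        raise ValueError("mu_x must be strictly positive")
    name = spec.name
    c = dict(spec.constants)
    _require(c, name)
    ybar, xbar = sample.ybar, sample.xbar
    notes: list[str] = []
    used: dict[str, float] = {}

    needs_log = name in ("T3", "T5", "T6", "T7", "T8", "TP1", "TP2")
    if needs_log and xbar <= 0:
        raise ValueError(f"{name} requires xbar > 0, got {xbar}")

    if name == "T0":
        value = ybar
    elif name == "T1":
        value = mu_x * ybar / xbar
    elif name == "T2":
        value = ybar * xbar / mu_x
    elif name == "T3":
        value = ybar * math.exp((mu_x - xbar) / (mu_x + xbar))
    elif name == "T4":
        if "phi1" in c:
            phi1 = c["phi1"]
        elif c.get("theoretical"):
            if summary is None:
                raise ValueError("T4 theoretical slope requires a PopulationSummary")
            phi1 = summary.S_yx / summary.S2_x
        else:
            if sample.s2_x == 0:
                raise ValueError("T4 slope undefined: sample variance of x is zero")
            phi1 = sample.s_yx / sample.s2_x
        used["phi1"] = phi1
        value = ybar + phi1 * (mu_x - xbar)
    elif name == "T5":
        if math.log(mu_x) == 0.0:
            raise ValueError("T5 undefined at mu_x = 1 (log(mu_x) = 0)")
        if spec.variant == "paper-literal":
            # published form: uses the unknown mu_y; diagnostic use only
            if summary is None:
                raise ValueError("paper-literal T5 requires a PopulationSummary (mu_y)")
            if ybar <= 0:
                raise ValueError("paper-literal T5 requires ybar > 0")
            if math.log(xbar) == 0.0:
                raise ValueError("T5 undefined at xbar = 1 (log(xbar) = 0)")
            value = summary.mu_y * math.log(ybar) / math.log(xbar)
        else:
            if math.log(xbar) == 0.0:
                raise ValueError("T5 undefined at xbar = 1 (log(xbar) = 0)")
            value = ybar * math.log(mu_x) / math.log(xbar)
    elif name == "T6":
        if "alpha" in c:
            alpha = c["alpha"]
        else:
            if summary is None:
                raise ValueError("T6 requires alpha or a PopulationSummary")
            alpha = default_t6_alpha(summary)
        used["alpha"] = alpha
        value = ybar + alpha * math.log(xbar / mu_x)
    elif name == "T7":
        used = {"w1": c["w1"], "w2": c["w2"]}
        value = ybar * (c["w1"] + 1.0) + c["w2"] * math.log(xbar / mu_x)
    elif name == "T8":
        if "Md" in c:
            md = c["Md"]
        else:
            if summary is None:
                raise ValueError("T8 requires Md or a PopulationSummary")
            md = summary.median_x
        used = {"K1": c["K1"], "K2": c["K2"], "Md": md}
        if xbar + md <= 0 or mu_x + md <= 0:
            raise ValueError("T8 log arguments must be positive")
        # as published T8 involves x only: (K1 - K2) * log[(mu_x+Md)/(xbar+Md)]
        lr = math.log((mu_x + md) / (xbar + md))
        value = c["K1"] * lr + c["K2"] * (-lr)
    elif name == "TP1":
        used = {"k1": c["k1"], "k2": c["k2"]}
        value = (c["k1"] * ybar + c["k2"]) * tp1_adjustment(xbar, mu_x)
    elif name == "TP2":
        used = {"k3": c["k3"], "k4": c["k4"]}
        adj = tp2_adjustment(xbar, mu_x)
        value = (c["k3"] * ybar + c["k4"]) * adj
        if adj == 0.0:
            notes.append("degenerate: xbar == mu_x, TP2 identically 0")
    else:  # pragma: no cover
        raise AssertionError(name)

    return EstimateResult(name=name, value=float(value),
                          constants_used=used, notes=tuple(notes))
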