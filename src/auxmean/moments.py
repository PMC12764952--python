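"""Population and sample summary moments for SRSWOR mean estimation.

Everything downstream (estimator formulas, first-order theory, simulation)
consumes the quantities defined here: the finite-population means, variances
(``N-1`` divisor), covariance, coefficients of variation and the design
constant ``lam = (1-f)/n`` that scales all first-order variances under simple
random sampling without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PopulationSummary",
    "DesignSpec",
    "SampleMoments",
    "summarize_population",
    "design_constants",
    "summarize_sample",
    "consistency_check",
]


@dataclass(frozen=True)
class PopulationSummary:
    """Finite-population quantities every estimator and formula consumes.

    Variances and the covariance use the ``N-1`` divisor.  ``C_yx`` is the
    relative covariance ``S_yx / (mu_y * mu_x)``; for well-defined means it
    equals ``rho * C_y * C_x``.  ``rho`` is ``nan`` when either variance is
    zero (flagged, not raised, so degenerate populations can still be
    described).
    """

    N: int
    mu_y: float
    mu_x: float
    S2_y: float
    S2_x: float
    S_yx: float
    C_y: float
    C_x: float
    C_yx: float
    rho: float
    median_x: float

    @property
    def rho_defined(self) -> bool:
        return not np.isnan(self.rho)


@dataclass(frozen=True)
class DesignSpec:
    """SRSWOR design constants for a sample of size ``n`` from ``N`` units.

    ``lam = (1-f)/n = (N-n)/(N*n)`` is the finite-population-correction
    factor that multiplies every first-order variance term.
    """

    n: int
    N: int
    f: float
    lam: float


@dataclass(frozen=True)
class SampleMoments:
    """Sample means and second moments (``n-1`` divisor) from paired data."""

    n: int
    ybar: float
    xbar: float
    s2_y: float
    s2_x: float
    s_yx: float


def _paired(y: Sequence[float], x: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.ndim != 1 or x.ndim != 1:
        raise ValueError("y and x must be one-dimensional")
    if y.size != x.size:
        raise ValueError(f"length mismatch: len(y)={y.size}, len(x)={x.size}")
    if y.size < 2:
        raise ValueError(f"need at least 2 paired observations, got {y.size}")
    return y, x


def summarize_population(y: Sequence[float], x: Sequence[float]) -> PopulationSummary:
    """Compute :class:`PopulationSummary` from the full population vectors.

    ``rho`` is set to ``nan`` when either variable is constant; ``C_y``/``C_x``
    are ``nan`` when the corresponding mean is zero.
    """
    y, x = _paired(y, x)
    N = y.size
    mu_y = float(y.mean())
    mu_x = float(x.mean())
    S2_y = float(y.var(ddof=1))
    S2_x = float(x.var(ddof=1))
    S_yx = float(np.cov(y, x, ddof=1)[0, 1])
    C_y = float(np.sqrt(S2_y) / mu_y) if mu_y != 0 else float("nan")
    C_x = float(np.sqrt(S2_x) / mu_x) if mu_x != 0 else float("nan")
    C_yx = float(S_yx / (mu_y * mu_x)) if mu_y != 0 and mu_x != 0 else float("nan")
    if S2_y > 0 and S2_x > 0:
        rho = float(S_yx / np.sqrt(S2_y * S2_x))
    else:
        rho = float("nan")
    return PopulationSummary(
        N=N, mu_y=mu_y, mu_x=mu_x, S2_y=S2_y, S2_x=S2_x, S_yx=S_yx,
        C_y=C_y, C_x=C_x, C_yx=C_yx, rho=rho, median_x=float(np.median(x)),
    )


def design_constants(n: int, N: int) -> DesignSpec:
    """SRSWOR design constants: sampling fraction ``f = n/N`` and
    ``lam = (1-f)/n = (N-n)/(N*n)``.
    """
    n = int(n)
    N = int(N)
    if n < 2:
        raise ValueError(f"sample size n must be >= 2, got {n}")
    if n > N:
        raise ValueError(f"sample size n={n} exceeds population size N={N}")
    f = n / N
    lam = (N - n) / (N * n)
    return DesignSpec(n=n, N=N, f=f, lam=lam)


def summarize_sample(y: Sequence[float], x: Sequence[float]) -> SampleMoments:
    """Sample means and ``n-1``-divisor second moments from paired data."""
    y, x = _paired(y, x)
    return SampleMoments(
        n=y.size,
        ybar=float(y.mean()),
        xbar=float(x.mean()),
        s2_y=float(y.var(ddof=1)),
        s2_x=float(x.var(ddof=1)),
        s_yx=float(np.cov(y, x, ddof=1)[0, 1]),
    )


@dataclass
class ConsistencyReport:
    """Violations of the internal redundancies of a :class:`PopulationSummary`."""

    violations: list[tuple[str, float]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, name: str, magnitude: float) -> None:
        self.violations.append((name, float(magnitude)))


def consistency_check(
    summary: PopulationSummary,
    *,
    tol: float = 1e-10,
) -> ConsistencyReport:
    """Check the redundant fields of a summary against one another.

    Checks (skipped where a participating field is undefined/nan):

    * ``S_yx^2 <= S2_y * S2_x``  (Cauchy-Schwarz)
    * ``rho == S_yx / sqrt(S2_y * S2_x)``
    * ``C_yx == rho * C_y * C_x``
    * ``C_y == sqrt(S2_y)/mu_y`` and likewise for x

    Returns a report listing each violated identity with the absolute
    magnitude of the discrepancy; the report is empty iff all hold within
    ``tol`` (absolute, on quantities of order one).
    """
    rep = ConsistencyReport()
    s = summary
    cs_excess = s.S_yx**2 - s.S2_y * s.S2_x
    scale = max(s.S2_y * s.S2_x, 1.0)
    if cs_excess > tol * scale:
        rep.add("cauchy_schwarz", cs_excess / scale)
    if s.S2_y > 0 and s.S2_x > 0 and not np.isnan(s.rho):
        d = abs(s.rho - s.S_yx / np.sqrt(s.S2_y * s.S2_x))
        if d > tol:
            rep.add("rho_vs_covariance", d)
    vals = (s.rho, s.C_y, s.C_x, s.C_yx)
    if not any(np.isnan(v) for v in vals):
        d = abs(s.C_yx - s.rho * s.C_y * s.C_x)
        if d > tol:
            rep.add("C_yx_vs_rho_Cy_Cx", d)
    if s.mu_y != 0 and not np.isnan(s.C_y):
        d = abs(s.C_y - np.sqrt(s.S2_y) / s.mu_y)
        if d > tol:
            rep.add("C_y_vs_S2_y", d)
    if s.mu_x != 0 and not np.isnan(s.C_x):
        d = abs(s.C_x - np.sqrt(s.S2_x) / s.mu_x)
        if d > tol:
            rep.add("C_x_vs_S2_x", d)
    return rep


def summary_from_config(
    *,
    N: int,
    mu_y: float,
    mu_x: float,
    C_y: float | None = None,
    C_x: float | None = None,
    rho: float | None = None,
    C_yx: float | None = None,
    S2_y: float | None = None,
    S2_x: float | None = None,
    S_yx: float | None = None,
    median_x: float | None = None,
) -> PopulationSummary:
    """Build a :class:`PopulationSummary` from published summary statistics.

    Accepts either coefficients of variation (``C_y``, ``C_x``) or variances
    (``S2_y``, ``S2_x``), and either ``rho`` or the covariance/relative
    covariance; missing redundant fields are filled from the others.
    """
    if S2_y is None:
        if C_y is None:
            raise ValueError("need C_y or S2_y")
        S2_y = (C_y * mu_y) ** 2
    elif C_y is None:
        C_y = float(np.sqrt(S2_y) / mu_y)
    if S2_x is None:
        if C_x is None:
            raise ValueError("need C_x or S2_x")
        S2_x = (C_x * mu_x) ** 2
    elif C_x is None:
        C_x = float(np.sqrt(S2_x) / mu_x)
    if S_yx is None:
        if rho is not None:
            S_yx = rho * float(np.sqrt(S2_y * S2_x))
        elif C_yx is not None:
            S_yx = C_yx * mu_y * mu_x
        else:
            raise ValueError("need rho, C_yx or S_yx")
    if rho is None:
        rho = float(S_yx / np.sqrt(S2_y * S2_x)) if S2_y > 0 and S2_x > 0 else float("nan")
    if C_yx is None:
        C_yx = float(S_yx / (mu_y * mu_x))
    return PopulationSummary(
        N=int(N), mu_y=float(mu_y), mu_x=float(mu_x),
        S2_y=float(S2_y), S2_x=float(S2_x), S_yx=float(S_yx),
        C_y=float(C_y), C_x=float(C_x), C_yx=float(C_yx), rho=float(rho),
        median_x=float(median_x) if median_x is not None else float(mu_x),
    )
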