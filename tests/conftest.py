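import numpy as np
import pytest

from auxmean.moments import design_constants, summarize_population
from auxmean.simulation import FinitePopulation


@pytest.fixture
def tiny_pop() -> FinitePopulation:
    """Small integer population (N=6) for exhaustive-enumeration oracles."""
    y = np.array([1.0, 3.0, 5.0, 7.0, 9.0, 11.0])
    x = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0])
    return FinitePopulation(y=y, x=x, summary=summarize_population(y, x))


@pytest.fixture
def design_n2_N6(tiny_pop):
    return design_constants(2, tiny_pop.N)


def random_summary(rng, *, lam_max=0.2, cv_max=0.5):
    """A random internally consistent PopulationSummary + DesignSpec pair."""
    from auxmean.moments import summary_from_config

    N = int(rng.integers(50, 2000))
    n = int(rng.integers(5, N // 2 + 1))  # guarantees lam = (N-n)/(Nn) <= 0.2
    mu_y = float(rng.uniform(5.0, 100.0))
    mu_x = float(rng.uniform(5.0, 100.0))
    C_y = float(rng.uniform(0.02, cv_max))
    C_x = float(rng.uniform(0.02, cv_max))
    rho = float(rng.uniform(-0.95, 0.95))
    summary = summary_from_config(N=N, mu_y=mu_y, mu_x=mu_x,
                                  C_y=C_y, C_x=C_x, rho=rho)
    design = design_constants(n, N)
    assert design.lam <= lam_max
    return summary, design
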