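import numpy as np
import pytest

from algalipid import datasets

# per-condition mean estimates for Coelastrum sp. HA-1 (five NaNO3 levels)
TABLE1_XMAX = [(0.075, 1.454), (0.15, 2.288), (0.3, 4.094), (0.6, 5.946), (0.9, 6.738)]
TABLE1_H0 = [(0.075, -0.624), (0.15, -0.719), (0.3, -1.338), (0.6, -1.289), (0.9, -1.593)]

# published empirical Xmax(N0) quadratic and h0(N0) line
PAPER_QUAD = (-7.891, 14.070, 0.439)
PAPER_H0_LINE = (-1.09, -0.6711)


@pytest.fixture(scope="session")
def ha1_conditions():
    return [datasets.fixture("HA1", N0=n0) for n0 in (0.075, 0.15, 0.3, 0.6, 0.9)]


@pytest.fixture(scope="session")
def csoro_conditions():
    return [datasets.fixture("Csoro", light=li) for li in (50, 100, 200)]


@pytest.fixture(scope="session")
def dense_times():
    """Sampling grid that resolves the nitrogen-depletion transient."""
    return tuple(np.concatenate([np.arange(0, 6, 0.25), np.arange(6.0, 25.0, 1.0)]))


def logistic_closed_form(t, X0, mu, Xmax):
    """Textbook logistic solution used as an independent oracle."""
    t = np.asarray(t, float)
    e = np.exp(mu * t)
    return X0 * Xmax * e / (Xmax - X0 + X0 * e)
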