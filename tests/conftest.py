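import numpy as np
import pytest

from symtrade import default_cost_set


@pytest.fixture(scope="session")
def costs():
    """The reference ATP cost set assembled from the built-in ledgers."""
    return default_cost_set()


@pytest.fixture
def rng():
    """Deterministic RNG for randomized property checks."""
    return np.random.default_rng(20261001)


def random_feasible_draw(rng):
    """One random parameterization with a mutually beneficial trade.

    Draws scalar costs satisfying the comparative-advantage condition
    (r_R < r_L1), a fixation cost no larger than the direct-uptake cost
    at s=1, and an exchange ratio strictly inside (r_R, r_L1); returns
    (a_LC, a_LN1, a_RC1, a_RN1, a_hat, r, c_L, c_R, b_L).
    """
    a_LC = rng.uniform(2.0, 20.0)
    a_RC1 = rng.uniform(2.0, 20.0)
    r_R = rng.uniform(0.5, 3.0)
    r_L1 = r_R * rng.uniform(1.05, 2.5)
    a_LN1 = r_L1 * a_LC
    a_RN1 = r_R * a_RC1
    a_hat = a_RN1 * rng.uniform(0.5, 1.0)  # fixation no costlier than direct uptake
    r = rng.uniform(r_R * 1.001, r_L1 * 0.999)
    c_L = rng.uniform(5.0, 30.0)
    c_R = rng.uniform(5.0, 30.0)
    b_L = rng.uniform(1.0, 20.0)
    return a_LC, a_LN1, a_RC1, a_RN1, a_hat, r, c_L, c_R, b_L
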