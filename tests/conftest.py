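import numpy as np
import pytest

import gxesim as g


@pytest.fixture(scope="session")
def low_ge():
    """A low-GEI TPE covariance, small enough for fast tests."""
    return g.scenario_covariance("low", 120, seed=7)


@pytest.fixture(scope="session")
def low_terms(low_ge):
    return g.decompose(low_ge, 7)


@pytest.fixture(scope="session")
def small_terms():
    """Full-rank terms of a tiny handmade covariance."""
    ge = np.array([[2.0, 1.0, 0.5], [1.0, 1.5, 0.3], [0.5, 0.3, 1.0]])
    return g.decompose(g.BetweenEnvCovariance(ge), 3)


def random_psd(rng, p, rank=None):
    """A random PSD matrix with strictly positive diagonal."""
    rank = rank or p
    a = rng.standard_normal((p, rank))
    m = a @ a.T / rank
    return m + 1e-6 * np.eye(p)
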