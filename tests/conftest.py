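import numpy as np
import pytest


def random_instance(seed, n=6, m=5, k=3, density=0.3, lam_scale=1.0):
    """A small random problem: binary A, symmetric unit-diagonal Wd/Ws, factors."""
    rng = np.random.default_rng(seed)
    A = (rng.uniform(size=(n, m)) < density).astype(float)
    X = rng.normal(size=(n, k))
    Y = rng.normal(size=(m, k))

    def sym(sz):
        raw = rng.uniform(size=(sz, sz))
        W = 0.5 * (raw + raw.T)
        np.fill_diagonal(W, 1.0)
        return W

    Wd, Ws = sym(n), sym(m)
    mu = float(rng.uniform(0.1, 2.0))
    lam = float(rng.uniform(0.0, 2.0)) * lam_scale
    return A, X, Y, Wd, Ws, mu, lam


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
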