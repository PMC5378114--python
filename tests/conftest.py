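import pytest

from evorescue import make_params


@pytest.fixture
def low_density_params():
    """Low-density rescue: K well above w0, mutants supercritical from the onset."""
    return make_params(w0=10000, K=110000, alpha=0.1, bm=1.3, dm=1.0, dw=1.0, mu=1e-4)


@pytest.fixture
def high_density_params():
    """High-density rescue: w0 = K, early mutants suppressed until w declines to w*."""
    return make_params(w0=10000, K=10000, alpha=0.3, bm=1.3, dm=1.0, dw=1.0, mu=1e-3)


@pytest.fixture
def marginal_params():
    """Slow decline with w0/K exactly at the density boundary and w0*mu = 1."""
    return make_params(w0=10000, K=110000, alpha=0.01, bm=1.1, dm=1.0, dw=1.0, mu=1e-4)
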