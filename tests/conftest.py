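import numpy as np
import pytest

from gtridge import DesignSpec, gen_design, svd_decompose


@pytest.fixture(scope="session")
def small_design():
    """Fixed 50x5 iid Gaussian design with its spectrum."""
    X = gen_design(DesignSpec(kind="iid", n=50, p=5, seed=11))
    return X, svd_decompose(X)


@pytest.fixture(scope="session")
def signal_data(small_design):
    """Design plus a response with genuine signal."""
    X, spec = small_design
    rng = np.random.default_rng(12)
    beta = np.array([0.8, 0.5, 0.0, 0.0, -0.3])
    y = X @ beta + rng.standard_normal(X.shape[0])
    return X, y, beta


@pytest.fixture(scope="session")
def tall_design():
    """Fixed 300x50 AR(1) design matching the main study dimensions."""
    X = gen_design(DesignSpec(kind="ar1", n=300, p=50, rho=0.5, seed=21))
    return X, svd_decompose(X)
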