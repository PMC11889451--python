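import numpy as np
import pytest

from miskit.data_model import DataMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, names=None, outcome=None) -> DataMatrix:
    values = np.asarray(values, dtype=float)
    names = names or [f"x{j + 1}" for j in range(values.shape[1])]
    return DataMatrix(values, names, outcome=outcome)


@pytest.fixture
def correlated_gaussian():
    """Complete bivariate Gaussian data with strong correlation, plus a
    factory that punches MCAR holes into it."""

    def build(n=200, rho=0.9, miss=0.2, seed=0):
        r = np.random.default_rng(seed)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        X = r.multivariate_normal([0, 0], cov, size=n)
        mask = r.random(X.shape) < miss
        # keep at least 2 observed per column
        for j in range(X.shape[1]):
            while (~mask[:, j]).sum() < 2:
                mask[r.integers(n), j] = False
        vals = X.copy()
        vals[mask] = np.nan
        return make_matrix(vals), X, mask

    return build
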