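import numpy as np
import pytest

from solvaprop.synthetic import FixtureSpec, make_fixture_dataset


@pytest.fixture(scope="session")
def small_fixture():
    """Small chromophore-solvent dataset shared across tests (24 x 8 pairs)."""
    spec = FixtureSpec(n_chromophores=24, seed=7)
    dataset, truth = make_fixture_dataset(spec)
    return spec, dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def numeric_gradient(f, param, eps=1e-6):
    """Central finite differences of scalar f() w.r.t. a Parameter tensor."""
    g = np.zeros_like(param.data)
    it = np.nditer(param.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = param.data[i]
        param.data[i] = old + eps
        f1 = float(f().data)
        param.data[i] = old - eps
        f2 = float(f().data)
        param.data[i] = old
        g[i] = (f1 - f2) / (2 * eps)
    return g
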