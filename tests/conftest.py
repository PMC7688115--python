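import numpy as np
import pytest

from tabletrade import GoodRegistry, Population, SimParams, init_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    return SimParams(t=200, omega=4, mu=0.3, mu_max=2.0, N=50)


def make_population(
    n_agents=12,
    active_wares=("ESA", "ESC"),
    rng=None,
    params=None,
):
    """A small population with the given wares activated."""
    rng = rng if rng is not None else np.random.default_rng(0)
    params = params or SimParams(t=400, omega=2, mu=0.1, mu_max=1.0, N=n_agents)
    goods = GoodRegistry()
    goods.set_active_wares(active_wares)
    return init_population(params, goods, rng)


def raw_population(produced, active_wares=(), rng=None):
    """A hand-built population (any size) for micro-fixtures."""
    rng = rng if rng is not None else np.random.default_rng(0)
    goods = GoodRegistry()
    goods.set_active_wares(active_wares)
    produced = np.asarray(produced, dtype=np.int64)
    n = produced.shape[0]
    return Population(
        goods=goods,
        produced=produced,
        values=1.0 - rng.random((n, goods.n_goods)),
        inventory=np.zeros((n, goods.n_goods)),
        score=np.zeros(n),
        tally=np.zeros(n),
    )


@pytest.fixture
def population(rng):
    return make_population(rng=rng)
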