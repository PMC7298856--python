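import numpy as np
import pytest

from vectorenm.grids import Grid, LayerStack
from vectorenm import synthetic as syn


@pytest.fixture(scope="session")
def grid60():
    return Grid(60, 60, 0.2, -100.0, 10.0)


@pytest.fixture(scope="session")
def spec60(grid60):
    return syn.SyntheticSpec(grid=grid60, seed=3)


@pytest.fixture(scope="session")
def stack60(spec60):
    return syn.gen_env_stack(spec60)


@pytest.fixture(scope="session")
def truth60(stack60, spec60):
    return syn.make_truth(stack60, spec60)


@pytest.fixture(scope="session")
def occ300(truth60):
    return syn.sample_occurrences(truth60, 300, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_stack():
    """4-layer 20x20 stack with a hand-built correlation structure."""
    r = np.random.default_rng(7)
    g = Grid(20, 20, 0.5, 0.0, 0.0)
    a = r.standard_normal(g.shape)
    b = 0.95 * a + 0.05 * r.standard_normal(g.shape)  # near-duplicate of a
    c = r.standard_normal(g.shape)
    d = 0.5 * c + 0.5 * r.standard_normal(g.shape)
    return LayerStack(g, {"a": a, "b": b, "c": c, "d": d})
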