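import numpy as np
import pytest
from hypothesis import settings

from deepneurite.imaging import ImageStack
from deepneurite.morphology import NeuronNode, NeuronTree

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def chain_tree(n: int, direction=(1.0, 0.0, 0.0), start=(0.0, 0.0, 0.0),
               type_code: int = 3, jitter: float = 0.0, seed: int = 0) -> NeuronTree:
    """Straight (optionally jittered) chain of n nodes with unit spacing."""
    g = np.random.default_rng(seed)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    nodes = []
    pos = np.asarray(start, dtype=float)
    for i in range(n):
        p = pos + i * d
        if jitter:
            p = p + g.normal(0, jitter, 3)
        nodes.append(NeuronNode(i + 1, type_code, *p, 1.0, i if i else -1))
    return NeuronTree(nodes)


def random_tree(rng: np.random.Generator, n: int = 30) -> NeuronTree:
    """Random valid forest for round-trip style tests."""
    nodes = []
    for i in range(n):
        parent = -1 if i == 0 or rng.random() < 0.1 else int(rng.integers(1, i + 1))
        nodes.append(
            NeuronNode(
                i + 1,
                int(rng.integers(0, 5)),
                float(rng.uniform(0, 100)),
                float(rng.uniform(0, 100)),
                float(rng.uniform(0, 30)),
                float(rng.uniform(0.5, 3.0)),
                parent,
            )
        )
    return NeuronTree(nodes)


@pytest.fixture
def tiny_stack():
    v = np.zeros((5, 8, 8), dtype=np.uint16)
    v[2, 3, 4] = 900
    return ImageStack(v)
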