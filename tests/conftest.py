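import numpy as np
import pytest

from sdfa import ActivationKind, LayerSpec, init_weights


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tanh_net():
    """A 3-4-2 tanh network with a linear output layer, fixed seed."""
    specs = (
        LayerSpec(3, 4, ActivationKind.TANH),
        LayerSpec(4, 2, ActivationKind.LINEAR),
    )
    return init_weights(specs, seed=7), specs


def random_net(rng, depth=None, max_width=6):
    """Random small architecture for gradient-oracle checks."""
    depth = depth or int(rng.integers(1, 4))
    widths = [int(rng.integers(2, max_width + 1)) for _ in range(depth + 1)]
    kinds = [ActivationKind.TANH, ActivationKind.SIGMOID, ActivationKind.LINEAR]
    specs = tuple(
        LayerSpec(widths[i], widths[i + 1],
                  kinds[int(rng.integers(len(kinds)))] if i < depth - 1
                  else ActivationKind.LINEAR)
        for i in range(depth)
    )
    return init_weights(specs, seed=int(rng.integers(2**31 - 1))), specs
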