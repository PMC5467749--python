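import numpy as np
import pytest

from predcoding import MLPArchitecture, PCNParams, WeightMatrices


def glorot_network(seed: int, max_layers: int = 4, max_nodes: int = 10,
                   activation: str | None = None, scale: float = 0.5):
    """Random small network with Glorot-uniform weights at half scale.

    Half-scale keeps every unit in its responsive regime and the
    fixed-point map well conditioned, so numerical comparisons against
    analytic references are limited by solver tolerance, not by weight
    draws near saturation."""
    rng = np.random.default_rng(seed)
    nl = int(rng.integers(2, max_layers + 1))
    sizes = tuple(int(s) for s in rng.integers(1, max_nodes + 1, size=nl + 1))
    act = activation or ["linear", "tanh", "logistic"][seed % 3]
    arch = MLPArchitecture(sizes, act)
    mats = []
    for l in range(1, arch.l_max + 1):
        r, c = arch.weight_shape(l)
        b = scale * np.sqrt(6.0 / (r + c))
        mats.append(rng.uniform(-b, b, (r, c)))
    return arch, WeightMatrices(mats), rng


@pytest.fixture
def chain_111():
    """1-1-1 tanh chain at the generative weights (1, 1)."""
    arch = MLPArchitecture((1, 1, 1), "tanh")
    weights = WeightMatrices([np.array([[1.0]]), np.array([[1.0]])])
    return arch, weights


@pytest.fixture
def small_pcn():
    """A 2-3-2 tanh PCN with fixed weights, unit variances."""
    arch = MLPArchitecture((2, 3, 2), "tanh")
    rng = np.random.default_rng(11)
    mats = [rng.uniform(-0.8, 0.8, arch.weight_shape(l)) for l in range(1, 3)]
    return PCNParams.from_weights(arch, WeightMatrices(mats), 1.0)
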