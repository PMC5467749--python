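"""Reference multilayer perceptron trained by error backpropagation.

Layer indexing convention (used consistently across this package, and the
reverse of most deep-learning libraries): **layer 0 is the output layer**
and layer ``l_max`` is the input layer.  A weight matrix at *level* ``l``
(for ``l`` in ``1..l_max``) connects layer ``l`` to layer ``l - 1``::

    y(l-1)_i = sum_j  w(l)_{i,j} f(y(l)_j)        (+ w(l)_{i,0} if biased)

``y`` are pre-nonlinearity node inputs ("activities"); ``f(y)`` are node
outputs.  The training objective is the *negative* half sum of squared
output errors, ``E = -1/2 sum_i (s_out_i - y(0)_i)^2``, so it is bounded
above by 0 and **maximized** by gradient ascent.  This sign convention makes
the correspondence with the free energy of the predictive-coding network
(which is likewise maximized) exact.

When a bias is enabled, it is stored as an extra leading column (index 0)
of each weight matrix; the forward pass feeds it a constant output of 1 and
no error term is ever propagated into it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ACTIVATIONS",
    "MLPArchitecture",
    "WeightMatrices",
    "ForwardState",
    "DeltaTerms",
    "ann_forward",
    "ann_objective",
    "ann_deltas",
    "ann_gradient",
    "apply_update",
]


def _logistic(x: np.ndarray) -> np.ndarray:
    # numerically stable on both tails
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


#: Registry of (f, f') pairs keyed by activation name.  Derivatives are
#: expressed in terms of x (not f(x)) so they can be evaluated directly on
#: node activities.
ACTIVATIONS: dict[str, tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]]] = {
    "linear": (lambda x: x, lambda x: np.ones_like(x)),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "logistic": (_logistic, lambda x: _logistic(x) * (1.0 - _logistic(x))),
}


@dataclass(frozen=True)
class MLPArchitecture:
    """Shape and nonlinearity of a layered network.

    Parameters
    ----------
    layer_sizes
        Node counts ``(n(0), n(1), ..., n(l_max))`` with **index 0 the
        output layer** and the last entry the input layer.
    activation
        One of ``"linear"``, ``"tanh"``, ``"logistic"``.
    has_bias
        If true, every weight matrix carries an extra bias column
        (index 0) whose presynaptic output is the constant 1.
    """

    layer_sizes: tuple[int, ...]
    activation: str = "tanh"
    has_bias: bool = False

    def __post_init__(self) -> None:
        sizes = tuple(int(n) for n in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        if len(sizes) < 2:
            raise ValueError("need at least 2 layers (output and input)")
        if any(n < 1 for n in sizes):
            raise ValueError("every layer must have at least one node")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}; "
                             f"choose from {sorted(ACTIVATIONS)}")

    @property
    def l_max(self) -> int:
        """Index of the input layer."""
        return len(self.layer_sizes) - 1

    def n(self, layer: int) -> int:
        return self.layer_sizes[layer]

    @property
    def f(self) -> Callable[[np.ndarray], np.ndarray]:
        return ACTIVATIONS[self.activation][0]

    @property
    def fprime(self) -> Callable[[np.ndarray], np.ndarray]:
        return ACTIVATIONS[self.activation][1]

    def weight_shape(self, level: int) -> tuple[int, int]:
        """Shape of the level-``level`` matrix (connecting layer
        ``level`` to layer ``level - 1``), bias column included."""
        if not 1 <= level <= self.l_max:
            raise IndexError(f"level must be in 1..{self.l_max}")
        rows = self.layer_sizes[level - 1]
        cols = self.layer_sizes[level] + (1 if self.has_bias else 0)
        return rows, cols


class WeightMatrices:
    """Per-level connection weights, indexed by level ``1..l_max``.

    ``weights[l]`` is the matrix mapping layer ``l`` outputs to layer
    ``l - 1`` activities.  The same container describes ANN weights ``w``
    and predictive-coding weights ``theta``; which interpretation applies
    is determined by the code using it.
    """

    def __init__(self, mats: Sequence[np.ndarray]):
        self.mats = [np.asarray(m, dtype=float) for m in mats]
        for m in self.mats:
            if m.ndim != 2:
                raise ValueError("each weight matrix must be 2-D")
            if not np.all(np.isfinite(m)):
                raise ValueError("weight matrices must be finite")

    @classmethod
    def zeros(cls, arch: MLPArchitecture) -> "WeightMatrices":
        return cls([np.zeros(arch.weight_shape(l)) for l in range(1, arch.l_max + 1)])

    def validate(self, arch: MLPArchitecture) -> None:
        if len(self.mats) != arch.l_max:
            raise ValueError(f"expected {arch.l_max} weight matrices, got {len(self.mats)}")
        for l in range(1, arch.l_max + 1):
            want = arch.weight_shape(l)
            if self[l].shape != want:
                raise ValueError(f"level {l} matrix has shape {self[l].shape}, expected {want}")

    def __getitem__(self, level: int) -> np.ndarray:
        return self.mats[level - 1]

    def __setitem__(self, level: int, value: np.ndarray) -> None:
        self.mats[level - 1] = np.asarray(value, dtype=float)

    def __len__(self) -> int:
        return len(self.mats)

    def copy(self) -> "WeightMatrices":
        return WeightMatrices([m.copy() for m in self.mats])

    def flatten(self) -> np.ndarray:
        """All entries concatenated into one vector (level order, C order)."""
        return np.concatenate([m.ravel() for m in self.mats]) if self.mats else np.zeros(0)

    def __add__(self, other: "WeightMatrices") -> "WeightMatrices":
        return WeightMatrices([a + b for a, b in zip(self.mats, other.mats)])

    def scaled(self, c: float) -> "WeightMatrices":
        return WeightMatrices([c * m for m in self.mats])

    def __repr__(self) -> str:
        return f"WeightMatrices({[m.shape for m in self.mats]})"


@dataclass
class ForwardState:
    """Activities of every layer after a forward pass.

    ``y[l]`` holds pre-activation inputs of layer ``l`` (``y[l_max]`` is the
    clamped input sample itself); ``fy[l] = f(y[l])``.  Arrays may carry a
    leading batch dimension.
    """

    arch: MLPArchitecture
    y: list[np.ndarray]
    fy: list[np.ndarray] = field(default_factory=list)

    @property
    def output(self) -> np.ndarray:
        return self.y[0]


#: Per-layer backpropagated error terms delta(l) for l in 0..l_max-1.
DeltaTerms = list


def _augment(fy: np.ndarray, has_bias: bool) -> np.ndarray:
    """Prepend the constant bias output 1 (column index 0) if enabled."""
    if not has_bias:
        return fy
    ones = np.ones(fy.shape[:-1] + (1,))
    return np.concatenate([ones, fy], axis=-1)


def ann_forward(weights: WeightMatrices, arch: MLPArchitecture, s_in: np.ndarray) -> ForwardState:
    """Layer-by-layer forward pass from the input layer ``l_max`` down to 0.

    ``s_in`` may be a single vector ``(n(l_max),)`` or a batch
    ``(m, n(l_max))``; all downstream arrays then share the batch shape.
    """
    weights.validate(arch)
    s_in = np.asarray(s_in, dtype=float)
    if s_in.shape[-1] != arch.n(arch.l_max):
        raise ValueError(
            f"s_in has {s_in.shape[-1]} entries but the input layer has {arch.n(arch.l_max)} nodes")
    f = arch.f
    y: list = [None] * (arch.l_max + 1)
    fy: list = [None] * (arch.l_max + 1)
    y[arch.l_max] = s_in
    fy[arch.l_max] = f(s_in)
    for l in range(arch.l_max - 1, -1, -1):
        pre = _augment(fy[l + 1], arch.has_bias)
        y[l] = pre @ weights[l + 1].T
        fy[l] = f(y[l])
    return ForwardState(arch=arch, y=y, fy=fy)


def ann_objective(y0: np.ndarray, s_out: np.ndarray) -> float:
    """Negative half sum of squared output errors (Table: E; maximized).

    For batched inputs the objective is summed over the batch.
    """
    y0 = np.asarray(y0, dtype=float)
    s_out = np.asarray(s_out, dtype=float)
    if y0.shape != s_out.shape:
        raise ValueError(f"shape mismatch: {y0.shape} vs {s_out.shape}")
    return float(-0.5 * np.sum((s_out - y0) ** 2))


def ann_deltas(weights: WeightMatrices, state: ForwardState, s_out: np.ndarray) -> DeltaTerms:
    """Backpropagated error terms, output layer first.

    delta(0) = s_out - y(0); for l >= 1,
    delta(l)_b = sum_i delta(l-1)_i w(l)_{i,b} f'(y(l)_b).
    Bias columns receive no delta (the bias node's output is constant).
    """
    arch = state.arch
    s_out = np.asarray(s_out, dtype=float)
    if s_out.shape != state.y[0].shape:
        raise ValueError(f"s_out shape {s_out.shape} != output shape {state.y[0].shape}")
    fp = arch.fprime
    off = 1 if arch.has_bias else 0
    deltas: DeltaTerms = [None] * arch.l_max
    deltas[0] = s_out - state.y[0]
    for l in range(1, arch.l_max):
        w = weights[l][:, off:]  # strip bias column: no error flows to the bias node
        deltas[l] = (deltas[l - 1] @ w) * fp(state.y[l])
    return deltas


def ann_gradient(state: ForwardState, deltas: DeltaTerms) -> WeightMatrices:
    """Gradient of E over every weight: dE/dw(a)_{b,c} = delta(a-1)_b f(y(a))_c.

    With batched states the per-sample outer products are **summed** over
    the batch (the gradient of the summed objective).
    """
    arch = state.arch
    grads = []
    for a in range(1, arch.l_max + 1):
        pre = _augment(state.fy[a], arch.has_bias)
        d = deltas[a - 1]
        if d.ndim == 1:
            g = np.outer(d, pre)
        else:
            g = d.reshape(-1, d.shape[-1]).T @ pre.reshape(-1, pre.shape[-1])
        grads.append(g)
    return WeightMatrices(grads)


def apply_update(weights: WeightMatrices, gradient: WeightMatrices, alpha: float) -> WeightMatrices:
    """One gradient-ascent step: w <- w + alpha * dE/dw."""
    if len(weights) != len(gradient):
        raise ValueError("weights and gradient have different numbers of levels")
    return WeightMatrices([w + alpha * g for w, g in zip(weights.mats, gradient.mats)])
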