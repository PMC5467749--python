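"""Supervised predictive-coding network with local Hebbian plasticity.

The network mirrors the layered Gaussian generative model

    P(x(l)_i | x(l+1)) = N(x(l)_i ; mu(l)_i, Sigma(l)_i),
    mu(l)_i = sum_j theta(l+1)_{i,j} f(x(l+1)_j),

for levels ``l = 0 .. l_max - 1`` (layer 0 = output, layer ``l_max`` =
input; see :mod:`predcoding.ann` for the indexing convention).  Inference
maximizes the free energy

    F = -1/2 sum_l sum_i (x(l)_i - mu(l)_i)^2 / Sigma(l)_i   <= 0

by evolving each unclamped node value along dF/dx (relaxation), which in
neural terms is mediated by prediction-error nodes
``eps(l)_i = (x(l)_i - mu(l)_i) / Sigma(l)_i``:

    dx(a)_b/dt = -eps(a)_b + sum_i eps(a-1)_i theta(a)_{i,b} f'(x(a)_b).

After relaxation, each weight changes by the product of the activities of
the two nodes it connects (Hebbian): d theta(a)_{b,c} = eps*(a-1)_b f(x*(a)_c).

Two operating modes:

* **prediction mode** — only the input layer is clamped; the fixed point
  reproduces the ANN forward pass exactly (all eps -> 0, F* -> 0);
* **learning mode** — input and output layers are both clamped; the fixed
  point errors carry backprop-like signals, and as the output variance
  ``Sigma(0)`` grows the weight update converges in direction to the
  backpropagation gradient.

Relaxation uses an explicit Euler scheme with an adaptive step (initial
0.2) that halves when the system is not converging: when the maximum
change in node activity per step runs far beyond the previously accepted
change, when the maximum velocity has barely decayed over a 50-step
window (marginal Euler stability), or when a trial step would decrease F.
After well-behaved steps it recovers geometrically toward the initial
value, so transient shrinks do not stall the integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ann import MLPArchitecture, WeightMatrices, ann_forward, _augment

__all__ = [
    "PCNParams",
    "PCNState",
    "RelaxationConfig",
    "DivergenceError",
    "make_sigma",
    "pcn_mu",
    "pcn_epsilon",
    "pcn_free_energy",
    "pcn_velocity",
    "pcn_relax",
    "pcn_weight_update",
    "pcn_train_step",
    "epsilon_recursion",
]


class DivergenceError(RuntimeError):
    """Relaxation produced non-finite node values."""

    def __init__(self, iteration: int):
        super().__init__(f"relaxation diverged (non-finite values) at iteration {iteration}")
        self.iteration = iteration


def make_sigma(arch: MLPArchitecture, values) -> list[np.ndarray]:
    """Build per-node variance vectors for levels ``0 .. l_max - 1``.

    ``values`` may be a single scalar (shared by every node on every
    level), a sequence of one scalar per level, or a sequence of per-level
    vectors.  All entries must be strictly positive.
    """
    n_levels = arch.l_max
    if np.isscalar(values):
        sig = [np.full(arch.n(l), float(values)) for l in range(n_levels)]
    else:
        if len(values) != n_levels:
            raise ValueError(f"expected {n_levels} sigma entries (levels 0..{n_levels - 1})")
        sig = []
        for l, v in enumerate(values):
            v = np.asarray(v, dtype=float)
            sig.append(np.full(arch.n(l), float(v)) if v.ndim == 0 else v.copy())
    for l, v in enumerate(sig):
        if v.shape != (arch.n(l),):
            raise ValueError(f"sigma at level {l} has shape {v.shape}, expected ({arch.n(l)},)")
        if np.any(v <= 0):
            raise ValueError("all variance parameters must be strictly positive")
    return sig


@dataclass
class PCNParams:
    """Weights ``theta`` and fixed per-node variances ``Sigma``."""

    arch: MLPArchitecture
    theta: WeightMatrices
    sigma: list[np.ndarray]

    def __post_init__(self) -> None:
        self.theta.validate(self.arch)
        self.sigma = make_sigma(self.arch, self.sigma)

    @classmethod
    def from_weights(cls, arch: MLPArchitecture, theta: WeightMatrices, sigma=1.0) -> "PCNParams":
        return cls(arch=arch, theta=theta, sigma=make_sigma(arch, sigma))

    @property
    def sigma0_scalar(self) -> float:
        """Output-layer variance as a scalar (all experiments set it
        uniformly; the first node's value is used)."""
        return float(self.sigma[0][0])

    def copy(self) -> "PCNParams":
        return PCNParams(self.arch, self.theta.copy(), [s.copy() for s in self.sigma])


@dataclass
class PCNState:
    """Node values, predictions and prediction errors at one instant.

    ``x[l]`` exists for every layer; ``mu[l]`` and ``eps[l]`` only for
    ``l < l_max`` (the input layer is predicted by nothing).  Arrays may
    carry a leading batch dimension.  ``clamped[l]`` marks layers whose
    values are held fixed during relaxation.
    """

    arch: MLPArchitecture
    x: list[np.ndarray]
    mu: list[np.ndarray]
    eps: list[np.ndarray]
    clamped: list[bool]
    converged: bool = True
    iterations: int = 0
    trace: Optional[list] = None  # rows (iteration, step, F, max |dx/dt|)

    def free_energy(self, params: "PCNParams") -> float:
        return pcn_free_energy(self, params)


def pcn_mu(params: PCNParams, x: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Top-down predictions mu(l)_i = sum_j theta(l+1)_{i,j} f(x(l+1)_j)
    for levels 0..l_max-1 (plus the bias term when enabled)."""
    arch = params.arch
    f = arch.f
    mu: list = [None] * arch.l_max
    for l in range(arch.l_max - 1, -1, -1):
        pre = _augment(f(np.asarray(x[l + 1], dtype=float)), arch.has_bias)
        mu[l] = pre @ params.theta[l + 1].T
    return mu


def pcn_epsilon(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Variance-normalized prediction error (x - mu) / Sigma."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if x.shape[-1] != mu.shape[-1] or x.shape[-1] != sigma.shape[-1]:
        raise ValueError("x, mu and sigma lengths differ")
    return (x - mu) / sigma


def _all_eps(params: PCNParams, x: Sequence[np.ndarray], mu: Sequence[np.ndarray]) -> list[np.ndarray]:
    return [pcn_epsilon(x[l], mu[l], params.sigma[l]) for l in range(params.arch.l_max)]


def pcn_free_energy(state: PCNState, params: PCNParams) -> float:
    """F = -1/2 sum_l sum_i (x(l)_i - mu(l)_i)^2 / Sigma(l)_i, summed over
    any batch dimension."""
    total = 0.0
    for l in range(params.arch.l_max):
        total += float(np.sum((state.x[l] - state.mu[l]) ** 2 / params.sigma[l]))
    return -0.5 * total


def pcn_velocity(state: PCNState, params: PCNParams) -> list[np.ndarray]:
    """Time derivative dF/dx of every node value; clamped layers get 0.

    Layer 0 (if unclamped, i.e. prediction mode) has no lower neighbour so
    only the ``-eps(0)`` term applies; the input layer (if ever unclamped)
    has no error node of its own so only the bottom-up term applies.
    """
    arch = params.arch
    fp = arch.fprime
    off = 1 if arch.has_bias else 0
    vel: list = []
    for a in range(arch.l_max + 1):
        if state.clamped[a]:
            vel.append(np.zeros_like(state.x[a]))
            continue
        v = np.zeros_like(state.x[a])
        if a < arch.l_max:
            v = v - state.eps[a]
        if a >= 1:
            w = params.theta[a][:, off:]
            v = v + (state.eps[a - 1] @ w) * fp(state.x[a])
        vel.append(v)
    return vel


def _max_abs(arrs: Sequence[np.ndarray]) -> float:
    m = 0.0
    for a in arrs:
        if a.size:
            m = max(m, float(np.max(np.abs(a))))
    return m


def _build_state(params: PCNParams, x: list[np.ndarray], clamped: list[bool]) -> PCNState:
    mu = pcn_mu(params, x)
    eps = _all_eps(params, x, mu)
    return PCNState(arch=params.arch, x=x, mu=mu, eps=eps, clamped=clamped)


@dataclass(frozen=True)
class RelaxationConfig:
    """Euler integration controls for the inference phase.

    Exactly one stopping regime is active: if ``fixed_steps`` is set, that
    many Euler steps are taken (the protocol used for minibatch training);
    otherwise integration stops once ``max |dF/dx| < tolerance / Sigma(0)``
    or after ``max_iterations`` steps (then the state is returned with
    ``converged=False`` and a warning).
    """

    initial_step: float = 0.2
    shrink_factor: float = 0.5
    growth_factor: float = 1.1
    tolerance: float = 1e-6
    max_iterations: int = 1_000_000
    fixed_steps: Optional[int] = None

    def __post_init__(self) -> None:
        if self.initial_step <= 0 or self.tolerance <= 0 or self.max_iterations < 1:
            raise ValueError("step, tolerance and iteration cap must be positive")
        if not 0 < self.shrink_factor < 1:
            raise ValueError("shrink_factor must lie in (0, 1)")
        if self.growth_factor < 1:
            raise ValueError("growth_factor must be >= 1")
        if self.fixed_steps is not None and self.fixed_steps < 1:
            raise ValueError("fixed_steps must be a positive integer")


def pcn_relax(
    params: PCNParams,
    clamps: Sequence[Optional[np.ndarray]],
    init: Optional[Sequence[Optional[np.ndarray]]] = None,
    config: RelaxationConfig = RelaxationConfig(),
    record_trace: bool = False,
) -> PCNState:
    """Relax unclamped node values to a fixed point of the dynamics.

    Parameters
    ----------
    clamps
        One entry per layer ``0..l_max``; a vector (optionally batched)
        clamps that layer to fixed values, ``None`` leaves it free.
    init
        Starting values for unclamped layers (same layout); free layers
        with no entry start at 0.
    config
        Integration controls; see :class:`RelaxationConfig`.
    record_trace
        If true, the returned state carries a ``trace`` list of
        ``(iteration, step, F, max_velocity)`` rows (one per accepted
        step) for convergence diagnostics.
    """
    arch = params.arch
    if len(clamps) != arch.l_max + 1:
        raise ValueError(f"need one clamp entry per layer (got {len(clamps)}, want {arch.l_max + 1})")
    batch_shape: tuple = ()
    for c in clamps:
        if c is not None:
            batch_shape = np.asarray(c, dtype=float).shape[:-1]
            break
    x: list = []
    clamped: list[bool] = []
    for l in range(arch.l_max + 1):
        if clamps[l] is not None:
            v = np.asarray(clamps[l], dtype=float)
            if v.shape[-1] != arch.n(l):
                raise ValueError(f"clamp at layer {l} has wrong length")
            x.append(v.copy())
            clamped.append(True)
        else:
            if init is not None and init[l] is not None:
                v = np.asarray(init[l], dtype=float)
                v = np.broadcast_to(v, batch_shape + (arch.n(l),)).copy()
            else:
                v = np.zeros(batch_shape + (arch.n(l),))
            x.append(v)
            clamped.append(False)

    state = _build_state(params, x, clamped)
    F_cur = pcn_free_energy(state, params)
    step = config.initial_step
    tol = config.tolerance / params.sigma0_scalar
    prev_maxdx: Optional[float] = None
    trace: list = [] if record_trace else None  # type: ignore[assignment]

    fixed_mode = config.fixed_steps is not None
    limit = config.fixed_steps if fixed_mode else config.max_iterations
    it = 0
    converged = fixed_mode
    check_maxv: Optional[float] = None  # stagnation checkpoint (windowed)
    allow_growth = True
    stagnation_enabled = True
    probation = False
    while True:
        vel = pcn_velocity(state, params)
        maxv = _max_abs(vel)
        if not np.isfinite(maxv):
            raise DivergenceError(it)
        if not fixed_mode and maxv < tol:
            converged = True
            break
        if it >= limit:
            if not fixed_mode:
                warnings.warn("relaxation hit the iteration cap before reaching tolerance",
                              RuntimeWarning, stacklevel=2)
            break
        # step adaptation ("reduce should the system not be converging"):
        #  - every 50 steps, if the max velocity has barely decayed, the
        #    system is marginally (un)stable at this step size: halve and
        #    hold the smaller step until decay resumes;
        #  - otherwise let the step recover geometrically toward its
        #    initial value, so transient shrinks do not stall the run;
        #  - if the prospective max change in node activity (step * max
        #    velocity) far exceeds the previously accepted change, the
        #    integration is running away: halve.
        if it > 0 and it % 50 == 0:
            poor = check_maxv is not None and maxv > 0.9 * check_maxv
            if poor and stagnation_enabled:
                if probation:
                    # halving did not restore decay: the slow mode is
                    # physical, not a stability artefact — undo and give up
                    step = min(step / config.shrink_factor, config.initial_step)
                    stagnation_enabled = False
                    allow_growth = True
                else:
                    step *= config.shrink_factor
                    probation = True
                    allow_growth = False
            else:
                probation = False
                allow_growth = True
            check_maxv = maxv
        elif allow_growth:
            step = min(step * config.growth_factor, config.initial_step)
        if prev_maxdx is not None and step * maxv > 2.0 * prev_maxdx:
            step *= config.shrink_factor
        # trial step, shrinking further if F would decrease
        while True:
            x_new = [xi if cl else xi + step * vi
                     for xi, vi, cl in zip(state.x, vel, clamped)]
            trial = _build_state(params, x_new, clamped)
            F_new = pcn_free_energy(trial, params)
            if np.isfinite(F_new) and F_new >= F_cur - 1e-12 * max(1.0, abs(F_cur)):
                break
            if step < 1e-300:
                raise DivergenceError(it)
            step *= config.shrink_factor
        state, F_cur, prev_maxdx = trial, F_new, step * maxv
        it += 1
        if trace is not None:
            trace.append((it, step, F_cur, maxv))

    state.converged = converged
    state.iterations = it
    state.trace = trace
    return state


def relaxation_trace_to_csv(state: PCNState, path) -> None:
    """Dump a recorded relaxation trace as CSV (iteration, step, F, max|dx/dt|)."""
    import pandas as pd

    if state.trace is None:
        raise ValueError("state has no recorded trace; pass record_trace=True to pcn_relax")
    pd.DataFrame(state.trace, columns=["iteration", "step", "F", "max_velocity"]).to_csv(
        path, index=False)


def pcn_weight_update(
    state: PCNState,
    params: PCNParams,
    alpha: float = 1.0,
    scale_by_sigma0: bool = False,
) -> WeightMatrices:
    """Hebbian weight increment at the relaxed state.

    d theta(a)_{b,c} = alpha * eps*(a-1)_b * f(x*(a)_c); the bias column
    (if present) uses a presynaptic output of 1.  With ``scale_by_sigma0``
    the error values are first multiplied by ``Sigma(0)``, undoing the
    uniform 1/Sigma(0) shrinkage of all fixed-point errors so that runs
    with different output variances are directly comparable.

    With batched states the per-sample increments are **summed** over the
    batch.
    """
    arch = params.arch
    f = arch.f
    scale = params.sigma0_scalar if scale_by_sigma0 else 1.0
    incs = []
    for a in range(1, arch.l_max + 1):
        pre = _augment(f(state.x[a]), arch.has_bias)
        e = state.eps[a - 1] * scale
        if e.ndim == 1:
            g = np.outer(e, pre)
        else:
            g = e.reshape(-1, e.shape[-1]).T @ pre.reshape(-1, pre.shape[-1])
        incs.append(alpha * g)
    return WeightMatrices(incs)


def feedforward_init(params: PCNParams, s_in: np.ndarray) -> list[np.ndarray]:
    """Layerwise prediction pass used to initialize hidden nodes before
    learning-mode inference (all error nodes would converge to zero in the
    prediction phase, so this is the prediction-mode fixed point)."""
    fs = ann_forward(params.theta, params.arch, s_in)
    return [yi.copy() for yi in fs.y]


def pcn_train_step(
    params: PCNParams,
    s_in: np.ndarray,
    s_out: np.ndarray,
    config: RelaxationConfig = RelaxationConfig(),
    alpha: float = 0.001,
    scale_by_sigma0: bool = False,
) -> PCNParams:
    """One supervised learning step: clamp both ends, relax, update weights.

    Hidden layers start from the layerwise feedforward prediction; the
    output layer is then clamped to ``s_out`` and inference runs to the
    configured stopping rule, after which the Hebbian update is applied.
    """
    arch = params.arch
    s_in = np.asarray(s_in, dtype=float)
    s_out = np.asarray(s_out, dtype=float)
    if s_in.shape[-1] != arch.n(arch.l_max) or s_out.shape[-1] != arch.n(0):
        raise ValueError("training pair dimensions do not match the architecture")
    ff = feedforward_init(params, s_in)
    clamps: list = [None] * (arch.l_max + 1)
    clamps[0] = s_out
    clamps[arch.l_max] = s_in
    init: list = [None] + [ff[l] for l in range(1, arch.l_max)] + [None]
    state = pcn_relax(params, clamps, init, config)
    inc = pcn_weight_update(state, params, alpha=alpha, scale_by_sigma0=scale_by_sigma0)
    new = params.copy()
    new.theta = new.theta + inc
    return new


def epsilon_recursion(params: PCNParams, x_star: Sequence[np.ndarray], s_out: np.ndarray) -> list[np.ndarray]:
    """Fixed-point prediction errors computed recursively from the output
    layer, mirroring the backprop delta recursion:

    eps*(0) = (s_out - mu*(0)) / Sigma(0);
    eps*(a-1)_b = sum_i eps*(a-2)_i theta(a-1)_{i,b} f'(x*(a-1)_b)  (a-1 > 0).

    With all Sigma = 1 and ``x_star`` replaced by the ANN activities this
    reproduces the backpropagation error terms exactly.
    """
    arch = params.arch
    fp = arch.fprime
    off = 1 if arch.has_bias else 0
    mu = pcn_mu(params, x_star)
    eps: list = [None] * arch.l_max
    eps[0] = (np.asarray(s_out, dtype=float) - mu[0]) / params.sigma[0]
    for l in range(1, arch.l_max):
        w = params.theta[l][:, off:]
        eps[l] = (eps[l - 1] @ w) * fp(np.asarray(x_star[l], dtype=float))
    return eps
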