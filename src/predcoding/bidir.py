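"""Bidirectional association network: two observed nodes, one latent cause.

A minimal predictive-coding architecture in which both the input and the
output sample are presented to *bottom* nodes ``x(0)_1 = s_out`` and
``x(0)_2 = s_in``, while a single unconstrained top node ``x(1)`` (with a
flat prior) explains them through linear weights:

    P(x(0)_i | x(1)) = N(x(0)_i ; theta_i * x(1), Sigma(0)_i)
    F = -1/2 sum_i (x(0)_i - theta_i x(1))^2 / Sigma(0)_i

Inference moves the free nodes along dF/dx:

    dx(1)/dt  = sum_i eps_i theta_i,      eps_i = (x(0)_i - theta_i x(1)) / Sigma(0)_i
    dx(0)_i/dt = -eps_i                    (only for unclamped bottom nodes)

Learning is Hebbian, ``d theta_i = alpha * eps_i * x(1)*``.  The relative
variances shape what is learned: equal variances give the total-least-
squares (first principal component) association, a large output variance
recovers ordinary forward regression (the backprop limit), and a large
input variance recovers inverse regression.  Because the architecture is
symmetric, the trained network predicts in either direction by clamping
one bottom node and relaxing the rest.

The Euler relaxation follows the same adaptive policy as
:func:`predcoding.pcn.pcn_relax` (initial step 0.2, halving on runaway
activity changes or windowed velocity stagnation, geometric recovery,
tolerance stop scaled by the largest variance), specialised to this
two-node linear model for speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pcn import RelaxationConfig, DivergenceError

__all__ = [
    "BidirModel",
    "BidirState",
    "bidir_relax",
    "bidir_fixed_point",
    "bidir_train",
    "bidir_predict",
    "baseline_slopes",
    "rmse",
    "direction_tradeoff_experiment",
]

#: Bottom-node index receiving the *output* sample (paper order: node 1).
OUT_NODE = 0
#: Bottom-node index receiving the *input* sample (node 2).
IN_NODE = 1


@dataclass
class BidirModel:
    """Linear two-arm generative model with a flat prior on the top node.

    The flat-prior constant never enters any gradient and is not stored.
    """

    theta: np.ndarray
    sigma0: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.sigma0 = np.asarray(self.sigma0, dtype=float)
        if self.theta.ndim != 1 or self.theta.size < 2:
            raise ValueError("theta must be a vector with at least 2 entries")
        if self.sigma0.shape != self.theta.shape:
            raise ValueError("sigma0 must match theta in shape")
        if np.any(self.sigma0 <= 0):
            raise ValueError("all variances must be strictly positive")

    @property
    def forward_slope(self) -> float:
        """Slope of the learned s_in -> s_out prediction line (theta ratio)."""
        return float(self.theta[OUT_NODE] / self.theta[IN_NODE])


@dataclass
class BidirState:
    x1: float
    x0: np.ndarray
    eps0: np.ndarray
    clamped: np.ndarray  # boolean mask over bottom nodes
    converged: bool = True
    iterations: int = 0

    def free_energy(self, model: BidirModel) -> float:
        return float(-0.5 * np.sum((self.x0 - model.theta * self.x1) ** 2 / model.sigma0))


def bidir_fixed_point(model: BidirModel, x0: np.ndarray) -> float:
    """Closed-form top-node fixed point with all bottom nodes given:
    the variance-weighted least-squares estimate
    x(1)* = (sum_i theta_i x_i / Sigma_i) / (sum_i theta_i^2 / Sigma_i)."""
    x0 = np.asarray(x0, dtype=float)
    num = float(np.sum(model.theta * x0 / model.sigma0))
    den = float(np.sum(model.theta ** 2 / model.sigma0))
    if den == 0.0:
        raise ValueError("all weights are zero; top node is unconstrained")
    return num / den


def bidir_relax(
    model: BidirModel,
    clamps: Sequence[Optional[float]],
    init: Optional[Sequence[float]] = None,
    config: RelaxationConfig = RelaxationConfig(),
    x1_init: float = 0.0,
) -> BidirState:
    """Adaptive-Euler relaxation of the two-arm network.

    ``clamps`` has one entry per bottom node (value or None); at least one
    bottom node must be clamped.  ``init`` optionally supplies starting
    values for unclamped bottom nodes; ``x1_init`` starts the top node.
    """
    n = model.theta.size
    if len(clamps) != n:
        raise ValueError(f"need one clamp entry per bottom node (got {len(clamps)})")
    mask = np.array([c is not None for c in clamps])
    if not mask.any():
        raise ValueError("at least one bottom node must be clamped")
    x0 = np.zeros(n)
    for i, c in enumerate(clamps):
        if c is not None:
            x0[i] = float(c)
        elif init is not None and init[i] is not None:
            x0[i] = float(init[i])
    x1 = float(x1_init)

    step = config.initial_step
    tol = config.tolerance / float(np.max(model.sigma0))
    prev_maxdx: Optional[float] = None
    fixed_mode = config.fixed_steps is not None
    limit = config.fixed_steps if fixed_mode else config.max_iterations

    def F_of(x1v: float, x0v: np.ndarray) -> float:
        return float(-0.5 * np.sum((x0v - model.theta * x1v) ** 2 / model.sigma0))

    F_cur = F_of(x1, x0)
    it = 0
    converged = fixed_mode
    check_maxv: Optional[float] = None
    allow_growth = True
    stagnation_enabled = True
    probation = False
    while True:
        eps = (x0 - model.theta * x1) / model.sigma0
        v1 = float(np.sum(eps * model.theta))
        v0 = np.where(mask, 0.0, -eps)
        maxv = max(abs(v1), float(np.max(np.abs(v0))) if n else 0.0)
        if not np.isfinite(maxv):
            raise DivergenceError(it)
        if not fixed_mode and maxv < tol:
            converged = True
            break
        if it >= limit:
            break
        # same adaptation policy as pcn_relax: windowed stagnation halving,
        # geometric recovery, and a runaway check on the activity change
        if it > 0 and it % 50 == 0:
            poor = check_maxv is not None and maxv > 0.9 * check_maxv
            if poor and stagnation_enabled:
                if probation:
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
        while True:
            x1_new = x1 + step * v1
            x0_new = x0 + step * v0
            F_new = F_of(x1_new, x0_new)
            if np.isfinite(F_new) and F_new >= F_cur - 1e-12 * max(1.0, abs(F_cur)):
                break
            if step < 1e-300:
                raise DivergenceError(it)
            step *= config.shrink_factor
        x1, x0, F_cur, prev_maxdx = x1_new, x0_new, F_new, step * maxv
        it += 1

    eps = (x0 - model.theta * x1) / model.sigma0
    return BidirState(x1=x1, x0=x0, eps0=eps, clamped=mask,
                      converged=converged, iterations=it)


def _train_relax_top(theta: np.ndarray, sigma0: np.ndarray, x0: np.ndarray,
                     config: RelaxationConfig) -> tuple[float, int]:
    """Training-mode relaxation (both bottom nodes clamped) in scalar
    arithmetic: only the top node moves, following the same adaptive-Euler
    policy as :func:`bidir_relax`.  Returns (x1*, iterations).

    Exists because online training relaxes once per sample; plain floats
    keep the inner loop an order of magnitude cheaper than array ops."""
    th = [float(t) for t in theta]
    sg = [float(s) for s in sigma0]
    xs = [float(v) for v in x0]
    # dx1/dt = b - a*x1 with the coefficients below (linear model)
    a = sum(t * t / s for t, s in zip(th, sg))
    b = sum(t * x / s for t, x, s in zip(th, xs, sg))
    x1 = 0.0
    step = config.initial_step
    tol = config.tolerance / max(sg)
    fixed_mode = config.fixed_steps is not None
    limit = config.fixed_steps if fixed_mode else config.max_iterations
    F_cur = -0.5 * sum((x - t * x1) ** 2 / s for t, x, s in zip(th, xs, sg))
    prev_maxdx = None
    check_maxv = None
    allow_growth = True
    stagnation_enabled = True
    probation = False
    it = 0
    while True:
        v = b - a * x1
        maxv = abs(v)
        if not np.isfinite(maxv):
            raise DivergenceError(it)
        if not fixed_mode and maxv < tol:
            break
        if it >= limit:
            break
        if it > 0 and it % 50 == 0:
            poor = check_maxv is not None and maxv > 0.9 * check_maxv
            if poor and stagnation_enabled:
                if probation:
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
        while True:
            x1_new = x1 + step * v
            F_new = -0.5 * sum((x - t * x1_new) ** 2 / s for t, x, s in zip(th, xs, sg))
            if np.isfinite(F_new) and F_new >= F_cur - 1e-12 * max(1.0, abs(F_cur)):
                break
            if step < 1e-300:
                raise DivergenceError(it)
            step *= config.shrink_factor
        x1, F_cur, prev_maxdx = x1_new, F_new, step * maxv
        it += 1
    return x1, it


def bidir_train(
    model: BidirModel,
    dataset: np.ndarray,
    alpha: float = 1.0,
    config: RelaxationConfig = RelaxationConfig(),
    epochs: int = 1,
    seed: Optional[int] = None,
) -> BidirModel:
    """Online Hebbian training on (s_in, s_out) pairs.

    Each sample clamps both bottom nodes (output sample on node 1, input
    sample on node 2), relaxes the top node to its fixed point, then
    applies ``d theta_i = alpha * eps_i * x(1)*``.  ``seed`` shuffles the
    presentation order each epoch (None keeps dataset order).
    """
    data = np.asarray(dataset, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("dataset must be an (n, 2) array of (s_in, s_out) pairs")
    if model.theta.size != 2:
        raise ValueError("scalar-pair training requires the two-bottom-node model")
    theta = model.theta.copy()
    rng = np.random.default_rng(seed) if seed is not None else None
    for _ in range(int(epochs)):
        order = rng.permutation(len(data)) if rng is not None else np.arange(len(data))
        for k in order:
            s_in, s_out = data[k]
            x0 = np.array([s_out, s_in])
            x1, _ = _train_relax_top(theta, model.sigma0, x0, config)
            eps = (x0 - theta * x1) / model.sigma0
            theta = theta + alpha * eps * x1
    return BidirModel(theta=theta, sigma0=model.sigma0.copy())


def bidir_predict(
    model: BidirModel,
    clamp_index: int,
    clamp_value: float,
    config: RelaxationConfig = RelaxationConfig(),
) -> float:
    """Clamp one bottom node, relax the rest, return the other node's
    fixed-point value (works in either direction)."""
    n = model.theta.size
    if n != 2:
        raise ValueError("bidir_predict expects the two-node model")
    clamps: list = [None, None]
    clamps[clamp_index] = float(clamp_value)
    st = bidir_relax(model, clamps, config=config)
    other = 1 - clamp_index
    return float(st.x0[other])


def rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """Root mean squared error."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth have different lengths")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def baseline_slopes(dataset: np.ndarray) -> tuple[float, float, float]:
    """Reference slopes in the forward (s_in -> s_out) frame.

    Returns ``(ols_forward, ols_inverse, first_pc)``:

    * ``ols_forward`` — ordinary regression of s_out on s_in;
    * ``ols_inverse`` — regression of s_in on s_out, re-expressed as a
      forward slope (its reciprocal);
    * ``first_pc`` — slope of the leading principal axis of the centered
      two-column data (total least squares).
    """
    data = np.asarray(dataset, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or len(data) < 2:
        raise ValueError("dataset must be an (n>=2, 2) array of (s_in, s_out) pairs")
    s_in, s_out = data[:, 0], data[:, 1]
    var_in = float(np.var(s_in))
    var_out = float(np.var(s_out))
    cov = float(np.cov(s_in, s_out, bias=True)[0, 1])
    if var_in == 0.0 or var_out == 0.0:
        raise ValueError("degenerate data: a column has zero variance")
    ols_forward = cov / var_in
    if cov == 0.0:
        raise ValueError("degenerate data: zero covariance, inverse slope undefined")
    ols_inverse = var_out / cov
    c = np.cov(data.T, bias=True)
    evals, evecs = np.linalg.eigh(c)
    lead = evecs[:, np.argmax(evals)]  # columns of eigh are eigenvectors
    if lead[0] == 0.0:
        raise ValueError("leading principal axis is vertical in the forward frame")
    first_pc = float(lead[1] / lead[0])
    return ols_forward, ols_inverse, first_pc


#: Variance settings of the direction trade-off experiment; "large" is
#: 100x "small" (the same large-variance regime used for minibatch
#: training with output variance 100).
SIGMA_SETTINGS = {
    "equal": (1.0, 1.0),
    "large_output": (100.0, 1.0),   # backprop limit: best forward prediction
    "large_input": (1.0, 100.0),    # inverse-regression limit
}


def direction_tradeoff_experiment(
    n_train: int = 2000,
    n_test: int = 100,
    n_reps: int = 50,
    alpha: float = 1.0,
    epochs: int = 1,
    config: RelaxationConfig = RelaxationConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Train the three variance settings on sum/difference data and score
    forward and inverse prediction RMSE on held-out samples.

    Data: s_in = a + b, s_out = a - b with a ~ N(0,1), b ~ N(0,1/9); each
    repetition draws fresh train/test sets.  Returns one row per setting
    with mean and standard error of both RMSEs over repetitions, plus the
    mean learned forward slope.
    """
    from .data import gen_sum_diff

    rng = np.random.default_rng(seed)
    acc: dict[str, dict[str, list]] = {
        name: {"rmse_forward": [], "rmse_inverse": [], "slope": []} for name in SIGMA_SETTINGS
    }
    for _ in range(int(n_reps)):
        train = gen_sum_diff(n_train, seed=int(rng.integers(2 ** 31)))
        test = gen_sum_diff(n_test, seed=int(rng.integers(2 ** 31)))
        train_xy = np.column_stack([train.s_in.ravel(), train.s_out.ravel()])
        init_theta = rng.uniform(0.5, 1.5, size=2)
        for name, (sig_out, sig_in) in SIGMA_SETTINGS.items():
            model = BidirModel(theta=init_theta.copy(), sigma0=np.array([sig_out, sig_in]))
            trained = bidir_train(model, train_xy, alpha=alpha, config=config, epochs=epochs)
            # the model has zero intercept, so one relaxation at unit input
            # gives the whole prediction line in each direction
            slope = bidir_predict(trained, IN_NODE, 1.0, config)
            inv_slope = bidir_predict(trained, OUT_NODE, 1.0, config)
            fwd = slope * test.s_in.ravel()
            inv = inv_slope * test.s_out.ravel()
            acc[name]["rmse_forward"].append(rmse(fwd, test.s_out.ravel()))
            acc[name]["rmse_inverse"].append(rmse(inv, test.s_in.ravel()))
            acc[name]["slope"].append(slope)
    rows = []
    for name, d in acc.items():
        row = {"setting": name}
        for key in ("rmse_forward", "rmse_inverse", "slope"):
            v = np.asarray(d[key])
            row[f"{key}_mean"] = float(v.mean())
            row[f"{key}_sem"] = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
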