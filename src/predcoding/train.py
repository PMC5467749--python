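"""Minibatch training loops for the reference ANN and the PCN.

The protocol matches the handwritten-digit experiment: logistic units with
a bias node, weights drawn uniformly on ±4*sqrt(6/N) (N = total node
count of the two connected layers), minibatches of 20, Adam with learning
rate 0.001, and — for the predictive-coding network — 20 Euler steps of
inference per example with the error nodes rescaled by Sigma(0) before
the weight update so that runs with different output variances are
comparable.  Classification is by argmax of the output layer.

Both network kinds train from the same parameter container
(:class:`~predcoding.pcn.PCNParams`); the ANN path simply ignores the
variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .ann import MLPArchitecture, WeightMatrices, ann_forward, ann_deltas, ann_gradient
from .data import Dataset
from .pcn import PCNParams, RelaxationConfig, pcn_relax, pcn_weight_update, feedforward_init

__all__ = [
    "TrainingConfig",
    "AdamOptimizer",
    "SGDOptimizer",
    "init_weights",
    "train",
    "run_many",
    "aggregate_runs",
]


@dataclass
class TrainingConfig:
    """Minibatch training hyperparameters (defaults follow the digit
    experiment's protocol)."""

    batch_size: int = 20
    learning_rate: float = 0.001
    optimizer: str = "adam"
    epochs: int = 10
    inference_steps: int = 20        # PCN only: fixed Euler steps per example
    sigma0: float = 1.0              # PCN only: output-layer variance
    scale_by_sigma0: bool = True     # PCN only: rescale errors by Sigma(0)
    seed: int = 0
    runs: int = 10

    def __post_init__(self) -> None:
        if min(self.batch_size, self.inference_steps, self.runs) < 1 or self.epochs < 0:
            raise ValueError("counts must be positive (epochs may be 0)")
        if self.learning_rate <= 0 or self.sigma0 <= 0:
            raise ValueError("learning_rate and sigma0 must be positive")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def init_weights(arch: MLPArchitecture, seed: int) -> WeightMatrices:
    """Uniform initialization on ±4*sqrt(6/N), N being the total number of
    (non-bias) nodes in the two layers the weight connects; bias columns
    start at 0."""
    rng = np.random.default_rng(seed)
    mats = []
    for l in range(1, arch.l_max + 1):
        n_total = arch.n(l - 1) + arch.n(l)
        bound = 4.0 * np.sqrt(6.0 / n_total)
        rows, cols = arch.weight_shape(l)
        m = rng.uniform(-bound, bound, size=(rows, cols))
        if arch.has_bias:
            m[:, 0] = 0.0
        mats.append(m)
    return WeightMatrices(mats)


class SGDOptimizer:
    """Plain gradient ascent: one step equals apply_update with alpha = lr."""

    def __init__(self, learning_rate: float):
        self.lr = learning_rate

    def step(self, weights: WeightMatrices, grads: WeightMatrices) -> WeightMatrices:
        return WeightMatrices([w + self.lr * g for w, g in zip(weights.mats, grads.mats)])


class AdamOptimizer:
    """Adam with standard hyperparameters (beta1=0.9, beta2=0.999,
    eps=1e-8), applied as gradient *ascent* on the objective."""

    def __init__(self, learning_rate: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = learning_rate, beta1, beta2, eps
        self.t = 0
        self.m: Optional[list[np.ndarray]] = None
        self.v: Optional[list[np.ndarray]] = None

    def step(self, weights: WeightMatrices, grads: WeightMatrices) -> WeightMatrices:
        if self.m is None:
            self.m = [np.zeros_like(g) for g in grads.mats]
            self.v = [np.zeros_like(g) for g in grads.mats]
        self.t += 1
        out = []
        for k, (w, g) in enumerate(zip(weights.mats, grads.mats)):
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            out.append(w + self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return WeightMatrices(out)


def _make_optimizer(config: TrainingConfig):
    return (AdamOptimizer(config.learning_rate) if config.optimizer == "adam"
            else SGDOptimizer(config.learning_rate))


def _classification_error(arch: MLPArchitecture, weights: WeightMatrices,
                          dataset: Dataset) -> float:
    out = ann_forward(weights, arch, dataset.s_in).y[0]
    pred = np.argmax(out, axis=-1)
    truth = np.argmax(dataset.s_out, axis=-1)
    return 100.0 * float(np.mean(pred != truth))


def _batch_gradient(model: str, params: PCNParams, s_in: np.ndarray,
                    s_out: np.ndarray, config: TrainingConfig) -> WeightMatrices:
    """Mean per-example gradient (ANN) or Hebbian increment (PCN) over one
    minibatch.  PCN examples relax independently (batched) for the fixed
    number of inference steps before their increments are averaged."""
    arch = params.arch
    n = len(s_in)
    if model == "ann":
        fs = ann_forward(params.theta, arch, s_in)
        g = ann_gradient(fs, ann_deltas(params.theta, fs, s_out))
    else:
        relax_cfg = RelaxationConfig(fixed_steps=config.inference_steps)
        ff = feedforward_init(params, s_in)
        clamps: list = [None] * (arch.l_max + 1)
        clamps[0] = s_out
        clamps[arch.l_max] = s_in
        init: list = [None] + [ff[l] for l in range(1, arch.l_max)] + [None]
        state = pcn_relax(params, clamps, init, relax_cfg)
        g = pcn_weight_update(state, params, alpha=1.0,
                              scale_by_sigma0=config.scale_by_sigma0)
    return g.scaled(1.0 / n)


def train(
    model: str,
    params: PCNParams,
    dataset: Dataset,
    config: TrainingConfig,
    val_dataset: Optional[Dataset] = None,
) -> tuple[PCNParams, pd.DataFrame]:
    """Minibatch-train one network and record its learning curve.

    ``model`` is ``"ann"`` (backpropagation) or ``"pcn"`` (inference then
    Hebbian update).  Returns the final parameters and a per-epoch frame
    with ``train_error`` and ``val_error`` percentages (validation NaN if
    no validation set is given).  The run is a pure function of
    ``config.seed``.
    """
    if model not in ("ann", "pcn"):
        raise ValueError(f"model must be 'ann' or 'pcn', got {model!r}")
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    params = params.copy()
    if model == "pcn":
        params.sigma[0] = np.full(params.arch.n(0), config.sigma0)
    rng = np.random.default_rng(config.seed)
    opt = _make_optimizer(config)
    records = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(dataset))
        for start in range(0, len(dataset), config.batch_size):
            idx = order[start:start + config.batch_size]
            g = _batch_gradient(model, params, dataset.s_in[idx], dataset.s_out[idx], config)
            if not all(np.all(np.isfinite(m)) for m in g.mats):
                raise RuntimeError(
                    f"non-finite {model} gradient at epoch {epoch}, batch start {start}")
            params.theta = opt.step(params.theta, g)
        rec = {"epoch": epoch,
               "train_error": _classification_error(params.arch, params.theta, dataset),
               "val_error": (_classification_error(params.arch, params.theta, val_dataset)
                             if val_dataset is not None else np.nan)}
        records.append(rec)
    curve = pd.DataFrame(records, columns=["epoch", "train_error", "val_error"])
    return params, curve


def run_many(
    model: str,
    arch: MLPArchitecture,
    dataset: Dataset,
    config: TrainingConfig,
    val_dataset: Optional[Dataset] = None,
) -> list[pd.DataFrame]:
    """Repeat training ``config.runs`` times from fresh initializations
    (seeds ``config.seed + r``); returns one learning curve per run."""
    curves = []
    for r in range(config.runs):
        seed = config.seed + r
        theta = init_weights(arch, seed=seed)
        params = PCNParams.from_weights(arch, theta, sigma=config.sigma0)
        run_cfg = TrainingConfig(**{**config.__dict__, "seed": seed, "runs": 1})
        _, curve = train(model, params, dataset, run_cfg, val_dataset)
        curve = curve.assign(run=r)
        curves.append(curve)
    return curves


def aggregate_runs(curves: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-epoch mean and standard error of the mean across runs (curves
    are aligned to the shortest)."""
    if not curves:
        raise ValueError("need at least one learning curve")
    n_epochs = min(len(c) for c in curves)
    rows = []
    for e in range(n_epochs):
        row = {"epoch": e}
        for metric in ("train_error", "val_error"):
            vals = np.array([c[metric].iloc[e] for c in curves], dtype=float)
            row[f"{metric}_mean"] = float(np.mean(vals))
            row[f"{metric}_sem"] = (float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                                    if len(vals) > 1 else 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
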