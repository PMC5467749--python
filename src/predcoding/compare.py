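"""Quantitative comparison between backpropagation and predictive coding.

Implements the gradient-direction angle, the two-weight sweep on the
1-1-1 tanh chain (output = W1 tanh(W2 tanh(input))), and a per-variance
equivalence report.  The headline property: as the output variance
Sigma(0) grows, the angle between the predictive-coding weight increment
and the backpropagation gradient shrinks toward zero at every weight
setting off the zero-gradient ridge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ann import MLPArchitecture, WeightMatrices, ann_forward, ann_deltas, ann_gradient
from .pcn import PCNParams, RelaxationConfig, pcn_relax, pcn_weight_update, feedforward_init

__all__ = [
    "UndefinedAngleError",
    "ANGLE_SENTINEL",
    "AngleGrid",
    "gradient_angle",
    "angle_sweep",
    "equivalence_report",
]


class UndefinedAngleError(ValueError):
    """Angle requested between vectors at least one of which is (near) zero."""


#: Grid cells where either summed gradient vanishes (norm < 1e-12) carry
#: this sentinel instead of a number, so monotonicity checks can skip them
#: rather than silently comparing meaningless zeros.
ANGLE_SENTINEL = np.nan

_ZERO_NORM = 1e-12


def gradient_angle(g1: np.ndarray, g2: np.ndarray) -> float:
    """Angle in degrees, in [0, 180], between two flattened gradients.

    Invariant under positive rescaling of either argument; symmetric.
    Raises :class:`UndefinedAngleError` if either vector is (near) zero.
    """
    g1 = np.asarray(g1, dtype=float).ravel()
    g2 = np.asarray(g2, dtype=float).ravel()
    if g1.shape != g2.shape:
        raise ValueError("gradient vectors have different lengths")
    n1 = np.linalg.norm(g1)
    n2 = np.linalg.norm(g2)
    if n1 < _ZERO_NORM or n2 < _ZERO_NORM:
        raise UndefinedAngleError("angle undefined for a zero-norm gradient")
    cosang = np.clip(g1 @ g2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class AngleGrid:
    """Gradient-direction angles over a (w1, w2) weight grid.

    ``angles[i, j]`` is the angle (degrees) at ``w1 = w1_axis[i]``,
    ``w2 = w2_axis[j]``; undefined cells hold :data:`ANGLE_SENTINEL`.
    """

    w1_axis: np.ndarray
    w2_axis: np.ndarray
    angles: np.ndarray
    sigma0: float

    def __post_init__(self) -> None:
        self.w1_axis = np.asarray(self.w1_axis, dtype=float)
        self.w2_axis = np.asarray(self.w2_axis, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.shape != (self.w1_axis.size, self.w2_axis.size):
            raise ValueError("grid dimensions do not match axis lengths")
        finite = self.angles[np.isfinite(self.angles)]
        if finite.size and (finite.min() < 0 or finite.max() > 180):
            raise ValueError("angles must lie in [0, 180] degrees")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.angles, index=pd.Index(self.w1_axis, name="w1"),
                            columns=pd.Index(self.w2_axis, name="w2"))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def _chain_weights(w1: float, w2: float) -> WeightMatrices:
    return WeightMatrices([np.array([[w1]]), np.array([[w2]])])


def _sweep_point(arch, s_in, s_out, w1, w2, sigma0, config):
    """Summed backprop gradient and summed PCN increment (both flattened
    2-vectors) at one weight setting, over all samples at once."""
    weights = _chain_weights(w1, w2)
    fs = ann_forward(weights, arch, s_in)
    g_ann = ann_gradient(fs, ann_deltas(weights, fs, s_out)).flatten()

    params = PCNParams.from_weights(arch, weights.copy(), sigma=[sigma0, 1.0])
    clamps = [s_out, None, s_in]
    init = [None, feedforward_init(params, s_in)[1], None]
    state = pcn_relax(params, clamps, init, config)
    g_pcn = pcn_weight_update(state, params, alpha=1.0).flatten()
    return g_ann, g_pcn


def angle_sweep(
    arch: MLPArchitecture,
    s_in: np.ndarray,
    s_out: np.ndarray,
    w1_axis: np.ndarray,
    w2_axis: np.ndarray,
    sigma0: float,
    config: RelaxationConfig = RelaxationConfig(),
) -> AngleGrid:
    """Angle between summed ANN gradient and summed PCN increment on a
    (w1, w2) grid of the 1-1-1 chain.

    For each grid point and training sample, layers 0 and 2 are clamped to
    the sample, the hidden node relaxes to its fixed point, and the
    per-sample weight increments are summed; the cell records the angle of
    the two summed 2-vectors (or the sentinel if either vanishes, e.g. on
    the zero-gradient ridge).
    """
    if arch.layer_sizes != (1, 1, 1):
        raise ValueError("angle_sweep is defined for the 1-1-1 chain")
    s_in = np.asarray(s_in, dtype=float).reshape(-1, 1)
    s_out = np.asarray(s_out, dtype=float).reshape(-1, 1)
    w1_axis = np.asarray(w1_axis, dtype=float)
    w2_axis = np.asarray(w2_axis, dtype=float)
    angles = np.full((w1_axis.size, w2_axis.size), ANGLE_SENTINEL)
    for i, w1 in enumerate(w1_axis):
        for j, w2 in enumerate(w2_axis):
            try:
                g_ann, g_pcn = _sweep_point(arch, s_in, s_out, w1, w2, sigma0, config)
            except Exception as exc:
                raise RuntimeError(f"sweep failed at grid point (w1={w1}, w2={w2})") from exc
            try:
                angles[i, j] = gradient_angle(g_ann, g_pcn)
            except UndefinedAngleError:
                pass  # sentinel stays
    return AngleGrid(w1_axis=w1_axis, w2_axis=w2_axis, angles=angles, sigma0=float(sigma0))


def equivalence_report(
    params: PCNParams,
    s_in: np.ndarray,
    s_out: np.ndarray,
    sigma0_list,
    config: RelaxationConfig = RelaxationConfig(),
) -> pd.DataFrame:
    """Per-Sigma(0) summary of how closely the PCN tracks the reference ANN.

    Columns (one row per Sigma(0) value):

    * ``max_abs_x_diff`` — prediction mode (input clamped only): largest
      deviation between relaxed node values and the ANN forward pass;
    * ``abs_F`` — |F*| at the prediction-mode fixed point (0 at equality);
    * ``angle_deg`` — learning mode (both ends clamped): angle between the
      summed all-level PCN increment and the summed backprop gradient
      (sentinel NaN when both vanish, e.g. perfectly predicted data).
    """
    arch = params.arch
    s_in = np.atleast_2d(np.asarray(s_in, dtype=float))
    s_out = np.atleast_2d(np.asarray(s_out, dtype=float))
    fs = ann_forward(params.theta, arch, s_in)
    g_ann = ann_gradient(fs, ann_deltas(params.theta, fs, s_out)).flatten()

    rows = []
    for sigma0 in sigma0_list:
        p = params.copy()
        p.sigma[0] = np.full(arch.n(0), float(sigma0))
        # prediction mode
        clamps_p: list = [None] * (arch.l_max + 1)
        clamps_p[arch.l_max] = s_in
        st_p = pcn_relax(p, clamps_p, None, config)
        xdiff = max(float(np.max(np.abs(st_p.x[l] - fs.y[l]))) for l in range(arch.l_max + 1))
        absF = abs(st_p.free_energy(p))
        # learning mode
        clamps_l: list = [None] * (arch.l_max + 1)
        clamps_l[0] = s_out
        clamps_l[arch.l_max] = s_in
        init = [None] + [fs.y[l] for l in range(1, arch.l_max)] + [None]
        st_l = pcn_relax(p, clamps_l, init, config)
        g_pcn = pcn_weight_update(st_l, p, alpha=1.0).flatten()
        try:
            ang = gradient_angle(g_ann, g_pcn)
        except UndefinedAngleError:
            ang = ANGLE_SENTINEL
        rows.append({"sigma0": float(sigma0), "max_abs_x_diff": xdiff,
                     "angle_deg": ang, "abs_F": absF})
    return pd.DataFrame(rows)
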