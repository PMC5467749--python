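"""Seeded dataset generators, the MNIST IDX reader, and fixture networks.

All generators are pure functions of their parameters and a seed: the same
call yields the same bytes.  Datasets are stored column-wise (one row per
sample) and iterate as (s_in, s_out) training pairs.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np

from .ann import MLPArchitecture, WeightMatrices, ann_forward

__all__ = [
    "TrainingPair",
    "Dataset",
    "gen_tanh_chain",
    "gen_sum_diff",
    "gen_synthetic_digits",
    "fixture_network",
    "mnist_read",
    "mnist_preprocess",
    "write_idx",
    "read_idx",
    "IdxFormatError",
    "save_pairs_csv",
    "load_pairs_csv",
    "write_manifest",
]


class TrainingPair(NamedTuple):
    """One supervised example (input vector, desired output vector)."""

    s_in: np.ndarray
    s_out: np.ndarray


@dataclass
class Dataset:
    """A sequence of training pairs stored as two (n, d) arrays."""

    s_in: np.ndarray
    s_out: np.ndarray

    def __post_init__(self) -> None:
        self.s_in = np.atleast_2d(np.asarray(self.s_in, dtype=float))
        self.s_out = np.atleast_2d(np.asarray(self.s_out, dtype=float))
        if len(self.s_in) != len(self.s_out):
            raise ValueError("s_in and s_out have different numbers of samples")
        if not (np.all(np.isfinite(self.s_in)) and np.all(np.isfinite(self.s_out))):
            raise ValueError("training data must be finite")

    def __len__(self) -> int:
        return len(self.s_in)

    def __getitem__(self, i: int) -> TrainingPair:
        return TrainingPair(self.s_in[i], self.s_out[i])

    def __iter__(self) -> Iterator[TrainingPair]:
        for i in range(len(self)):
            yield self[i]

    def subset(self, idx) -> "Dataset":
        return Dataset(self.s_in[idx], self.s_out[idx])


def gen_tanh_chain(n: int = 300, seed: int = 0, W1: float = 1.0, W2: float = 1.0) -> Dataset:
    """Noise-free data from the two-weight tanh chain.

    s_in ~ U[-5, 5] (scalar), s_out = W1 * tanh(W2 * tanh(s_in)).  By
    construction a 1-1-1 tanh network with weights (W1, W2) predicts every
    sample exactly, so its summed objective there is 0.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    s_in = rng.uniform(-5.0, 5.0, size=(n, 1))
    s_out = W1 * np.tanh(W2 * np.tanh(s_in))
    return Dataset(s_in, s_out)


def gen_sum_diff(n: int = 2000, seed: int = 0) -> Dataset:
    """Scalar sum/difference pairs: s_in = a + b, s_out = a - b with
    a ~ N(0, 1) and b ~ N(0, 1/9).

    Population moments: var(s_in) = var(s_out) = 10/9 and
    cov(s_in, s_out) = 8/9, so the forward regression slope is 0.8, the
    first principal axis has slope 1, and inverse regression (in the
    forward frame) has slope 1.25.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n, 1))
    b = rng.normal(0.0, 1.0 / 3.0, size=(n, 1))
    return Dataset(a + b, a - b)


def gen_synthetic_digits(
    n: int = 500,
    seed: int = 0,
    n_classes: int = 10,
    dim: int = 784,
    cluster_std: float = 2.0,
    target_high: float = 0.97,
    target_low: float = 0.03,
) -> Dataset:
    """Synthetic stand-in for a digit-classification set: isotropic
    Gaussian class clusters in ``dim`` dimensions with soft one-hot
    targets (``target_high`` at the true class, ``target_low`` elsewhere).

    This is *not* image data; it emulates only the shape of the
    classification problem (many input features, 10 classes, targets coded
    away from the logistic saturation points).
    """
    from sklearn.datasets import make_blobs

    X, y = make_blobs(n_samples=n, n_features=dim, centers=n_classes,
                      cluster_std=cluster_std, random_state=seed)
    X = (X - X.mean(axis=0)) / (X.std(axis=0) + 1e-12)
    targets = np.full((n, n_classes), target_low)
    targets[np.arange(n), y] = target_high
    return Dataset(X, targets)


def fixture_network(kind: str = "fig1_like") -> tuple[MLPArchitecture, WeightMatrices, TrainingPair]:
    """Deterministic 2-2-2 tanh network with two independent strong
    chains, plus a training pair in which exactly the second output node
    is mispredicted (by +1).  Useful for qualitative checks: error terms
    should be large at the mispredicted node and zero at the other.
    """
    if kind != "fig1_like":
        raise ValueError(f"unknown fixture kind {kind!r}")
    arch = MLPArchitecture(layer_sizes=(2, 2, 2), activation="tanh")
    weights = WeightMatrices([np.diag([2.0, 2.0]), np.diag([2.0, 2.0])])
    s_in = np.array([1.0, 1.0])
    y0 = ann_forward(weights, arch, s_in).y[0]
    s_out = y0 + np.array([0.0, 1.0])  # node 2 mispredicted, node 1 exact
    return arch, weights, TrainingPair(s_in=s_in, s_out=s_out)


# ---------------------------------------------------------------------------
# MNIST IDX format


class IdxFormatError(ValueError):
    """Malformed IDX file (bad magic number, dimensions, or truncation)."""


_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
               0x0D: ">f4", 0x0E: ">f8"}


def read_idx(path) -> np.ndarray:
    """Read one IDX-format array (the MNIST container format): a 4-byte
    magic number (0, 0, dtype code, rank), then rank big-endian uint32
    dimensions, then the raw array data."""
    raw = Path(path).read_bytes()
    if len(raw) < 4:
        raise IdxFormatError(f"{path}: too short for an IDX header")
    zero1, zero2, code, rank = struct.unpack(">BBBB", raw[:4])
    if zero1 != 0 or zero2 != 0 or code not in _IDX_DTYPES:
        raise IdxFormatError(f"{path}: bad IDX magic number {raw[:4]!r}")
    header_end = 4 + 4 * rank
    if len(raw) < header_end:
        raise IdxFormatError(f"{path}: truncated dimension header")
    dims = struct.unpack(f">{rank}I", raw[4:header_end])
    dtype = np.dtype(_IDX_DTYPES[code])
    expected = int(np.prod(dims)) * dtype.itemsize
    body = raw[header_end:]
    if len(body) != expected:
        raise IdxFormatError(
            f"{path}: expected {expected} data bytes for dims {dims}, found {len(body)}")
    return np.frombuffer(body, dtype=dtype).reshape(dims)


def write_idx(path, array: np.ndarray) -> None:
    """Write an array in IDX format (inverse of :func:`read_idx`)."""
    array = np.asarray(array)
    codes = {np.dtype(np.uint8): 0x08, np.dtype(np.int8): 0x09,
             np.dtype(">i2"): 0x0B, np.dtype(">i4"): 0x0C,
             np.dtype(">f4"): 0x0D, np.dtype(">f8"): 0x0E}
    code = codes.get(array.dtype)
    if code is None:
        raise ValueError(f"dtype {array.dtype} has no IDX code; convert first")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, code, array.ndim))
        fh.write(struct.pack(f">{array.ndim}I", *array.shape))
        fh.write(array.tobytes())


def mnist_read(images_path, labels_path) -> list[tuple[np.ndarray, int]]:
    """Read an MNIST-style image/label file pair into a list of
    (flattened unit-interval pixel vector, class label) tuples.

    The reader accepts local paths only; it never downloads anything.
    """
    images = read_idx(images_path)
    labels = read_idx(labels_path)
    if images.ndim != 3:
        raise IdxFormatError(f"{images_path}: expected rank-3 image data, got rank {images.ndim}")
    if labels.ndim != 1:
        raise IdxFormatError(f"{labels_path}: expected rank-1 label data, got rank {labels.ndim}")
    if len(images) != len(labels):
        raise IdxFormatError(
            f"image count {len(images)} does not match label count {len(labels)}")
    flat = images.reshape(len(images), -1).astype(float) / 255.0
    return [(flat[i], int(labels[i])) for i in range(len(images))]


def mnist_preprocess(
    pixels: np.ndarray,
    label: int,
    n_classes: int = 10,
    gamma: float = 0.05,
    target_high: float = 0.97,
    target_low: float = 0.03,
) -> TrainingPair:
    """Map unit-interval pixels through the inverse logistic (logit) after
    clipping into [gamma, 1-gamma], and code the label as a soft one-hot
    target (``target_high`` at the true class, ``target_low`` elsewhere).

    The clipping constant keeps saturated pixels (exactly 0 or 1) finite.
    """
    p = np.clip(np.asarray(pixels, dtype=float), gamma, 1.0 - gamma)
    s_in = np.log(p / (1.0 - p))
    s_out = np.full(n_classes, target_low)
    if not 0 <= label < n_classes:
        raise ValueError(f"label {label} outside 0..{n_classes - 1}")
    s_out[label] = target_high
    return TrainingPair(s_in=s_in, s_out=s_out)


# ---------------------------------------------------------------------------
# Plain-text persistence


def save_pairs_csv(path, dataset: Dataset) -> None:
    """Write a scalar-pair dataset as 2-column CSV (s_in, s_out)."""
    import pandas as pd

    if dataset.s_in.shape[1] != 1 or dataset.s_out.shape[1] != 1:
        raise ValueError("CSV persistence is defined for scalar-pair datasets")
    # repr is the shortest exact round-trip representation of a double
    pd.DataFrame({"s_in": dataset.s_in.ravel(),
                  "s_out": dataset.s_out.ravel()}).to_csv(
        path, index=False, float_format=lambda v: repr(float(v)))


def load_pairs_csv(path) -> Dataset:
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    return Dataset(df["s_in"].to_numpy().reshape(-1, 1),
                   df["s_out"].to_numpy().reshape(-1, 1))


def write_manifest(path, generator: str, n: int, seed: int, **params) -> None:
    """JSON manifest recording how a dataset was generated."""
    Path(path).write_text(json.dumps(
        {"generator": generator, "n": n, "seed": seed, "parameters": params},
        indent=2, sort_keys=True) + "\n")
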