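"""Weight-archive persistence.

A network is stored as a single ``.npz`` archive: one named float64 array
per weight level (``level_1`` .. ``level_{l_max}``), optional per-level
variance vectors (``sigma_0`` ..), and a JSON architecture header.  The
round trip is bit-exact.  The same file can seed both a reference ANN and
its predictive-coding counterpart.
"""

from __future__ import annotations

import json

import numpy as np

from .ann import MLPArchitecture, WeightMatrices
from .pcn import PCNParams

__all__ = ["save_network", "load_network", "load_pcn"]


def save_network(path, arch: MLPArchitecture, weights: WeightMatrices,
                 sigma: list[np.ndarray] | None = None) -> None:
    weights.validate(arch)
    header = {
        "layer_sizes": list(arch.layer_sizes),
        "activation": arch.activation,
        "has_bias": arch.has_bias,
        "has_sigma": sigma is not None,
    }
    arrays = {f"level_{l}": weights[l] for l in range(1, arch.l_max + 1)}
    if sigma is not None:
        if len(sigma) != arch.l_max:
            raise ValueError(f"expected {arch.l_max} sigma vectors")
        arrays.update({f"sigma_{l}": np.asarray(s, dtype=float) for l, s in enumerate(sigma)})
    arrays["header"] = np.frombuffer(json.dumps(header, sort_keys=True).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_network(path) -> tuple[MLPArchitecture, WeightMatrices, list[np.ndarray] | None]:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        arch = MLPArchitecture(layer_sizes=tuple(header["layer_sizes"]),
                               activation=header["activation"],
                               has_bias=header["has_bias"])
        weights = WeightMatrices([z[f"level_{l}"] for l in range(1, arch.l_max + 1)])
        sigma = ([z[f"sigma_{l}"] for l in range(arch.l_max)]
                 if header["has_sigma"] else None)
    weights.validate(arch)
    return arch, weights, sigma


def load_pcn(path, default_sigma: float = 1.0) -> PCNParams:
    """Build predictive-coding parameters from a weight archive (using the
    stored variances, or a uniform default when none were saved)."""
    arch, weights, sigma = load_network(path)
    return PCNParams(arch=arch, theta=weights,
                     sigma=sigma if sigma is not None else default_sigma)
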