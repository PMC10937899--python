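"""Weight initialization (Xavier/Glorot scheme)."""

from __future__ import annotations

import numpy as np


def _fans(shape: tuple[int, ...]) -> tuple[int, int]:
    if len(shape) == 2:  # linear (out, in)
        return shape[1], shape[0]
    if len(shape) == 4:  # conv (out, in, kh, kw)
        rf = shape[2] * shape[3]
        return shape[1] * rf, shape[0] * rf
    raise ValueError(f"unsupported weight shape {shape}")


def xavier_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """U(-a, a) with a = sqrt(6 / (fan_in + fan_out))."""
    fan_in, fan_out = _fans(shape)
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=shape).astype(np.float32)


def xavier_bound(shape: tuple[int, ...]) -> float:
    fan_in, fan_out = _fans(shape)
    return float(np.sqrt(6.0 / (fan_in + fan_out)))
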