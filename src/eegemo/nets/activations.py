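"""Elementwise nonlinearities and their derivatives.

Two rectifier variants are provided because the literature this pipeline
follows labels the softplus formula ln(1 + e^x) "ReLU": the default is the
standard rectifier max(0, x), with softplus selectable everywhere an
activation kind is configurable.
"""

from __future__ import annotations

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softplus(x: np.ndarray) -> np.ndarray:
    """ln(1 + e^x), computed stably for large |x|."""
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = np.asarray(x, dtype=float)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def activation(x: np.ndarray, kind: str) -> np.ndarray:
    """Dispatch by name; ``kind`` in {relu, softplus, sigmoid, softmax, linear}."""
    try:
        return _FORWARD[kind](x)
    except KeyError:
        raise ValueError(f"unknown activation {kind!r}") from None


def activation_grad(kind: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    """d activation / d preactivation, elementwise, given both z and a = f(z).

    Softmax is excluded: its Jacobian is not elementwise and is always fused
    with categorical crossentropy at the output layer.
    """
    if kind == "relu":
        return (z > 0).astype(z.dtype)
    if kind == "softplus":
        return sigmoid(z)
    if kind == "sigmoid":
        return a * (1.0 - a)
    if kind == "linear":
        return np.ones_like(z)
    raise ValueError(f"no elementwise gradient for activation {kind!r}")


_FORWARD = {
    "relu": relu,
    "softplus": softplus,
    "sigmoid": sigmoid,
    "softmax": softmax,
    "linear": lambda x: np.asarray(x, dtype=float),
}
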