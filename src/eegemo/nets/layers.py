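"""Network layers with forward and analytic backward passes.

All layers operate on float arrays whose leading axis is the batch.  Image
inputs are (batch, channels, H, W).  Convolution kernels are one-dimensional
(klen x 1), slid vertically over the image height so each electrode row
mixes only with its neighbours — this preserves the spatial ordering of the
electrode axis, which is the point of using 1-D rather than 2-D filters on
connectivity images.  Convolution is "valid" (no padding), stride 1, and a
kernel spans all input channels.  Max pooling uses stride equal to the pool
size and truncates partial blocks.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .activations import activation as _act, activation_grad as _act_grad


def fan_in_uniform(
    rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int, dtype=np.float64
) -> np.ndarray:
    """Uniform init with fan-in scaling, limit sqrt(6 / fan_in).

    Fan-in-only scaling keeps activation variance roughly constant through
    stacked rectifier layers (fan-average scaling lets activations decay
    with depth, which starves downstream stages); the seed travels with
    ``rng``.
    """
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    trainable = False

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, in_shape: Tuple[int, ...]) -> Tuple[int, ...]:
        """Shape of one sample's output given one sample's input shape."""
        return in_shape


class Conv1DVertical(Layer):
    """k vertical 1-D kernels over all input channels: (N,C,H,W) -> (N,K,H-klen+1,W)."""

    trainable = True

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        klen: int = 3,
        activation: str = "relu",
        rng: Optional[np.random.Generator] = None,
        dtype=np.float64,
        compute_input_grad: bool = True,
    ) -> None:
        if klen < 1:
            raise ValueError("kernel length must be >= 1")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.klen = klen
        self.activation = activation
        # the first layer of a network never needs d(loss)/d(input)
        self.compute_input_grad = compute_input_grad
        fan_in = in_channels * klen
        self.params: Dict[str, np.ndarray] = {
            # stored as (K, C*klen) so forward/backward are single matmuls
            "W": fan_in_uniform(rng, (out_channels, fan_in), fan_in, dtype),
            "b": np.zeros(out_channels, dtype=dtype),
        }
        self.grads: Dict[str, np.ndarray] = {}

    @property
    def kernels(self) -> np.ndarray:
        """Kernels viewed as (out_channels, in_channels, klen)."""
        return self.params["W"].reshape(self.out_channels, self.in_channels, self.klen)

    def output_shape(self, in_shape):
        c, h, w = in_shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        if self.klen > h:
            raise ValueError(f"kernel length {self.klen} exceeds input height {h}")
        return (self.out_channels, h - self.klen + 1, w)

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        _, h_out, _ = self.output_shape((c, h, w))
        # patches: (N, C, H', W, klen) -> rows (N*H'*W, C*klen)
        windows = sliding_window_view(x, self.klen, axis=2)
        patches = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4)).reshape(
            n * h_out * w, c * self.klen
        )
        z = patches @ self.params["W"].T + self.params["b"]
        self._cache = (patches, z, (n, c, h, w, h_out))
        a = _act(z, self.activation)
        return np.ascontiguousarray(
            a.reshape(n, h_out, w, self.out_channels).transpose(0, 3, 1, 2)
        )

    def backward(self, d_out):
        patches, z, (n, c, h, w, h_out) = self._cache
        d_a = d_out.transpose(0, 2, 3, 1).reshape(n * h_out * w, self.out_channels)
        d_z = d_a * _act_grad(self.activation, z, _act(z, self.activation))
        self.grads = {"W": d_z.T @ patches, "b": d_z.sum(axis=0)}
        if not self.compute_input_grad:
            return None
        d_patches = (d_z @ self.params["W"]).reshape(n, h_out, w, c, self.klen)
        d_x = np.zeros((n, c, h, w), dtype=d_out.dtype)
        for i in range(self.klen):
            d_x[:, :, i : i + h_out, :] += d_patches[..., i].transpose(0, 3, 1, 2)
        return d_x


class MaxPool2D(Layer):
    """Square max pooling, stride = pool size, partial blocks truncated."""

    def __init__(self, size: int = 3) -> None:
        self.size = size

    def output_shape(self, in_shape):
        c, h, w = in_shape
        if h < self.size or w < self.size:
            raise ValueError(f"input {h}x{w} smaller than pool {self.size}x{self.size}")
        return (c, h // self.size, w // self.size)

    def forward(self, x, train=False, rng=None):
        s = self.size
        n, c, h, w = x.shape
        _, h2, w2 = self.output_shape((c, h, w))
        blocks = x[:, :, : h2 * s, : w2 * s].reshape(n, c, h2, s, w2, s)
        flat = np.ascontiguousarray(blocks.transpose(0, 1, 2, 4, 3, 5)).reshape(
            n, c, h2, w2, s * s
        )
        idx = flat.argmax(axis=-1)  # first max wins on ties
        self._cache = (idx, (n, c, h, w, h2, w2))
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, d_out):
        idx, (n, c, h, w, h2, w2) = self._cache
        s = self.size
        d_flat = np.zeros((n, c, h2, w2, s * s), dtype=d_out.dtype)
        np.put_along_axis(d_flat, idx[..., None], d_out[..., None], axis=-1)
        d_blocks = d_flat.reshape(n, c, h2, w2, s, s).transpose(0, 1, 2, 4, 3, 5)
        d_x = np.zeros((n, c, h, w), dtype=d_out.dtype)
        d_x[:, :, : h2 * s, : w2 * s] = d_blocks.reshape(n, c, h2 * s, w2 * s)
        return d_x


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, d_out):
        return d_out if self._mask is None else d_out * self._mask


class Flatten(Layer):
    def output_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, d_out):
        return d_out.reshape(self._shape)


class Dense(Layer):
    """Affine map plus elementwise activation (softmax allowed only on top).

    ``backward`` expects the gradient w.r.t. the post-activation output;
    ``backward_z`` expects it w.r.t. the preactivation, which is how
    output layers fused with a crossentropy loss are driven.
    """

    trainable = True

    def __init__(
        self,
        in_units: int,
        out_units: int,
        activation: str = "linear",
        rng: Optional[np.random.Generator] = None,
        dtype=np.float64,
    ) -> None:
        rng = rng or np.random.default_rng()
        self.in_units = in_units
        self.out_units = out_units
        self.activation = activation
        self.params: Dict[str, np.ndarray] = {
            "W": fan_in_uniform(rng, (in_units, out_units), in_units, dtype),
            "b": np.zeros(out_units, dtype=dtype),
        }
        self.grads: Dict[str, np.ndarray] = {}

    def output_shape(self, in_shape):
        if in_shape != (self.in_units,):
            raise ValueError(f"expected input shape ({self.in_units},), got {in_shape}")
        return (self.out_units,)

    def forward(self, x, train=False, rng=None):
        z = x @ self.params["W"] + self.params["b"]
        a = _act(z, self.activation)
        self._cache = (x, z, a)
        return a

    def backward_z(self, d_z):
        x, _, _ = self._cache
        self.grads = {"W": x.T @ d_z, "b": d_z.sum(axis=0)}
        return d_z @ self.params["W"].T

    def backward(self, d_out):
        if self.activation == "softmax":
            raise ValueError("softmax layers must be driven through backward_z")
        _, z, a = self._cache
        return self.backward_z(d_out * _act_grad(self.activation, z, a))
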