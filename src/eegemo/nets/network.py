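"""A minimal sequential container with loss-fused output gradients."""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .layers import Dense, Layer
from .losses import EPS, binary_crossentropy, categorical_crossentropy


class Network:
    """Sequential stack of layers with an optional fused output loss.

    ``loss`` is ``"binary_ce"`` (sigmoid output units, one-hot or binary
    targets) or ``"categorical_ce"`` (softmax output).  For both, the
    gradient of the mean loss w.r.t. the output preactivation has the
    closed form (p - y) / normaliser, which :meth:`loss_and_delta`
    returns alongside the scalar loss.
    """

    def __init__(self, layers: List[Layer], loss: Optional[str] = None) -> None:
        self.layers = layers
        self.loss = loss

    # ------------------------------------------------------------------ shape
    def output_shape(self, in_shape: Tuple[int, ...]) -> Tuple[int, ...]:
        shape = in_shape
        for layer in self.layers:
            shape = layer.output_shape(shape)
        return shape

    # ---------------------------------------------------------------- forward
    def forward(
        self, x: np.ndarray, train: bool = False, rng: Optional[np.random.Generator] = None
    ) -> np.ndarray:
        self._outputs = []
        out = x
        for layer in self.layers:
            out = layer.forward(out, train=train, rng=rng)
            self._outputs.append(out)
        return out

    def layer_output(self, idx: int) -> np.ndarray:
        """Cached output of layer ``idx`` from the most recent forward pass."""
        return self._outputs[idx]

    # ------------------------------------------------------------------- loss
    def loss_and_delta(self, y: np.ndarray, out: np.ndarray) -> Tuple[float, np.ndarray]:
        y = np.asarray(y, dtype=float)
        if self.loss == "binary_ce":
            value = binary_crossentropy(y, out)
            # mean over all elements; d/dz through the sigmoid is (p - y)/size
            delta = (out - y) / y.size
        elif self.loss == "categorical_ce":
            value = categorical_crossentropy(y, out)
            delta = (out - y) / y.shape[0]
        else:
            raise ValueError(f"network has no fused loss (loss={self.loss!r})")
        return value, delta.astype(out.dtype)

    # --------------------------------------------------------------- backward
    def backward(
        self, delta_z: np.ndarray, extra: Optional[Dict[int, np.ndarray]] = None
    ) -> np.ndarray:
        """Backpropagate from the output layer's preactivation gradient.

        ``extra`` maps a layer index to an additional gradient w.r.t. that
        layer's *output* (used to inject the sparsity-penalty gradient at
        an autoencoder's hidden layer).
        """
        extra = extra or {}
        n = len(self.layers)
        top = self.layers[-1]
        d = top.backward_z(delta_z) if isinstance(top, Dense) else top.backward(delta_z)
        for i in reversed(range(n - 1)):
            if i in extra:
                d = d + extra[i]
            d = self.layers[i].backward(d)
        return d

    # ----------------------------------------------------------------- params
    def param_items(self) -> Iterator[Tuple[int, str, np.ndarray]]:
        for i, layer in enumerate(self.layers):
            if layer.trainable:
                for name, arr in layer.params.items():
                    yield i, name, arr

    def grad_items(self) -> Iterator[Tuple[int, str, np.ndarray]]:
        for i, layer in enumerate(self.layers):
            if layer.trainable:
                for name in layer.params:
                    yield i, name, layer.grads[name]

    @property
    def n_parameters(self) -> int:
        return sum(arr.size for _, _, arr in self.param_items())

    def get_flat_params(self) -> np.ndarray:
        return np.concatenate([arr.ravel() for _, _, arr in self.param_items()])

    def set_flat_params(self, flat: np.ndarray) -> None:
        pos = 0
        for _, _, arr in self.param_items():
            arr[...] = flat[pos : pos + arr.size].reshape(arr.shape)
            pos += arr.size
        if pos != flat.size:
            raise ValueError("flat parameter vector has the wrong length")

    def get_flat_grads(self) -> np.ndarray:
        return np.concatenate([g.ravel() for _, _, g in self.grad_items()])
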