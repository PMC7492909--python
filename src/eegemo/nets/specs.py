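"""Declarative layer-size specifications for the three network cores."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple


@dataclass(frozen=True)
class ConvSpec:
    """Two 1-D-kernel convolutional layers plus one max pool.

    The larger preset (kernels 32 and 64) fits the 32-channel montage; the
    smaller (8 and 16) fits the 62-channel montage whose corpus has fewer
    samples.  Kernels are (klen x 1), slid over the image height, and must
    be shorter than the input height.
    """

    kernels: Tuple[int, int] = (32, 64)
    klen: int = 3
    pool: int = 3
    dropout: float = 0.25
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.klen < 1 or self.pool < 1:
            raise ValueError("kernel and pool sizes must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.activation not in ("relu", "softplus"):
            raise ValueError("activation must be 'relu' or 'softplus'")


@dataclass(frozen=True)
class SAESpec:
    """Sparse autoencoder sizes and sparsity penalty.

    ``rho`` is the target mean activation of the hidden layer and ``beta``
    the penalty weight; ``beta = 0`` gives a plain autoencoder.  The
    reconstruction layer is sigmoid so binary crossentropy on [0, 1]-scaled
    inputs is well defined.
    """

    encode_units: int = 512
    hidden_units: int = 128
    decode_units: int = 512
    rho: float = 0.05
    beta: float = 3.0
    activation: str = "relu"

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must be in (0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class DNNSpec:
    """Fully connected classifier head.

    A 2-unit sigmoid output with one-hot targets encodes the binary task
    (matching the configured layer sizes); a 1-unit sigmoid alternative is
    accepted.  Three-class heads use softmax.
    """

    layer_units: Tuple[int, ...] = (512, 256, 2)
    activation: str = "relu"

    def __post_init__(self) -> None:
        if len(self.layer_units) < 2:
            raise ValueError("need at least one hidden and one output layer")
        if self.n_out not in (1, 2, 3):
            raise ValueError("output layer must have 1, 2, or 3 units")

    @property
    def n_out(self) -> int:
        return self.layer_units[-1]

    @property
    def output_activation(self) -> str:
        return "softmax" if self.n_out == 3 else "sigmoid"

    @property
    def loss_kind(self) -> str:
        return "categorical_ce" if self.n_out == 3 else "binary_ce"


@dataclass(frozen=True)
class LossSpec:
    """Loss kind plus the learning rate of the gradient updates."""

    kind: str = "binary_ce"
    lr: float = 0.01

    def __post_init__(self) -> None:
        if self.kind not in ("binary_ce", "categorical_ce"):
            raise ValueError("kind must be 'binary_ce' or 'categorical_ce'")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
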