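"""The three-stage training protocol and the end-to-end baseline.

Stage 1 trains the convolutional extractor with a temporary fully connected
output layer on *all* samples, then discards the head.  Stage 2 trains the
sparse autoencoder, unsupervised, on the flattened and [0, 1]-scaled pooled
features.  Stage 3 splits the autoencoder's exported representation 80/20
and trains the fully connected classifier, tracking test accuracy every
epoch; the reported metric is the mean test accuracy of the last 10 epochs.

The protocol deliberately reproduces a leakage-prone choice of the method
it implements: in ``paper`` mode the extractor and autoencoder see every
sample (including those later assigned to the test split) during their
unsupervised/representation training.  ``strict`` mode splits first and
fits all three stages on the training portion only; reports label the mode.

The baseline is a single CNN with the same convolutional and dense sizes,
trained end-to-end on the same 80/20 split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features import FeatureTensor
from .nets.layers import Conv1DVertical, Dense, Dropout, Flatten, MaxPool2D
from .nets.losses import EPS, kl_bernoulli, sparse_cost
from .nets.network import Network
from .nets.optim import Adadelta, Adam, Optimizer
from .nets.specs import ConvSpec, DNNSpec, SAESpec


@dataclass(frozen=True)
class StageConfig:
    """Epochs, batch sizes, learning rates and split policy per stage."""

    cnn_epochs: int = 50
    cnn_batch: int = 128
    cnn_lr: float = 0.01
    sae_epochs: int = 100
    sae_batch: int = 64
    sae_lr: float = 0.01
    dnn_epochs: int = 100
    dnn_batch: int = 128
    dnn_lr: float = 0.01
    baseline_epochs: int = 100
    baseline_batch: int = 128
    baseline_lr: float = 0.01
    split_fraction: float = 0.8
    mode: str = "paper"  # or "strict"
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        for name in ("cnn_epochs", "sae_epochs", "dnn_epochs", "baseline_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mode not in ("paper", "strict"):
            raise ValueError("mode must be 'paper' or 'strict'")

    def replace(self, **kw) -> "StageConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TrainResult:
    """Histories and final metrics of one trained model."""

    model: str
    histories: Dict[str, Dict[str, List[float]]]
    final_accuracy: float
    convergence_epoch: int
    n_train: int
    n_test: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seeds: Dict[str, int]
    config: StageConfig
    mode: str = "paper"

    @property
    def accuracy_history(self) -> List[float]:
        key = "dnn" if "dnn" in self.histories else "baseline"
        return self.histories[key]["test_accuracy"]


# ---------------------------------------------------------------------------
# metric helpers


def last10_mean(history: Sequence[float]) -> float:
    """Mean of the final 10 per-epoch accuracies; errors on shorter input."""
    if len(history) < 10:
        raise ValueError(f"need >= 10 epochs, got {len(history)}")
    return float(np.mean(np.asarray(history, dtype=float)[-10:]))


def convergence_epoch(history: Sequence[float], frac: float = 0.95) -> int:
    """First epoch (1-based) whose accuracy reaches ``frac`` of the plateau.

    The plateau is operationalised as the last-10-epoch mean.
    """
    plateau = last10_mean(history)
    hits = np.nonzero(np.asarray(history, dtype=float) >= frac * plateau)[0]
    return int(hits[0]) + 1


def one_hot(labels: np.ndarray, n_out: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if n_out == 1:
        return labels.reshape(-1, 1).astype(float)
    out = np.zeros((labels.size, n_out))
    out[np.arange(labels.size), labels] = 1.0
    return out


def predict_classes(probs: np.ndarray, n_out: int) -> np.ndarray:
    if n_out == 1:
        return (probs[:, 0] >= 0.5).astype(int)
    return probs.argmax(axis=1)


def accuracy(labels: np.ndarray, probs: np.ndarray, n_out: int) -> float:
    return float(np.mean(predict_classes(probs, n_out) == np.asarray(labels, dtype=int)))


def train_test_split_indices(
    labels: np.ndarray, split_fraction: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Fully random split; errors if any class is absent from the train set."""
    n = len(labels)
    perm = rng.permutation(n)
    n_train = int(round(split_fraction * n))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    if len(test_idx) == 0:
        raise ValueError("split leaves no test samples")
    missing = set(np.unique(labels)) - set(np.unique(labels[train_idx]))
    if missing:
        raise ValueError(f"split leaves classes {sorted(missing)} absent from the train set")
    return train_idx, test_idx


# ---------------------------------------------------------------------------
# network builders


def build_extractor(
    in_shape: Tuple[int, int, int],
    conv_spec: ConvSpec,
    rng: np.random.Generator,
    dtype=np.float32,
) -> Network:
    """Conv -> dropout -> conv -> dropout -> max-pool feature extractor."""
    bands, h, w = in_shape
    k1, k2 = conv_spec.kernels
    layers = [
        Conv1DVertical(
            bands, k1, conv_spec.klen, conv_spec.activation, rng, dtype,
            compute_input_grad=False,
        ),
        Dropout(conv_spec.dropout),
        Conv1DVertical(k1, k2, conv_spec.klen, conv_spec.activation, rng, dtype),
        Dropout(conv_spec.dropout),
        MaxPool2D(conv_spec.pool),
    ]
    net = Network(layers)
    net.output_shape(in_shape)  # validates kernel/pool fit
    return net


def extractor_flat_dim(in_shape: Tuple[int, int, int], conv_spec: ConvSpec) -> int:
    """Flattened size of the pooled feature maps for one sample."""
    bands, h, w = in_shape
    h_out = h - 2 * (conv_spec.klen - 1)  # two valid convolutions
    return conv_spec.kernels[1] * (h_out // conv_spec.pool) * (w // conv_spec.pool)


def _head_loss(n_out: int) -> str:
    return "categorical_ce" if n_out == 3 else "binary_ce"


def build_cnn_with_head(
    in_shape: Tuple[int, int, int],
    conv_spec: ConvSpec,
    n_out: int,
    rng: np.random.Generator,
    dtype=np.float32,
) -> Network:
    """The stage-1 network: extractor plus one temporary output layer."""
    ext = build_extractor(in_shape, conv_spec, rng, dtype)
    flat = int(np.prod(ext.output_shape(in_shape)))
    out_act = "softmax" if n_out == 3 else "sigmoid"
    layers = ext.layers + [Flatten(), Dense(flat, n_out, out_act, rng, dtype)]
    return Network(layers, loss=_head_loss(n_out))


def build_sae(input_dim: int, spec: SAESpec, rng: np.random.Generator, dtype=np.float32) -> Network:
    """Encoder 512 -> hidden 128 -> decode 512 (exported) -> sigmoid reconstruction."""
    act = spec.activation
    layers = [
        Dense(input_dim, spec.encode_units, act, rng, dtype),
        Dense(spec.encode_units, spec.hidden_units, act, rng, dtype),
        Dense(spec.hidden_units, spec.decode_units, act, rng, dtype),
        Dense(spec.decode_units, input_dim, "sigmoid", rng, dtype),
    ]
    return Network(layers, loss="binary_ce")


SAE_HIDDEN_LAYER = 1  # index of the 128-unit layer carrying the sparsity penalty
SAE_EXPORT_LAYER = 2  # index of the 512-unit decode layer exported to the DNN


def sae_encode(sae: Network, x: np.ndarray) -> np.ndarray:
    """Hidden representation: two affine+rectifier maps, input -> 512 -> 128."""
    out = x
    for layer in sae.layers[: SAE_HIDDEN_LAYER + 1]:
        out = layer.forward(out, train=False)
    return out


def sae_decode(sae: Network, h: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """From hidden units back out: the 512-unit exported features (rectifier)
    and the sigmoid reconstruction with the input's dimensionality."""
    export = sae.layers[SAE_EXPORT_LAYER].forward(h, train=False)
    recon = sae.layers[SAE_EXPORT_LAYER + 1].forward(export, train=False)
    return export, recon


def build_dnn(in_dim: int, spec: DNNSpec, rng: np.random.Generator, dtype=np.float32) -> Network:
    layers: List = []
    prev = in_dim
    for units in spec.layer_units[:-1]:
        layers.append(Dense(prev, units, spec.activation, rng, dtype))
        prev = units
    layers.append(Dense(prev, spec.n_out, spec.output_activation, rng, dtype))
    return Network(layers, loss=spec.loss_kind)


def build_baseline_cnn(
    in_shape: Tuple[int, int, int],
    conv_spec: ConvSpec,
    dnn_spec: DNNSpec,
    rng: np.random.Generator,
    dtype=np.float32,
) -> Network:
    """End-to-end CNN mirroring the composite's layer sizes."""
    ext = build_extractor(in_shape, conv_spec, rng, dtype)
    flat = int(np.prod(ext.output_shape(in_shape)))
    layers = ext.layers + [Flatten()]
    prev = flat
    for units in dnn_spec.layer_units[:-1]:
        layers.append(Dense(prev, units, dnn_spec.activation, rng, dtype))
        prev = units
    layers.append(Dense(prev, dnn_spec.n_out, dnn_spec.output_activation, rng, dtype))
    return Network(layers, loss=dnn_spec.loss_kind)


def make_optimizer(n_out: int, lr: float) -> Optimizer:
    """Adadelta for the binary task, Adam for the 3-class task."""
    return Adam(lr=lr) if n_out == 3 else Adadelta(lr=lr)


# ---------------------------------------------------------------------------
# generic supervised loop


def _minibatches(n: int, batch: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch):
        yield order[start : start + batch]


def _evaluate(net: Network, x: np.ndarray, y: np.ndarray, labels: np.ndarray, n_out: int):
    out = net.forward(x, train=False)
    loss, _ = net.loss_and_delta(y, out)
    return loss, accuracy(labels, out, n_out)


def _train_supervised(
    net: Network,
    x: np.ndarray,
    labels: np.ndarray,
    n_out: int,
    epochs: int,
    batch: int,
    optimizer: Optimizer,
    rng: np.random.Generator,
    eval_data: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> Dict[str, List[float]]:
    y = one_hot(labels, n_out)
    hist: Dict[str, List[float]] = {"loss": [], "accuracy": []}
    if eval_data is not None:
        hist["test_loss"] = []
        hist["test_accuracy"] = []
        y_eval = one_hot(eval_data[1], n_out)
    for _ in range(epochs):
        losses = []
        n_correct = 0
        for idx in _minibatches(len(labels), batch, rng):
            out = net.forward(x[idx], train=True, rng=rng)
            loss, delta = net.loss_and_delta(y[idx], out)
            net.backward(delta)
            optimizer.step(net)
            losses.append(loss)
            # running train accuracy from the same forward passes (dropout
            # active), avoiding an extra full-set evaluation per epoch
            n_correct += int(np.sum(predict_classes(out, n_out) == labels[idx]))
        hist["loss"].append(float(np.mean(losses)))
        hist["accuracy"].append(n_correct / len(labels))
        if eval_data is not None:
            test_loss, test_acc = _evaluate(net, eval_data[0], y_eval, eval_data[1], n_out)
            hist["test_loss"].append(test_loss)
            hist["test_accuracy"].append(test_acc)
        if not np.isfinite(hist["loss"][-1]):
            raise FloatingPointError(
                f"non-finite training loss at epoch {len(hist['loss'])}: {hist['loss'][-1]}"
            )
    return hist


# ---------------------------------------------------------------------------
# stages


def train_cnn_stage(
    x: np.ndarray,
    labels: np.ndarray,
    config: StageConfig,
    conv_spec: ConvSpec,
    n_out: int,
    seed: int,
) -> Tuple[Network, Dict[str, List[float]]]:
    """Stage 1: fit the extractor with a temporary head, then drop the head.

    The returned network ends at the max-pooling layer; the classification
    layer used during this stage is discarded.
    """
    dtype = np.dtype(config.dtype).type
    rng = np.random.default_rng(seed)
    x = np.ascontiguousarray(x, dtype=dtype)
    net = build_cnn_with_head(x.shape[1:], conv_spec, n_out, rng, dtype)
    optimizer = make_optimizer(n_out, config.cnn_lr)
    hist = _train_supervised(
        net, x, labels, n_out, config.cnn_epochs, config.cnn_batch, optimizer, rng
    )
    extractor = Network(net.layers[:-2])  # abandon Flatten + temporary head
    return extractor, hist


def extract_pooled(
    extractor: Network,
    x: np.ndarray,
    batch: int = 256,
    scale: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Forward samples through the extractor, flatten, min-max scale to [0, 1].

    ``scale`` may carry precomputed (min, max) constants (e.g. from the
    training split under strict mode); out-of-range values are clipped.
    """
    chunks = []
    for start in range(0, len(x), batch):
        out = extractor.forward(np.asarray(x[start : start + batch]), train=False)
        chunks.append(out.reshape(out.shape[0], -1))
    flat = np.concatenate(chunks, axis=0)
    if scale is None:
        lo, hi = float(flat.min()), float(flat.max())
    else:
        lo, hi = scale
    span = hi - lo if hi > lo else 1.0
    return np.clip((flat - lo) / span, 0.0, 1.0), (lo, lo + span)


def train_sae_stage(
    flat: np.ndarray,
    config: StageConfig,
    sae_spec: SAESpec,
    seed: int,
) -> Tuple[Network, np.ndarray, Dict[str, List[float]]]:
    """Stage 2: unsupervised sparse-autoencoder training on pooled features.

    Minimises binary crossentropy reconstruction plus
    ``beta * sum_j KL(rho || rho_hat_j)`` over the 128-unit hidden layer,
    where rho_hat is the per-unit batch-mean activation (clipped into the
    KL domain; clipped units receive no penalty gradient).  Returns the
    trained network, the 512-dimensional exported representation of every
    sample, and loss histories.
    """
    if flat.min() < 0.0 or flat.max() > 1.0:
        raise ValueError("SAE input must be scaled to [0, 1]")
    dtype = np.dtype(config.dtype).type
    rng = np.random.default_rng(seed)
    flat = np.ascontiguousarray(flat, dtype=dtype)
    sae = build_sae(flat.shape[1], sae_spec, rng, dtype)
    optimizer = Adadelta(lr=config.sae_lr)
    rho, beta = sae_spec.rho, sae_spec.beta
    hist: Dict[str, List[float]] = {"loss": [], "recon_loss": [], "mean_hidden_activation": []}
    for _ in range(config.sae_epochs):
        totals, recons, hacts = [], [], []
        for idx in _minibatches(len(flat), config.sae_batch, rng):
            xb = flat[idx]
            out = sae.forward(xb, train=True, rng=rng)
            recon_loss, delta = sae.loss_and_delta(xb, out)
            hidden = sae.layer_output(SAE_HIDDEN_LAYER)
            rho_hat_raw = hidden.mean(axis=0)
            inside = (rho_hat_raw > EPS) & (rho_hat_raw < 1.0 - EPS)
            rho_hat = np.clip(rho_hat_raw, EPS, 1.0 - EPS)
            extra = None
            if beta > 0:
                d_rho = np.where(
                    inside, -rho / rho_hat + (1.0 - rho) / (1.0 - rho_hat), 0.0
                )
                d_hidden = np.broadcast_to(
                    (beta * d_rho / hidden.shape[0]).astype(hidden.dtype), hidden.shape
                )
                extra = {SAE_HIDDEN_LAYER: d_hidden}
            sae.backward(delta, extra=extra)
            optimizer.step(sae)
            totals.append(sparse_cost(recon_loss, rho_hat, rho, beta))
            recons.append(recon_loss)
            hacts.append(float(rho_hat_raw.mean()))
        hist["loss"].append(float(np.mean(totals)))
        hist["recon_loss"].append(float(np.mean(recons)))
        hist["mean_hidden_activation"].append(float(np.mean(hacts)))
        if not np.isfinite(hist["loss"][-1]):
            raise FloatingPointError("non-finite SAE loss; training diverged")
    export = _sae_export(sae, flat)
    return sae, export, hist


def _sae_export(sae: Network, flat: np.ndarray, batch: int = 512) -> np.ndarray:
    chunks = []
    for start in range(0, len(flat), batch):
        sae.forward(flat[start : start + batch], train=False)
        chunks.append(sae.layer_output(SAE_EXPORT_LAYER).copy())
    return np.concatenate(chunks, axis=0)


def train_dnn_stage(
    sae_features: np.ndarray,
    labels: np.ndarray,
    config: StageConfig,
    dnn_spec: DNNSpec,
    seed: int,
    split_seed: int,
    split: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> Tuple[Network, Dict[str, List[float]], Tuple[np.ndarray, np.ndarray]]:
    """Stage 3: 80/20 split and supervised training of the classifier head.

    Only training-split samples enter weight updates; test accuracy is
    evaluated every epoch and the canonical metric is the last-10-epoch
    mean.  A precomputed ``split`` may be passed so the baseline can reuse
    identical indices.
    """
    dtype = np.dtype(config.dtype).type
    rng = np.random.default_rng(seed)
    x = np.ascontiguousarray(sae_features, dtype=dtype)
    labels = np.asarray(labels, dtype=int)
    if split is None:
        split = train_test_split_indices(
            labels, config.split_fraction, np.random.default_rng(split_seed)
        )
    train_idx, test_idx = split
    net = build_dnn(x.shape[1], dnn_spec, rng, dtype)
    optimizer = make_optimizer(dnn_spec.n_out, config.dnn_lr)
    hist = _train_supervised(
        net,
        x[train_idx],
        labels[train_idx],
        dnn_spec.n_out,
        config.dnn_epochs,
        config.dnn_batch,
        optimizer,
        rng,
        eval_data=(x[test_idx], labels[test_idx]),
    )
    return net, hist, (train_idx, test_idx)


def train_baseline_cnn(
    x: np.ndarray,
    labels: np.ndarray,
    config: StageConfig,
    conv_spec: ConvSpec,
    dnn_spec: DNNSpec,
    seed: int,
    split_seed: int,
    split: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> TrainResult:
    """The comparison model: one CNN with the composite's sizes, end-to-end."""
    dtype = np.dtype(config.dtype).type
    rng = np.random.default_rng(seed)
    x = np.ascontiguousarray(x, dtype=dtype)
    labels = np.asarray(labels, dtype=int)
    if split is None:
        split = train_test_split_indices(
            labels, config.split_fraction, np.random.default_rng(split_seed)
        )
    train_idx, test_idx = split
    net = build_baseline_cnn(x.shape[1:], conv_spec, dnn_spec, rng, dtype)
    optimizer = make_optimizer(dnn_spec.n_out, config.baseline_lr)
    hist = _train_supervised(
        net,
        x[train_idx],
        labels[train_idx],
        dnn_spec.n_out,
        config.baseline_epochs,
        config.baseline_batch,
        optimizer,
        rng,
        eval_data=(x[test_idx], labels[test_idx]),
    )
    acc_hist = hist["test_accuracy"]
    return TrainResult(
        model="baseline_cnn",
        histories={"baseline": hist},
        final_accuracy=last10_mean(acc_hist) if len(acc_hist) >= 10 else float(acc_hist[-1]),
        convergence_epoch=convergence_epoch(acc_hist) if len(acc_hist) >= 10 else len(acc_hist),
        n_train=len(train_idx),
        n_test=len(test_idx),
        train_idx=np.asarray(train_idx),
        test_idx=np.asarray(test_idx),
        seeds={"init": seed, "split": split_seed},
        config=config,
        mode=config.mode,
    )


def run_experiment(config, **kw):
    """Comparison protocol across models, features and window settings.

    Thin wrapper over :func:`eegemo.experiments.run_experiment` so the
    training module exposes the full protocol surface.
    """
    from .experiments import run_experiment as _impl

    return _impl(config, **kw)
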