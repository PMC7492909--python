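"""Model/results objects wrapping the staged training protocol.

`StagedEmotionClassifier` is constructed from a feature tensor (or built
straight from a recording) and `fit()` runs the three stages, returning a
`StagedResults` carrying per-stage histories, the canonical last-10-epoch
test accuracy, the convergence epoch, the split bookkeeping and a
`summary()` table.  `BaselineCNNClassifier` offers the same surface for the
end-to-end comparison CNN.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import train as _train
from .features import FeatureTensor, feature_tensor
from .nets.network import Network
from .nets.specs import ConvSpec, DNNSpec, SAESpec
from .preprocess import DEFAULT_BANDS, decompose_bands, segment_windows, trim_lead
from .train import StageConfig, TrainResult, convergence_epoch, last10_mean


def _features_from_recording(rec, window_s, step_s, kind, trim_s=0.0, band_edges=DEFAULT_BANDS):
    if trim_s:
        rec = trim_lead(rec, trim_s)
    stack = decompose_bands(rec, band_edges)
    segments = segment_windows(stack, window_s, step_s)
    return feature_tensor(segments, kind)


@dataclass
class StagedResults:
    """Fit results of the composite CNN-SAE-DNN model."""

    histories: Dict[str, Dict[str, List[float]]]
    final_accuracy: float
    conv_extractor: Network
    sae: Network
    dnn: Network
    train_idx: np.ndarray
    test_idx: np.ndarray
    seeds: Dict[str, int]
    config: StageConfig
    mode: str
    feature_kind: str
    n_parameters: Dict[str, int]

    @property
    def accuracy_history(self) -> List[float]:
        return self.histories["dnn"]["test_accuracy"]

    @property
    def convergence_epoch(self) -> int:
        hist = self.accuracy_history
        if len(hist) >= 10:
            return convergence_epoch(hist)
        # short smoke runs: plateau from whatever epochs exist
        plateau = float(np.mean(hist))
        return int(np.nonzero(np.asarray(hist) >= 0.95 * plateau)[0][0]) + 1

    @property
    def sae_recon_history(self) -> List[float]:
        return self.histories["sae"]["recon_loss"]

    def as_train_result(self) -> TrainResult:
        return TrainResult(
            model="composite",
            histories=self.histories,
            final_accuracy=self.final_accuracy,
            convergence_epoch=self.convergence_epoch,
            n_train=len(self.train_idx),
            n_test=len(self.test_idx),
            train_idx=self.train_idx,
            test_idx=self.test_idx,
            seeds=self.seeds,
            config=self.config,
            mode=self.mode,
        )

    def summary(self) -> str:
        lines = [
            "Staged CNN-SAE-DNN classification results",
            "=" * 45,
            f"feature kind:          {self.feature_kind}",
            f"training mode:         {self.mode}",
            f"train / test samples:  {len(self.train_idx)} / {len(self.test_idx)}",
            f"parameters (cnn/sae/dnn): "
            f"{self.n_parameters['cnn']} / {self.n_parameters['sae']} / {self.n_parameters['dnn']}",
            f"final test accuracy:   {self.final_accuracy:.4f}  (mean of last 10 epochs)",
            f"convergence epoch:     {self.convergence_epoch}  (first >= 95% of plateau)",
            f"SAE reconstruction:    {self.sae_recon_history[0]:.4f} -> {self.sae_recon_history[-1]:.4f}",
            f"seeds:                 {self.seeds}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Per-epoch test accuracy with the last-10-epoch mean marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        acc = self.accuracy_history
        ax.plot(np.arange(1, len(acc) + 1), acc, label="test accuracy")
        ax.axhline(self.final_accuracy, color="red", ls="--", label="last-10 mean")
        ax.set_xlabel("epoch")
        ax.set_ylabel("accuracy")
        ax.legend()
        return ax


class StagedEmotionClassifier:
    """The composite model: conv extractor -> sparse autoencoder -> classifier.

    Parameters
    ----------
    features
        A stacked feature tensor (samples x bands x H x W, scaled to [0, 1]).
    config
        Per-stage epochs/batches/learning rates and the split policy.
    conv_spec, sae_spec, dnn_spec
        Layer-size specifications; defaults match the 32-channel preset.
    """

    def __init__(
        self,
        features: FeatureTensor,
        config: Optional[StageConfig] = None,
        conv_spec: Optional[ConvSpec] = None,
        sae_spec: Optional[SAESpec] = None,
        dnn_spec: Optional[DNNSpec] = None,
    ) -> None:
        self.features = features
        self.config = config or StageConfig()
        self.conv_spec = conv_spec or ConvSpec()
        self.sae_spec = sae_spec or SAESpec()
        n_classes = int(np.max(features.labels)) + 1
        if dnn_spec is None:
            dnn_spec = DNNSpec(layer_units=(512, 256, 3 if n_classes == 3 else 2))
        self.dnn_spec = dnn_spec

    @classmethod
    def from_recording(
        cls,
        rec,
        window_s: float,
        step_s: float,
        kind: str = "pcc",
        trim_s: float = 0.0,
        band_edges=DEFAULT_BANDS,
        **kw,
    ) -> "StagedEmotionClassifier":
        """Preprocess + featurize a recording, then construct the model."""
        return cls(_features_from_recording(rec, window_s, step_s, kind, trim_s, band_edges), **kw)

    def fit(self, seed: int = 0, split_seed: Optional[int] = None) -> StagedResults:
        """Run the three training stages and evaluate on the held-out split."""
        cfg = self.config
        split_seed = seed if split_seed is None else split_seed
        x = self.features.data
        labels = np.asarray(self.features.labels, dtype=int)

        split = _train.train_test_split_indices(
            labels, cfg.split_fraction, np.random.default_rng(split_seed)
        )
        train_idx, test_idx = split
        rep_idx = train_idx if cfg.mode == "strict" else np.arange(len(labels))

        extractor, cnn_hist = _train.train_cnn_stage(
            x[rep_idx], labels[rep_idx], cfg, self.conv_spec, self.dnn_spec.n_out, seed
        )
        if cfg.mode == "strict":
            # scaling constants from the training portion only
            _, scale = _train.extract_pooled(extractor, x[train_idx])
            flat, _ = _train.extract_pooled(extractor, x, scale=scale)
            sae, _, sae_hist = _train.train_sae_stage(
                flat[train_idx], cfg, self.sae_spec, seed + 1
            )
            export = _train._sae_export(sae, flat.astype(np.dtype(cfg.dtype).type))
        else:
            flat, _ = _train.extract_pooled(extractor, x)
            sae, export, sae_hist = _train.train_sae_stage(flat, cfg, self.sae_spec, seed + 1)
        dnn, dnn_hist, split = _train.train_dnn_stage(
            export, labels, cfg, self.dnn_spec, seed + 2, split_seed, split=split
        )
        acc_hist = dnn_hist["test_accuracy"]
        final = last10_mean(acc_hist) if len(acc_hist) >= 10 else float(acc_hist[-1])
        return StagedResults(
            histories={"cnn": cnn_hist, "sae": sae_hist, "dnn": dnn_hist},
            final_accuracy=final,
            conv_extractor=extractor,
            sae=sae,
            dnn=dnn,
            train_idx=np.asarray(train_idx),
            test_idx=np.asarray(test_idx),
            seeds={"init": seed, "split": split_seed},
            config=cfg,
            mode=cfg.mode,
            feature_kind=self.features.kind,
            n_parameters={
                "cnn": extractor.n_parameters,
                "sae": sae.n_parameters,
                "dnn": dnn.n_parameters,
            },
        )


class BaselineCNNClassifier:
    """End-to-end CNN with the composite model's layer sizes."""

    def __init__(
        self,
        features: FeatureTensor,
        config: Optional[StageConfig] = None,
        conv_spec: Optional[ConvSpec] = None,
        dnn_spec: Optional[DNNSpec] = None,
    ) -> None:
        self.features = features
        self.config = config or StageConfig()
        self.conv_spec = conv_spec or ConvSpec()
        n_classes = int(np.max(features.labels)) + 1
        if dnn_spec is None:
            dnn_spec = DNNSpec(layer_units=(512, 256, 3 if n_classes == 3 else 2))
        self.dnn_spec = dnn_spec

    @classmethod
    def from_recording(
        cls,
        rec,
        window_s: float,
        step_s: float,
        kind: str = "pcc",
        trim_s: float = 0.0,
        band_edges=DEFAULT_BANDS,
        **kw,
    ) -> "BaselineCNNClassifier":
        return cls(_features_from_recording(rec, window_s, step_s, kind, trim_s, band_edges), **kw)

    def fit(self, seed: int = 0, split_seed: Optional[int] = None) -> TrainResult:
        split_seed = seed if split_seed is None else split_seed
        return _train.train_baseline_cnn(
            self.features.data,
            self.features.labels,
            self.config,
            self.conv_spec,
            self.dnn_spec,
            seed,
            split_seed,
        )
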