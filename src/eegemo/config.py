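"""Experiment configuration: presets, YAML round-trip, pipeline orchestration.

Presets encode the two study geometries the pipeline targets:

``deap_like``
    32 subjects x 40 trials, 32 channels at 128 Hz, 63-s trials with the
    first 3 s trimmed, binary labels, conv kernels (32, 64), 2-unit head.
``seed_like``
    15 subjects x 15 trials, 62 channels at 200 Hz, 80-s segments, 3-class
    labels, conv kernels (8, 16), 3-unit softmax head.
``deap_like_small``
    The deap_like geometry scaled to 4 subjects x 10 trials with shorter
    stage schedules (20/30/30 epochs) — the desk-scale preset used by the
    benchmark experiments.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from .nets.specs import ConvSpec, DNNSpec, SAESpec
from .preprocess import DEFAULT_BANDS
from .synthetic import SynthSpec
from .train import StageConfig


@dataclass
class ExperimentConfig:
    """Everything one run needs, serialisable to YAML."""

    preset: str = "deap_like_small"
    synth: SynthSpec = field(
        default_factory=lambda: SynthSpec(
            n_subjects=4, n_trials_per_subject=10, n_channels=32, fs=128.0, duration=63.0
        )
    )
    trim_s: float = 3.0
    band_edges: Tuple[Tuple[float, float], ...] = DEFAULT_BANDS
    window_s: float = 8.0
    step_s: float = 4.0
    feature_kind: str = "pcc"
    conv: ConvSpec = field(default_factory=ConvSpec)
    sae: SAESpec = field(default_factory=SAESpec)
    dnn: DNNSpec = field(default_factory=DNNSpec)
    stages: StageConfig = field(default_factory=StageConfig)
    seeds: Dict[str, int] = field(default_factory=lambda: {"data": 0, "split": 0, "init": 0})
    mode: str = "paper"
    out_dir: str = "eegemo_run"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("pcc", "pca", "sc"):
            raise ValueError("feature_kind must be pcc, pca, or sc")
        if self.mode not in ("paper", "strict"):
            raise ValueError("mode must be 'paper' or 'strict'")
        if self.window_s > self.synth.duration - self.trim_s:
            raise ValueError("window longer than trimmed trial")

    # ------------------------------------------------------------- serialise
    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["synth"] = dataclasses.asdict(self.synth)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "ExperimentConfig":
        d = dict(d)
        synth = d.pop("synth")
        synth["band_edges"] = tuple(tuple(b) for b in synth.get("band_edges", DEFAULT_BANDS))
        conv = d.pop("conv", {})
        conv["kernels"] = tuple(conv.get("kernels", (32, 64)))
        dnn = d.pop("dnn", {})
        dnn["layer_units"] = tuple(dnn.get("layer_units", (512, 256, 2)))
        d["band_edges"] = tuple(tuple(b) for b in d.get("band_edges", DEFAULT_BANDS))
        return cls(
            synth=SynthSpec(**synth),
            conv=ConvSpec(**conv),
            sae=SAESpec(**d.pop("sae", {})),
            dnn=DNNSpec(**dnn),
            stages=StageConfig(**d.pop("stages", {})),
            **d,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw)


def _deap_like(**synth_kw) -> ExperimentConfig:
    synth = SynthSpec(
        n_subjects=32,
        n_trials_per_subject=40,
        n_channels=32,
        fs=128.0,
        duration=63.0,
        n_classes=2,
        preset_name="deap_like",
        **synth_kw,
    )
    return ExperimentConfig(
        preset="deap_like",
        synth=synth,
        trim_s=3.0,
        conv=ConvSpec(kernels=(32, 64)),
        dnn=DNNSpec(layer_units=(512, 256, 2)),
        stages=StageConfig(),
    )


def preset(name: str) -> ExperimentConfig:
    """Named experiment configurations; raises on unknown names."""
    if name == "deap_like":
        return _deap_like()
    if name == "deap_like_small":
        cfg = _deap_like()
        return cfg.replace(
            preset="deap_like_small",
            synth=cfg.synth.replace(
                n_subjects=4, n_trials_per_subject=10, preset_name="deap_like_small"
            ),
            stages=StageConfig(
                cnn_epochs=20, sae_epochs=30, dnn_epochs=30, baseline_epochs=30,
                # batch sizes scaled with the study so optimizer steps per
                # epoch stay in the regime the full-scale protocol assumes
                cnn_batch=32, sae_batch=32, dnn_batch=32, baseline_batch=32,
            ),
        )
    if name == "seed_like":
        synth = SynthSpec(
            n_subjects=15,
            n_trials_per_subject=15,
            n_channels=62,
            fs=200.0,
            duration=80.0,
            n_classes=3,
            preset_name="seed_like",
        )
        return ExperimentConfig(
            preset="seed_like",
            synth=synth,
            trim_s=0.0,
            conv=ConvSpec(kernels=(8, 16)),
            dnn=DNNSpec(layer_units=(512, 256, 3)),
            stages=StageConfig(),
        )
    raise ValueError(f"unknown preset {name!r}; known: deap_like, deap_like_small, seed_like")


# ---------------------------------------------------------------------------
# pipeline orchestration

_STAGES = ("simulate", "preprocess", "featurize", "train")


def _manifest_path(out_dir: Path) -> Path:
    return out_dir / "manifest.json"


def _load_manifest(out_dir: Path) -> Dict:
    p = _manifest_path(out_dir)
    if p.exists():
        return json.loads(p.read_text())
    return {"completed": []}


def _mark_done(out_dir: Path, manifest: Dict, stage: str) -> None:
    if stage not in manifest["completed"]:
        manifest["completed"].append(stage)
    _manifest_path(out_dir).write_text(json.dumps(manifest, indent=2))


def run_pipeline(config: ExperimentConfig, force: bool = False, compare: bool = False) -> Dict:
    """Run simulate -> preprocess -> featurize -> train, one artifact each.

    Completed stages recorded in ``manifest.json`` are skipped unless
    ``force`` is set, so an interrupted run resumes from the last finished
    stage.  With ``compare=True`` the training stage fits both the staged
    model and the baseline CNN on identical splits.
    """
    from . import io as _io
    from . import __version__
    from .features import feature_tensor
    from .models import BaselineCNNClassifier, StagedEmotionClassifier
    from .preprocess import decompose_bands, segment_windows, trim_lead
    from .synthetic import generate_recording

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(out)
    if force:
        manifest = {"completed": []}
    config.to_yaml(out / "resolved_config.yaml")
    (out / "version.txt").write_text(f"eegemo {__version__}\n")

    rec_path = out / "recording.h5"
    seg_path = out / "segments.h5"
    feat_path = out / f"features_{config.feature_kind}.h5"
    results: Dict = {"out_dir": str(out)}

    if "simulate" not in manifest["completed"] or not rec_path.exists():
        rec = generate_recording(config.synth.replace(seed=config.seeds["data"]))
        _io.save_recording(rec_path, rec, seed=config.seeds["data"])
        _mark_done(out, manifest, "simulate")
    if "preprocess" not in manifest["completed"] or not seg_path.exists():
        rec = _io.load_recording(rec_path)
        if config.trim_s:
            rec = trim_lead(rec, config.trim_s)
        stack = decompose_bands(rec, config.band_edges)
        segs = segment_windows(stack, config.window_s, config.step_s)
        _io.save_segments(seg_path, segs, csv_index=out / "segments_index.csv")
        _mark_done(out, manifest, "preprocess")
    if "featurize" not in manifest["completed"] or not feat_path.exists():
        segs = _io.load_segments(seg_path)
        ft = feature_tensor(segs, config.feature_kind)
        _io.save_features(feat_path, ft)
        _mark_done(out, manifest, "featurize")
    if "train" not in manifest["completed"]:
        ft = _io.load_features(feat_path)
        model = StagedEmotionClassifier(
            ft, config=config.stages.replace(mode=config.mode),
            conv_spec=config.conv, sae_spec=config.sae, dnn_spec=config.dnn,
        )
        res = model.fit(seed=config.seeds["init"], split_seed=config.seeds["split"])
        _io.metrics_frame("composite", res.histories).to_csv(
            out / "metrics_composite.csv", index=False
        )
        report = {
            "mode": res.mode,
            "composite": {
                "final_accuracy": res.final_accuracy,
                "convergence_epoch": res.convergence_epoch,
                "n_train": len(res.train_idx),
                "n_test": len(res.test_idx),
            },
            "seeds": config.seeds,
        }
        import h5py

        with h5py.File(out / "models.h5", "w") as f:
            _io.save_network(f, res.conv_extractor, "conv_extractor")
            _io.save_network(f, res.sae, "sae")
            _io.save_network(f, res.dnn, "dnn")
        if compare:
            base = BaselineCNNClassifier(
                ft, config=config.stages.replace(mode=config.mode),
                conv_spec=config.conv, dnn_spec=config.dnn,
            ).fit(seed=config.seeds["init"], split_seed=config.seeds["split"])
            _io.metrics_frame("baseline_cnn", base.histories).to_csv(
                out / "metrics_baseline.csv", index=False
            )
            report["baseline_cnn"] = {
                "final_accuracy": base.final_accuracy,
                "convergence_epoch": base.convergence_epoch,
            }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        results["report"] = report
        _mark_done(out, manifest, "train")
    else:
        report_path = out / "report.json"
        if report_path.exists():
            results["report"] = json.loads(report_path.read_text())
    return results
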