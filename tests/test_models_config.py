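"""Model/results API, configuration presets, persistence and the CLI."""

import json

import numpy as np
import pytest
import yaml

from eegemo import (
    BaselineCNNClassifier,
    ExperimentConfig,
    StagedEmotionClassifier,
    preset,
)
from eegemo.config import run_pipeline
from eegemo.nets.specs import ConvSpec, DNNSpec, SAESpec
from eegemo.train import StageConfig
from eegemo import io as eio

SMALL_CONV = ConvSpec(kernels=(4, 8))
SMALL_DNN = DNNSpec(layer_units=(16, 8, 2))
SMALL_SAE = SAESpec(encode_units=32, hidden_units=8, decode_units=32)
FAST = StageConfig(
    cnn_epochs=2, cnn_batch=16, sae_epochs=3, sae_batch=16, dnn_epochs=12, dnn_batch=16,
    baseline_epochs=12, baseline_batch=16,
)


@pytest.fixture(scope="module")
def fitted(tiny_features):
    model = StagedEmotionClassifier(
        tiny_features, config=FAST, conv_spec=SMALL_CONV,
        sae_spec=SMALL_SAE, dnn_spec=SMALL_DNN,
    )
    return model.fit(seed=0)


class TestModels:
    def test_results_carry_histories_and_metric(self, fitted):
        assert set(fitted.histories) == {"cnn", "sae", "dnn"}
        assert 0.0 <= fitted.final_accuracy <= 1.0
        assert len(fitted.accuracy_history) == FAST.dnn_epochs
        assert fitted.convergence_epoch >= 1

    def test_summary_mentions_key_quantities(self, fitted):
        text = fitted.summary()
        assert "final test accuracy" in text
        assert f"{fitted.final_accuracy:.4f}" in text
        assert "pcc" in text

    def test_as_train_result_round_trip(self, fitted):
        tr = fitted.as_train_result()
        assert tr.model == "composite"
        assert tr.final_accuracy == fitted.final_accuracy

    def test_strict_mode_runs_and_is_labeled(self, tiny_features):
        res = StagedEmotionClassifier(
            tiny_features, config=FAST.replace(mode="strict"), conv_spec=SMALL_CONV,
            sae_spec=SMALL_SAE, dnn_spec=SMALL_DNN,
        ).fit(seed=0)
        assert res.mode == "strict"

    def test_baseline_classifier_api(self, tiny_features):
        res = BaselineCNNClassifier(
            tiny_features, config=FAST, conv_spec=SMALL_CONV, dnn_spec=SMALL_DNN
        ).fit(seed=0)
        assert res.model == "baseline_cnn"

    def test_from_recording_constructor(self, tiny_recording):
        model = StagedEmotionClassifier.from_recording(
            tiny_recording, window_s=6.0, step_s=3.0, kind="sc",
            config=FAST, conv_spec=SMALL_CONV, sae_spec=SMALL_SAE, dnn_spec=SMALL_DNN,
        )
        assert model.features.kind == "sc"
        assert model.features.data.shape[0] == 40


class TestPresets:
    def test_deap_like_values(self):
        cfg = preset("deap_like")
        assert cfg.synth.n_subjects == 32
        assert cfg.synth.n_channels == 32
        assert cfg.synth.fs == 128.0
        assert cfg.synth.duration == 63.0
        assert cfg.trim_s == 3.0
        assert cfg.conv.kernels == (32, 64)
        assert cfg.dnn.layer_units == (512, 256, 2)
        assert cfg.stages.cnn_epochs == 50
        assert cfg.stages.sae_epochs == 100
        assert cfg.stages.dnn_epochs == 100

    def test_seed_like_values(self):
        cfg = preset("seed_like")
        assert cfg.synth.n_channels == 62
        assert cfg.synth.fs == 200.0
        assert cfg.synth.duration == 80.0
        assert cfg.synth.n_classes == 3
        assert cfg.conv.kernels == (8, 16)
        assert cfg.dnn.layer_units == (512, 256, 3)
        assert cfg.dnn.output_activation == "softmax"

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset("unknown")

    def test_yaml_round_trip(self, tmp_path):
        cfg = preset("deap_like_small")
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        again = ExperimentConfig.from_yaml(path)
        assert again == cfg


class TestIO:
    def test_recording_round_trip(self, tmp_path, tiny_recording):
        p = tmp_path / "rec.h5"
        eio.save_recording(p, tiny_recording, seed=11)
        back = eio.load_recording(p)
        np.testing.assert_allclose(back.data, tiny_recording.data, atol=1e-6)
        np.testing.assert_array_equal(back.labels, tiny_recording.labels)
        assert back.fs == tiny_recording.fs

    def test_segments_round_trip_with_csv_index(self, tmp_path, tiny_segments):
        p = tmp_path / "segs.h5"
        csv = tmp_path / "segs.csv"
        eio.save_segments(p, tiny_segments, csv_index=csv)
        back = eio.load_segments(p)
        assert back.data.shape == tiny_segments.data.shape
        np.testing.assert_array_equal(back.labels, tiny_segments.labels)
        assert back.window_s == tiny_segments.window_s
        import pandas as pd

        idx = pd.read_csv(csv)
        assert list(idx.columns) == ["subject", "trial", "window_start_s", "label"]
        assert len(idx) == tiny_segments.n_segments

    def test_features_round_trip(self, tmp_path, tiny_features):
        p = tmp_path / "feat.h5"
        eio.save_features(p, tiny_features)
        back = eio.load_features(p)
        np.testing.assert_allclose(back.data, tiny_features.data, atol=1e-6)
        assert back.kind == tiny_features.kind
        assert back.scale_min == tiny_features.scale_min

    def test_network_round_trip_preserves_forward(self, tmp_path, rng):
        from eegemo.train import build_baseline_cnn

        net = build_baseline_cnn((2, 8, 8), SMALL_CONV, SMALL_DNN, rng, np.float64)
        x = rng.standard_normal((3, 2, 8, 8))
        p = tmp_path / "net.h5"
        eio.save_network(p, net)
        back = eio.load_network(p)
        np.testing.assert_allclose(back.forward(x), net.forward(x), atol=1e-12)


def _tiny_pipeline_config(tmp_path, name):
    from eegemo.synthetic import SynthSpec

    return ExperimentConfig(
        preset="custom",
        synth=SynthSpec(
            n_subjects=2, n_trials_per_subject=4, n_channels=8, fs=128.0, duration=20.0,
            n_latent_sources=4, seed=11,
        ),
        trim_s=2.0,
        window_s=6.0,
        step_s=3.0,
        feature_kind="pcc",
        conv=SMALL_CONV,
        sae=SMALL_SAE,
        dnn=SMALL_DNN,
        stages=FAST,
        seeds={"data": 11, "split": 1, "init": 0},
        out_dir=str(tmp_path / name),
    )


class TestPipeline:
    def test_end_to_end_artifacts(self, tmp_path):
        cfg = _tiny_pipeline_config(tmp_path, "run1")
        results = run_pipeline(cfg, compare=True)
        out = tmp_path / "run1"
        for artifact in (
            "recording.h5",
            "segments.h5",
            "segments_index.csv",
            "features_pcc.h5",
            "metrics_composite.csv",
            "metrics_baseline.csv",
            "models.h5",
            "report.json",
            "resolved_config.yaml",
            "manifest.json",
        ):
            assert (out / artifact).exists(), artifact
        report = results["report"]
        assert "composite" in report and "baseline_cnn" in report
        assert report["mode"] == "paper"

    def test_rerun_resumes_without_recomputation(self, tmp_path):
        cfg = _tiny_pipeline_config(tmp_path, "run2")
        run_pipeline(cfg)
        stamp = (tmp_path / "run2" / "recording.h5").stat().st_mtime_ns
        run_pipeline(cfg)  # all stages complete: nothing overwritten
        assert (tmp_path / "run2" / "recording.h5").stat().st_mtime_ns == stamp

    def test_force_reruns_all_stages(self, tmp_path):
        cfg = _tiny_pipeline_config(tmp_path, "run3")
        run_pipeline(cfg)
        stamp = (tmp_path / "run3" / "recording.h5").stat().st_mtime_ns
        run_pipeline(cfg, force=True)
        assert (tmp_path / "run3" / "recording.h5").stat().st_mtime_ns > stamp

    def test_resume_from_partial_manifest(self, tmp_path):
        cfg = _tiny_pipeline_config(tmp_path, "run4")
        run_pipeline(cfg)
        out = tmp_path / "run4"
        manifest = json.loads((out / "manifest.json").read_text())
        manifest["completed"] = ["simulate", "preprocess"]  # pretend interrupted
        (out / "manifest.json").write_text(json.dumps(manifest))
        stamp = (out / "recording.h5").stat().st_mtime_ns
        results = run_pipeline(cfg)
        assert (out / "recording.h5").stat().st_mtime_ns == stamp  # not regenerated
        assert "report" in results


class TestCLI:
    def test_simulate_preprocess_featurize_chain(self, tmp_path):
        from click.testing import CliRunner
        from eegemo.cli import main

        runner = CliRunner()
        rec = tmp_path / "rec.h5"
        segs = tmp_path / "segs.h5"
        feats = tmp_path / "feats.h5"
        r = runner.invoke(
            main,
            ["simulate", "--preset", "deap_like_small", "--seed", "3", "--out", str(rec)],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            main,
            ["preprocess", str(rec), str(segs), "--trim", "3", "--window", "8", "--step", "4"],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["featurize", str(segs), str(feats), "--kind", "sc"])
        assert r.exit_code == 0, r.output
        ft = eio.load_features(feats)
        assert ft.data.shape == (4 * 10 * 14, 4, 32, 4)

    def test_train_verb_with_config(self, tmp_path):
        from click.testing import CliRunner
        from eegemo.cli import main

        cfg = _tiny_pipeline_config(tmp_path, "cli_run")
        cfg_path = tmp_path / "cfg.yaml"
        cfg.to_yaml(cfg_path)
        runner = CliRunner()
        r = runner.invoke(main, ["train", "--config", str(cfg_path)])
        assert r.exit_code == 0, r.output
        assert "final_accuracy" in r.output
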