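"""HDF5 and CSV persistence for every pipeline stage.

One artifact per stage (recording -> segments -> features -> models /
metrics) so each stage can be produced, inspected and tested in isolation.
All layouts are plain datasets plus JSON-encoded attributes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import h5py
import numpy as np
import pandas as pd

from .features import FeatureTensor
from .nets.layers import Conv1DVertical, Dense, Dropout, Flatten, MaxPool2D
from .nets.network import Network
from .preprocess import BandStack, SegmentSet
from .synthetic import Recording


def save_recording(path, rec: Recording, seed: Optional[int] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype(np.float32))
        f.create_dataset("labels", data=rec.labels.astype(np.int8))
        f.attrs["fs"] = rec.fs
        f.attrs["preset"] = rec.preset_name
        f.attrs["label_map"] = json.dumps(rec.label_map)
        f.attrs["n_classes"] = rec.n_classes
        if seed is not None:
            f.attrs["seed"] = seed


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            data=f["data"][...],
            fs=float(f.attrs["fs"]),
            labels=f["labels"][...],
            preset_name=str(f.attrs.get("preset", "custom")),
            label_map=json.loads(f.attrs.get("label_map", "{}")),
            n_classes=int(f.attrs.get("n_classes", 2)),
        )


def save_segments(path, segs: SegmentSet, csv_index: Optional[Path] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=segs.data.astype(np.float32))
        f.create_dataset("labels", data=segs.labels.astype(np.int8))
        g = f.create_group("provenance")
        g.create_dataset("subject", data=segs.subject.astype(np.int32))
        g.create_dataset("trial", data=segs.trial.astype(np.int32))
        g.create_dataset("window_start_s", data=segs.window_start_s.astype(np.float64))
        f.attrs["fs"] = segs.fs
        f.attrs["band_edges"] = json.dumps(segs.band_edges)
        f.attrs["window_s"] = segs.window_s
        f.attrs["step_s"] = segs.step_s
    if csv_index is not None:
        pd.DataFrame(
            {
                "subject": segs.subject,
                "trial": segs.trial,
                "window_start_s": segs.window_start_s,
                "label": segs.labels,
            }
        ).to_csv(csv_index, index=False)


def load_segments(path) -> SegmentSet:
    with h5py.File(path, "r") as f:
        return SegmentSet(
            data=f["data"][...].astype(float),
            fs=float(f.attrs["fs"]),
            band_edges=tuple(tuple(b) for b in json.loads(f.attrs["band_edges"])),
            labels=f["labels"][...],
            subject=f["provenance/subject"][...],
            trial=f["provenance/trial"][...],
            window_start_s=f["provenance/window_start_s"][...],
            window_s=float(f.attrs["window_s"]),
            step_s=float(f.attrs["step_s"]),
        )


def save_features(path, ft: FeatureTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=ft.data.astype(np.float32))
        f.create_dataset("labels", data=np.asarray(ft.labels).astype(np.int8))
        if ft.subject is not None:
            g = f.create_group("provenance")
            g.create_dataset("subject", data=ft.subject.astype(np.int32))
            g.create_dataset("trial", data=ft.trial.astype(np.int32))
            g.create_dataset("window_start_s", data=ft.window_start_s.astype(np.float64))
        if ft.degenerate_mask is not None:
            f.create_dataset("degenerate_mask", data=ft.degenerate_mask.astype(bool))
        f.attrs["kind"] = ft.kind
        f.attrs["band_edges"] = json.dumps(ft.band_edges)
        f.attrs["scale_min"] = ft.scale_min
        f.attrs["scale_max"] = ft.scale_max


def load_features(path) -> FeatureTensor:
    with h5py.File(path, "r") as f:
        prov = {}
        if "provenance" in f:
            prov = {
                "subject": f["provenance/subject"][...],
                "trial": f["provenance/trial"][...],
                "window_start_s": f["provenance/window_start_s"][...],
            }
        return FeatureTensor(
            data=f["features"][...].astype(float),
            labels=f["labels"][...],
            kind=str(f.attrs["kind"]),
            band_edges=tuple(tuple(b) for b in json.loads(f.attrs["band_edges"])),
            scale_min=float(f.attrs["scale_min"]),
            scale_max=float(f.attrs["scale_max"]),
            degenerate_mask=f["degenerate_mask"][...] if "degenerate_mask" in f else None,
            **prov,
        )


# ---------------------------------------------------------------------------
# network weights

_LAYER_TAGS = {
    Conv1DVertical: "conv1d_vertical",
    Dense: "dense",
    Dropout: "dropout",
    Flatten: "flatten",
    MaxPool2D: "maxpool2d",
}


def _layer_meta(layer) -> Dict:
    if isinstance(layer, Conv1DVertical):
        return {
            "in_channels": layer.in_channels,
            "out_channels": layer.out_channels,
            "klen": layer.klen,
            "activation": layer.activation,
        }
    if isinstance(layer, Dense):
        return {
            "in_units": layer.in_units,
            "out_units": layer.out_units,
            "activation": layer.activation,
        }
    if isinstance(layer, Dropout):
        return {"rate": layer.rate}
    if isinstance(layer, MaxPool2D):
        return {"size": layer.size}
    return {}


def save_network(path_or_group, net: Network, name: str = "network") -> None:
    """Persist layer structure and weights under one HDF5 group."""

    def _write(f):
        g = f.create_group(name)
        g.attrs["loss"] = net.loss or ""
        g.attrs["n_layers"] = len(net.layers)
        for i, layer in enumerate(net.layers):
            lg = g.create_group(f"layer_{i:02d}")
            lg.attrs["tag"] = _LAYER_TAGS[type(layer)]
            lg.attrs["meta"] = json.dumps(_layer_meta(layer))
            if layer.trainable:
                for pname, arr in layer.params.items():
                    lg.create_dataset(pname, data=arr)

    if isinstance(path_or_group, (str, Path)):
        with h5py.File(path_or_group, "w") as f:
            _write(f)
    else:
        _write(path_or_group)


def load_network(path_or_group, name: str = "network", dtype=np.float64) -> Network:
    def _read(f) -> Network:
        g = f[name]
        layers = []
        for i in range(int(g.attrs["n_layers"])):
            lg = g[f"layer_{i:02d}"]
            tag = lg.attrs["tag"]
            meta = json.loads(lg.attrs["meta"])
            if tag == "conv1d_vertical":
                layer = Conv1DVertical(
                    meta["in_channels"], meta["out_channels"], meta["klen"], meta["activation"]
                )
            elif tag == "dense":
                layer = Dense(meta["in_units"], meta["out_units"], meta["activation"])
            elif tag == "dropout":
                layer = Dropout(meta["rate"])
            elif tag == "flatten":
                layer = Flatten()
            elif tag == "maxpool2d":
                layer = MaxPool2D(meta["size"])
            else:
                raise ValueError(f"unknown layer tag {tag!r}")
            if getattr(layer, "trainable", False):
                for pname in layer.params:
                    layer.params[pname] = lg[pname][...].astype(dtype)
            layers.append(layer)
        loss = str(g.attrs.get("loss", "")) or None
        return Network(layers, loss=loss)

    if isinstance(path_or_group, (str, Path)):
        with h5py.File(path_or_group, "r") as f:
            return _read(f)
    return _read(path_or_group)


# ---------------------------------------------------------------------------
# metrics


def metrics_frame(run_id: str, histories: Dict[str, Dict[str, list]]) -> pd.DataFrame:
    """Tidy per-epoch metrics: (run_id, stage, epoch, metric, value)."""
    rows = []
    for stage, hist in histories.items():
        for metric, values in hist.items():
            for epoch, value in enumerate(values, start=1):
                rows.append(
                    {
                        "run_id": run_id,
                        "stage": stage,
                        "epoch": epoch,
                        "metric": metric,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)
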