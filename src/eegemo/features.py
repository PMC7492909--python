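"""Per-band 2D feature images: channel correlations, PCA scores, statistics.

Three feature kinds are supported, each computed independently per segment
and per frequency band, then stacked over the band axis:

``pcc``
    channels x channels Pearson-correlation matrix — a functional
    connectivity image; the strongest of the three for correlation-coded
    class structure.
``pca``
    channels x k matrix of principal-component scores where channels are
    the observations and time points the variables; with k = n_channels
    this yields a square image (32 x 32 or 62 x 62).
``sc``
    channels x 4 matrix of per-channel statistics in fixed column order
    (variance, mean, kurtosis, skewness); kurtosis is Fisher excess and
    all moments use population (n) denominators.

Stacked tensors are min-max scaled to [0, 1] so the autoencoder stage can
score reconstructions with binary crossentropy; the scaling constants are
stored for exact inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _stats
from sklearn.decomposition import PCA as _PCA

from .preprocess import SegmentSet

FEATURE_KINDS = ("pcc", "pca", "sc")


@dataclass
class FeatureTensor:
    """Feature images: (samples, bands, H, W) with aligned labels.

    ``scale_min``/``scale_max`` are the global min-max constants applied at
    stacking time; :meth:`unscaled` inverts them.  ``degenerate_mask`` flags
    samples in which a zero-variance channel forced the correlation /
    moment conventions.
    """

    data: np.ndarray
    labels: np.ndarray
    kind: str
    band_edges: Tuple[Tuple[float, float], ...]
    scale_min: float
    scale_max: float
    subject: Optional[np.ndarray] = None
    trial: Optional[np.ndarray] = None
    window_start_s: Optional[np.ndarray] = None
    degenerate_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("FeatureTensor.data must be (samples, bands, H, W)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels misaligned with samples")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def image_shape(self) -> Tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def unscaled(self) -> np.ndarray:
        """Invert the stored min-max scaling."""
        return self.data * (self.scale_max - self.scale_min) + self.scale_min


def pcc_matrix(segment: np.ndarray, return_flags: bool = False):
    """Pearson correlation of every channel pair of a (channels, time) segment.

    Zero-variance channels make the correlation undefined; by convention
    their whole row and column (diagonal included) are set to 0 so the
    image stays finite, and the affected channels are flagged.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 2 or seg.shape[1] < 2:
        raise ValueError("segment must be (channels, time>=2)")
    sd = seg.std(axis=1)
    const = sd == 0
    if const.any():
        centred = seg - seg.mean(axis=1, keepdims=True)
        sd_safe = np.where(const, 1.0, sd)
        c = (centred @ centred.T) / seg.shape[1] / np.outer(sd_safe, sd_safe)
        c[const, :] = 0.0
        c[:, const] = 0.0
        np.fill_diagonal(c, np.where(const, 0.0, 1.0))
    else:
        c = np.corrcoef(seg)
        np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    return (c, const) if return_flags else c


def pca_features(segment: np.ndarray, k: Optional[int] = None) -> np.ndarray:
    """Top-k principal-component scores treating channels as observations.

    The segment's time points are the variables; the returned matrix is
    (channels, k) of scores on the leading components, ordered by
    decreasing explained variance.  The fit is per segment, so no
    information crosses segment boundaries.  Signs follow a deterministic
    convention: the largest-magnitude loading of each component is
    positive.
    """
    seg = np.asarray(segment, dtype=float)
    n_ch = seg.shape[0]
    if k is None:
        k = n_ch
    if k > n_ch:
        raise ValueError(f"k={k} exceeds n_channels={n_ch}")
    pca = _PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(seg)
    comps = pca.components_
    flip = np.sign(comps[np.arange(k), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return scores * flip


def sc_features(segment: np.ndarray, return_flags: bool = False):
    """Per-channel (variance, mean, kurtosis, skewness), population denominators.

    Kurtosis is Fisher excess (0 for a normal distribution).  Channels with
    zero variance get kurtosis and skewness 0 by convention and are flagged.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 2 or seg.shape[1] < 4:
        raise ValueError("segment must be (channels, time>=4)")
    var = seg.var(axis=1)
    mean = seg.mean(axis=1)
    const = var == 0
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        kurt = _stats.kurtosis(seg, axis=1, fisher=True, bias=True)
        skew = _stats.skew(seg, axis=1, bias=True)
    kurt = np.where(const, 0.0, kurt)
    skew = np.where(const, 0.0, skew)
    out = np.column_stack([var, mean, kurt, skew])
    return (out, const) if return_flags else out


def stack_bands(
    per_band: Sequence[np.ndarray],
    labels: np.ndarray,
    kind: str,
    band_edges: Sequence[Tuple[float, float]],
    scale: bool = True,
    **provenance,
) -> FeatureTensor:
    """Stack per-band image arrays (each (samples, H, W)) into one tensor.

    The band axis follows the order of ``band_edges``.  A single global
    min-max scaling to [0, 1] is applied (constants stored) so the tensor
    is a valid target for binary-crossentropy reconstruction downstream.
    """
    shapes = {a.shape for a in per_band}
    if len(shapes) != 1:
        raise ValueError(f"band shape mismatch: {sorted(shapes)}")
    if len(per_band) != len(band_edges):
        raise ValueError("one array per band required")
    data = np.stack(per_band, axis=1).astype(np.float64)
    if len(labels) != data.shape[0]:
        raise ValueError("labels misaligned with samples")
    if scale:
        lo, hi = float(data.min()), float(data.max())
        span = hi - lo if hi > lo else 1.0
        data = (data - lo) / span
        scale_min, scale_max = lo, lo + span
    else:
        scale_min, scale_max = 0.0, 1.0
    return FeatureTensor(
        data=data,
        labels=np.asarray(labels),
        kind=kind,
        band_edges=tuple(tuple(b) for b in band_edges),
        scale_min=scale_min,
        scale_max=scale_max,
        **provenance,
    )


def _segment_image(seg: np.ndarray, kind: str, k: Optional[int]):
    if kind == "pcc":
        return pcc_matrix(seg, return_flags=True)
    if kind == "pca":
        return pca_features(seg, k=k), np.zeros(seg.shape[0], dtype=bool)
    if kind == "sc":
        return sc_features(seg, return_flags=True)
    raise ValueError(f"unknown feature kind {kind!r}")


def feature_tensor(segments: SegmentSet, kind: str, k: Optional[int] = None) -> FeatureTensor:
    """Compute one feature kind for every segment and band, then stack.

    This is the bridge from windowed band-decomposed signals to network
    input: a DEAP-shaped run (32 channels, 8-s/4-s windows) yields
    N x 4 x 32 x 32 tensors for ``pcc``/``pca`` and N x 4 x 32 x 4 for
    ``sc``.
    """
    n_seg, n_band = segments.data.shape[:2]
    per_band: List[np.ndarray] = []
    degenerate = np.zeros(n_seg, dtype=bool)
    for b in range(n_band):
        imgs = []
        for i in range(n_seg):
            img, flags = _segment_image(segments.data[i, b], kind, k)
            degenerate[i] |= bool(flags.any())
            imgs.append(img)
        per_band.append(np.stack(imgs))
    return stack_bands(
        per_band,
        segments.labels,
        kind,
        segments.band_edges,
        subject=segments.subject,
        trial=segments.trial,
        window_start_s=segments.window_start_s,
        degenerate_mask=degenerate,
    )
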