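"""Synthetic EEG with class-conditional, band-specific correlation structure.

Real emotion-EEG corpora are gated behind access applications, so the test
bed is a generator that emulates their geometry (subjects x trials x
channels x samples at a sampling rate, with per-trial labels) while placing
the class signal where the downstream features look for it: in the
inter-channel correlation pattern of each frequency band.

Per trial, each band gets a handful of band-limited latent sources (white
noise passed through the same zero-phase Butterworth band-pass the analysis
pipeline uses, then scaled to unit variance).  The sources are mixed into
channels by a class-conditional matrix ``M[class, band] = M0[band] +
effect_size * D[class, band]``; bands are summed and white sensor noise is
added.  ``M0`` and ``D`` are drawn once per seed, so the whole recording is
a deterministic function of its :class:`SynthSpec`.  At ``effect_size = 0`` the two (or
three) classes are draws from one distribution and nothing downstream
should beat chance.

Marginal channel variances are deliberately class-independent: the label
lives in the correlation structure, so the channel-correlation feature is
the directly discriminative one and PCA/statistical features pick the
signal up only indirectly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _signal

from .preprocess import DEFAULT_BANDS, DEFAULT_FILTER_ORDER, band_sos


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic EEG study.

    ``effect_size`` scales the class-dependent part of the mixing matrices
    (0 means the classes are generatively identical); ``noise_sd`` is the
    standard deviation of the additive white sensor noise, in the same
    units as the unit-variance band sources.
    """

    n_subjects: int
    n_trials_per_subject: int
    n_channels: int
    fs: float
    duration: float
    n_classes: int = 2
    n_latent_sources: int = 6
    band_edges: Tuple[Tuple[float, float], ...] = DEFAULT_BANDS
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    balanced: bool = True
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"duration * fs = {n} is not an integer sample count")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        prev_hi = 0.0
        for lo, hi in self.band_edges:
            if not (0.0 < lo < hi):
                raise ValueError(f"degenerate band ({lo}, {hi})")
            if hi >= self.fs / 2.0:
                raise ValueError(f"band ({lo}, {hi}) reaches Nyquist at fs={self.fs}")
            if lo < prev_hi:
                raise ValueError("band_edges must be ordered")
            prev_hi = hi

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def replace(self, **kw) -> "SynthSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class Recording:
    """Raw multichannel EEG: (subjects, trials, channels, samples) plus labels.

    ``label_map`` records how external label conventions (e.g. -1/0/1 for
    negative/neutral/positive) map onto the contiguous codes stored in
    ``labels``.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    preset_name: str = "custom"
    label_map: Dict[str, int] = field(default_factory=dict)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("Recording.data must be (subjects, trials, channels, samples)")
        if self.labels.shape != self.data.shape[:2]:
            raise ValueError("labels must be (subjects, trials)")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")
        valid = set(range(self.n_classes))
        if not set(np.unique(self.labels)) <= valid:
            raise ValueError(f"labels must be contiguous codes in {sorted(valid)}")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.data.shape[3] / self.fs


_LABEL_MAPS = {
    2: {"low": 0, "high": 1},
    3: {"negative": 0, "neutral": 1, "positive": 2},
}


def _balanced_labels(rng: np.random.Generator, n_subjects: int, n_trials: int, n_classes: int) -> np.ndarray:
    """Per subject, classes as balanced as n_trials allows, order shuffled."""
    labels = np.empty((n_subjects, n_trials), dtype=np.int8)
    base = np.resize(np.arange(n_classes), n_trials)
    for s in range(n_subjects):
        labels[s] = rng.permutation(base)
    return labels


def generate_recording(spec: SynthSpec) -> Recording:
    """Draw one synthetic study; identical specs give bit-identical output."""
    rng = np.random.default_rng(spec.seed)
    n_b = len(spec.band_edges)
    L, C, T = spec.n_latent_sources, spec.n_channels, spec.n_samples

    # Mixing matrices are part of the seed contract: drawn once, before any
    # trial noise, in a label-independent order.
    scale = 1.0 / np.sqrt(L)
    M0 = rng.standard_normal((n_b, C, L)) * scale
    D = rng.standard_normal((spec.n_classes, n_b, C, L)) * scale

    if spec.balanced:
        labels = _balanced_labels(rng, spec.n_subjects, spec.n_trials_per_subject, spec.n_classes)
    else:
        labels = rng.integers(
            0, spec.n_classes, size=(spec.n_subjects, spec.n_trials_per_subject)
        ).astype(np.int8)

    sos = [band_sos(lo, hi, spec.fs, DEFAULT_FILTER_ORDER) for lo, hi in spec.band_edges]
    mix = M0[None] + spec.effect_size * D  # (class, band, C, L)

    data = np.empty((spec.n_subjects, spec.n_trials_per_subject, C, T), dtype=np.float32)
    for s in range(spec.n_subjects):
        for t in range(spec.n_trials_per_subject):
            c = labels[s, t]
            x = np.zeros((C, T))
            for b in range(n_b):
                src = rng.standard_normal((L, T))
                src = _signal.sosfiltfilt(sos[b], src, axis=-1)
                src /= src.std(axis=-1, keepdims=True)
                x += mix[c, b] @ src
            x += spec.noise_sd * rng.standard_normal((C, T))
            data[s, t] = x
    return Recording(
        data=data,
        fs=spec.fs,
        labels=labels,
        preset_name=spec.preset_name,
        label_map=dict(_LABEL_MAPS[spec.n_classes]),
        n_classes=spec.n_classes,
    )


def class_separability_check(
    rec: Recording,
    band_edges: Sequence[Tuple[float, float]] = DEFAULT_BANDS,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Per-band separation of class-mean channel-correlation matrices.

    For each band, every trial's band-passed channel-correlation matrix is
    vectorised (upper triangle); the score is the mean Euclidean distance
    between class-mean vectors over all class pairs.  Approximately zero
    when classes are generatively identical and nondecreasing in the
    generator's effect size.
    """
    labels = rec.labels.reshape(-1)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("separability needs at least two classes present")
    counts = {c: int((labels == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"need >= 2 trials per class, got {counts}")

    flat = rec.data.reshape(-1, rec.n_channels, rec.data.shape[-1]).astype(float)
    iu = np.triu_indices(rec.n_channels, k=1)
    scores = np.empty(len(band_edges))
    for b, (lo, hi) in enumerate(band_edges):
        sos = band_sos(lo, hi, rec.fs, order)
        filt = _signal.sosfiltfilt(sos, flat, axis=-1)
        vecs = np.stack([np.corrcoef(x)[iu] for x in filt])
        means = {c: vecs[labels == c].mean(axis=0) for c in classes}
        d = [
            np.linalg.norm(means[a] - means[b_])
            for i, a in enumerate(classes)
            for b_ in classes[i + 1 :]
        ]
        scores[b] = float(np.mean(d))
    return scores
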