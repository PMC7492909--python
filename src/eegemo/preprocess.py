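"""Trimming, band-pass filtering, band decomposition, resampling, windowing.

Each trial is processed independently; no filtering state crosses trial
boundaries.  Filters are 4th-order Butterworth band-passes applied
forward-backward (zero phase), the standard choice when downstream features
are inter-channel correlations, which phase distortion would corrupt.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence, Tuple

import numpy as np
from scipy import signal

#: The four analysis bands, in Hz.  The label-to-range pairing follows the
#: source configuration verbatim; band names are treated as opaque elsewhere.
DEFAULT_BANDS: Tuple[Tuple[float, float], ...] = (
    (1.0, 7.0),
    (8.0, 13.0),
    (14.0, 30.0),
    (30.0, 45.0),
)

DEFAULT_FILTER_ORDER = 4


def band_sos(low: float, high: float, fs: float, order: int = DEFAULT_FILTER_ORDER) -> np.ndarray:
    """Second-order sections of a Butterworth band-pass filter."""
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({fs / 2} Hz)"
        )
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(
    x: np.ndarray,
    fs: float,
    low: float,
    high: float,
    order: int = DEFAULT_FILTER_ORDER,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along ``axis``; shape preserved."""
    sos = band_sos(low, high, fs, order)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


# ---------------------------------------------------------------------------
# containers


@dataclass
class BandStack:
    """Band-decomposed trials, flattened over (subject, trial).

    ``data`` has shape (trials_total, n_bands, n_channels, n_samples); the
    ``subject``/``trial`` arrays keep provenance for every flattened row.
    """

    data: np.ndarray
    fs: float
    band_edges: Tuple[Tuple[float, float], ...]
    labels: np.ndarray
    subject: np.ndarray
    trial: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BandStack.data must be 4-D (trials, bands, channels, time)")
        if self.data.shape[1] != len(self.band_edges):
            raise ValueError("bands axis must match band_edges")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must align with trials")

    @property
    def n_bands(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[-1] / self.fs


@dataclass
class SegmentSet:
    """Sliding-window segments cut from a :class:`BandStack`.

    Every segment inherits the label of its source trial.  Provenance
    (subject, trial, window start in seconds) is carried per segment.
    """

    data: np.ndarray  # (segments, bands, channels, window_samples)
    fs: float
    band_edges: Tuple[Tuple[float, float], ...]
    labels: np.ndarray
    subject: np.ndarray
    trial: np.ndarray
    window_start_s: np.ndarray
    window_s: float
    step_s: float

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# operations on recordings (imported lazily to avoid a cycle with synthetic)


def trim_lead(rec, trim_s: float):
    """Drop the first ``trim_s`` seconds of every trial.

    Emulates discarding a pre-stimulus baseline (e.g. the first 3 s of a
    63-s trial, leaving 60 s).
    """
    n_drop = trim_s * rec.fs
    if abs(n_drop - round(n_drop)) > 1e-9:
        raise ValueError(f"trim_s * fs = {n_drop} is not an integer sample count")
    n_drop = int(round(n_drop))
    if n_drop >= rec.data.shape[-1]:
        raise ValueError(f"trim of {trim_s}s is not shorter than the trial")
    if n_drop == 0:
        return rec
    return replace(rec, data=rec.data[..., n_drop:])


def downsample(rec, target_fs: float):
    """Resample every trial to ``target_fs`` with polyphase anti-alias filtering.

    Integer and rational ratios are both handled by ``scipy.signal.resample_poly``;
    the output length is ``ceil(n * up / down)`` for ``target_fs/fs = up/down``
    in lowest terms (for 63 s at 512 Hz down to 128 Hz that is exactly 8064
    samples).
    """
    if target_fs > rec.fs:
        raise ValueError(f"upsampling requested ({rec.fs} -> {target_fs} Hz)")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs).limit_denominator(10_000) / Fraction(rec.fs).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(np.asarray(rec.data, dtype=float), up, down, axis=-1)
    return replace(rec, data=out, fs=float(target_fs))


def decompose_bands(
    rec,
    band_edges: Sequence[Tuple[float, float]] = DEFAULT_BANDS,
    order: int = DEFAULT_FILTER_ORDER,
) -> BandStack:
    """Filter a recording into one copy per frequency band.

    The (subjects, trials) axes are flattened into a single trial axis with
    provenance retained, ready for windowing.
    """
    band_edges = tuple((float(lo), float(hi)) for lo, hi in band_edges)
    for lo, hi in band_edges:
        band_sos(lo, hi, rec.fs, order)  # validate every band up front
    n_subj, n_trials, n_ch, n_t = rec.data.shape
    flat = rec.data.reshape(n_subj * n_trials, n_ch, n_t)
    out = np.empty((flat.shape[0], len(band_edges), n_ch, n_t), dtype=float)
    for b, (lo, hi) in enumerate(band_edges):
        out[:, b] = bandpass(flat, rec.fs, lo, hi, order=order, axis=-1)
    subject = np.repeat(np.arange(n_subj), n_trials)
    trial = np.tile(np.arange(n_trials), n_subj)
    return BandStack(
        data=out,
        fs=rec.fs,
        band_edges=band_edges,
        labels=np.asarray(rec.labels).reshape(-1).copy(),
        subject=subject,
        trial=trial,
    )


def n_windows(duration_s: float, window_s: float, step_s: float) -> int:
    """Number of sliding windows: ``floor((duration - window)/step) + 1``.

    Windows are aligned to the trial start and a trailing partial window is
    dropped, so a 60-s trial yields 14 windows of 8 s stepping 4 s and 7
    windows of 12 s stepping 8 s.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    if window_s > duration_s:
        raise ValueError(f"window of {window_s}s exceeds trial duration {duration_s}s")
    # guard float jitter in the division
    return int(np.floor((duration_s - window_s) / step_s + 1e-9)) + 1


def segment_windows(stack: BandStack, window_s: float, step_s: float) -> SegmentSet:
    """Cut every trial of a band stack into overlapping fixed-length windows.

    Segment k of a trial starts at ``k * step_s``; every segment keeps its
    source trial's label.
    """
    win = window_s * stack.fs
    step = step_s * stack.fs
    if abs(win - round(win)) > 1e-9 or abs(step - round(step)) > 1e-9:
        raise ValueError("window_s and step_s must be integer sample counts at this fs")
    win, step = int(round(win)), int(round(step))
    n_t = stack.data.shape[-1]
    n_seg = n_windows(n_t / stack.fs, window_s, step_s)
    starts = np.arange(n_seg) * step

    n_trials = stack.data.shape[0]
    segs = np.empty(
        (n_trials * n_seg, stack.n_bands, stack.data.shape[2], win), dtype=stack.data.dtype
    )
    for i, s in enumerate(starts):
        segs[i::n_seg] = stack.data[..., s : s + win]
    rep = lambda a: np.repeat(a, n_seg)
    return SegmentSet(
        data=segs,
        fs=stack.fs,
        band_edges=stack.band_edges,
        labels=rep(stack.labels),
        subject=rep(stack.subject),
        trial=rep(stack.trial),
        window_start_s=np.tile(starts / stack.fs, n_trials),
        window_s=float(window_s),
        step_s=float(step_s),
    )
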