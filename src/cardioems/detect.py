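"""Trace conditioning and adaptive-threshold beat detection.

Raw FP traces are low-pass filtered (zero-phase, so feature-point timing is
unbiased); raw MB carrier traces are demodulated to the impedance envelope.
Beats are then located with a sliding median + k*MAD threshold: the local
median tracks baseline drift, the MAD estimates the local noise spread
robustly against the beats themselves, and k sets the detection strictness
in units of noise standard deviations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .synth import InvalidParameterError

__all__ = [
    "FilterSpec",
    "DetectionParams",
    "BeatEvent",
    "FP_DETECTION",
    "MB_DETECTION",
    "apply_filter",
    "demodulate_impedance",
    "adaptive_threshold",
    "detect_beats",
]

_MAD_TO_SD = 1.4826  # Gaussian consistency factor


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth filter specification."""

    kind: str  # lowpass | highpass | bandpass
    cutoff_hz: float | tuple[float, float]
    order: int = 4

    def validate(self, fs: float) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise InvalidParameterError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise InvalidParameterError("filter order must be >= 1")
        cutoffs = (
            self.cutoff_hz if isinstance(self.cutoff_hz, tuple) else (self.cutoff_hz,)
        )
        if self.kind == "bandpass" and len(cutoffs) != 2:
            raise InvalidParameterError("bandpass needs (low, high) cutoffs")
        for c in cutoffs:
            if not 0 < c < fs / 2:
                raise InvalidParameterError(
                    f"cutoff {c} Hz outside (0, Nyquist={fs / 2} Hz)"
                )


@dataclass(frozen=True)
class DetectionParams:
    """Adaptive-threshold detector settings for one signal kind."""

    threshold_k: float = 5.0  # multiples of robust (MAD-based) SD
    window: float = 2.0  # s, sliding-statistics window
    refractory: float = 0.35  # s, minimum anchor spacing
    polarity: str = "auto"  # auto | positive | negative
    pre_max: float = 0.25  # s, max pre-anchor extraction window
    post_max: float = 0.60  # s, max post-anchor extraction window
    post_frac: float = 0.80  # post window as a fraction of the next inter-beat gap

    def validate(self) -> None:
        if self.threshold_k <= 0 or self.refractory <= 0 or self.window <= 0:
            raise InvalidParameterError("threshold_k, window, refractory must be > 0")
        if self.polarity not in ("auto", "positive", "negative"):
            raise InvalidParameterError(f"bad polarity {self.polarity!r}")


#: defaults tuned per modality: the FP fast spike is narrow and large (k=5,
#: 2 s window); the MB bump is broad and occupies a large duty cycle, so the
#: window is longer and k lower.  The 0.35 s FP refractory must outlast the
#: crest of the slow second wave (so it is never double-counted as a beat)
#: while still resolving rates up to ~170/min.
FP_DETECTION = DetectionParams(
    threshold_k=5.0, window=2.0, refractory=0.35, pre_max=0.25, post_max=0.60,
    post_frac=0.80,
)
MB_DETECTION = DetectionParams(
    threshold_k=3.0, window=5.0, refractory=0.30, pre_max=0.50, post_max=0.75,
    post_frac=0.70,
)


@dataclass(frozen=True)
class BeatEvent:
    """One detected beat: extremum anchor plus its extraction window."""

    anchor_time: float  # s; fast-spike peak (FP) or bump peak (MB)
    window_start: float
    window_end: float
    channel: int = 0
    signal_kind: str = "FP"  # FP | MB
    polarity_flipped: bool = False


def apply_filter(trace: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth filtering."""
    spec.validate(fs)
    trace = np.asarray(trace, dtype=float)
    if len(trace) == 0:
        return trace.copy()
    wn = (
        [c / (fs / 2) for c in spec.cutoff_hz]
        if isinstance(spec.cutoff_hz, tuple)
        else spec.cutoff_hz / (fs / 2)
    )
    sos = sps.butter(spec.order, wn, btype=spec.kind, output="sos")
    return sps.sosfiltfilt(sos, trace)


def demodulate_impedance(
    raw_carrier: np.ndarray,
    fs: float,
    carrier_freq: float,
    fs_mb: float = 1000.0,
    lp_cutoff: float = 200.0,
) -> np.ndarray:
    """Recover the MB impedance trace from an amplitude-modulated carrier.

    Implemented as complex mixing at the carrier frequency followed by
    zero-phase low-pass filtering (a digital lock-in), which equals the
    short-time Fourier magnitude at the carrier bin.  The envelope is
    referenced to its median and resampled to ``fs_mb``.
    """
    if fs < 4.0 * carrier_freq:
        raise InvalidParameterError("fs must be >= 4x carrier_freq")
    raw = np.asarray(raw_carrier, dtype=float)
    if len(raw) == 0:
        return raw.copy()
    t = np.arange(len(raw)) / fs
    mixed = raw * np.exp(-2j * np.pi * carrier_freq * t)
    sos = sps.butter(4, lp_cutoff / (fs / 2), btype="lowpass", output="sos")
    env = 2.0 * np.abs(sps.sosfiltfilt(sos, mixed))
    if np.max(env) < 1e-12:
        warnings.warn("carrier absent: demodulated envelope is ~0", stacklevel=2)
        n_out = int(round(len(raw) / fs * fs_mb))
        return np.zeros(n_out)
    t_out = np.arange(0.0, len(raw) / fs, 1.0 / fs_mb)
    mb = np.interp(t_out, t, env)
    return mb - np.median(mb)


def _sliding_median_mad(trace: np.ndarray, w: int):
    """Median and MAD on half-overlapping windows, interpolated to all samples."""
    n = len(trace)
    hop = max(1, w // 2)
    starts = list(range(0, max(1, n - w + 1), hop))
    if starts[-1] != n - w and n > w:
        starts.append(n - w)
    centers, meds, mads = [], [], []
    for s in starts:
        chunk = trace[s : s + w]
        m = np.median(chunk)
        centers.append(s + len(chunk) / 2.0)
        meds.append(m)
        mads.append(np.median(np.abs(chunk - m)))
    centers = np.asarray(centers)
    idx = np.arange(n)
    med = np.interp(idx, centers, meds)
    mad = np.interp(idx, centers, mads)
    return med, mad


def adaptive_threshold(
    trace: np.ndarray, fs: float, params: DetectionParams
) -> np.ndarray:
    """Sliding median + k * (MAD-scaled) SD, one value per sample."""
    params.validate()
    trace = np.asarray(trace, dtype=float)
    w = int(round(params.window * fs))
    if w >= len(trace):
        warnings.warn(
            "stats window longer than trace: using a single global threshold",
            stacklevel=2,
        )
        med = np.median(trace)
        mad = np.median(np.abs(trace - med))
        return np.full(len(trace), med + params.threshold_k * _MAD_TO_SD * mad)
    med, mad = _sliding_median_mad(trace, w)
    return med + params.threshold_k * _MAD_TO_SD * mad


def _resolve_polarity(trace: np.ndarray, mode: str) -> bool:
    """True if the trace should be flipped (negative-dominant excursions)."""
    if mode == "positive":
        return False
    if mode == "negative":
        return True
    centred = trace - np.median(trace)
    return abs(centred.min()) > abs(centred.max())


def detect_beats(
    trace: np.ndarray,
    fs: float,
    params: DetectionParams,
    signal_kind: str = "FP",
    channel: int = 0,
) -> list[BeatEvent]:
    """Locate beats as suprathreshold excursions respecting a refractory period.

    Each contiguous suprathreshold run contributes one candidate anchored at
    its extremum; candidates closer than ``params.refractory`` to the last
    accepted anchor are discarded (this also suppresses the slower FP second
    wave, which crests within the refractory window of the fast spike).
    Extraction windows extend up to ``pre_max``/``post_max`` seconds around
    the anchor but never overlap a neighbouring beat's core.
    """
    params.validate()
    trace = np.asarray(trace, dtype=float)
    if len(trace) == 0:
        return []
    flipped = _resolve_polarity(trace, params.polarity)
    y = -trace if flipped else trace
    th = adaptive_threshold(y, fs, params)

    above = y > th
    if not np.any(above):
        return []
    # anchors come from a lightly smoothed copy (~3 ms) so wideband noise on
    # a peak's crest cannot drag the anchor off the true extremum
    n_sm = max(1, int(round(0.003 * fs)))
    if n_sm > 1:
        kernel = np.full(n_sm, 1.0 / n_sm)
        ys = np.convolve(y, kernel, mode="same")
    else:
        ys = y
    idx = np.flatnonzero(above)
    # one excursion = suprathreshold runs separated by less than half the
    # refractory period (noise briefly dipping below threshold, or the FP
    # second wave re-crossing it, must not split/duplicate a beat)
    merge_gap = max(1, int(round(0.5 * params.refractory * fs)))
    run_breaks = np.flatnonzero(np.diff(idx) > merge_gap)
    run_starts = np.concatenate(([0], run_breaks + 1))
    run_ends = np.concatenate((run_breaks, [len(idx) - 1]))

    anchors = []
    refr = int(round(params.refractory * fs))
    last = -10 * refr
    half = n_sm // 2
    for rs, re in zip(run_starts, run_ends):
        i0, i1 = idx[rs], idx[re] + 1
        peak = i0 + int(np.argmax(ys[i0:i1]))
        # smoothing drags the crest toward the slower flank; the raw extremum
        # within half a smoothing window of the candidate is unbiased
        lo, hi = max(0, peak - half), min(len(y), peak + half + 1)
        peak = lo + int(np.argmax(y[lo:hi]))
        if peak - last < refr:
            continue
        anchors.append(peak)
        last = peak

    n = len(trace)
    events = []
    for j, a in enumerate(anchors):
        prev_a = anchors[j - 1] if j > 0 else None
        next_a = anchors[j + 1] if j + 1 < len(anchors) else None
        pre = params.pre_max * fs
        if prev_a is not None:
            pre = min(pre, 0.45 * (a - prev_a))
        post = params.post_max * fs
        if next_a is not None:
            post = min(post, params.post_frac * (next_a - a))
        w0 = max(0, int(math.floor(a - pre)))
        w1 = min(n - 1, int(math.ceil(a + post)))
        events.append(
            BeatEvent(
                anchor_time=a / fs,
                window_start=w0 / fs,
                window_end=w1 / fs,
                channel=channel,
                signal_kind=signal_kind,
                polarity_flipped=flipped,
            )
        )
    return events
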