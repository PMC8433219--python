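"""E1–E8 / M1–M5 feature-point localization and the 36 feature parameters.

Feature points per beat
-----------------------
FP (firing potential): E1/E2 at 10%/50% of the rising edge, E3 the first
peak, E4 the valley, E5 at 50% of the second rising edge, E6 the second
peak, E7 at 50% of the second falling edge, E8 the second valley.

MB (mechanical beating): M1/M2 at 10%/50% of the rising edge, M3 the peak,
M4/M5 at 50%/90% of the falling edge.

Fraction conventions: a rising f% point is where the signal has risen f of
(peak − pre-onset baseline); a falling f% point is where it has descended f
of (peak − post-beat baseline).  All crossings are linearly interpolated
between samples; missing morphology (e.g. a vanished second wave or a
contraction bump below the noise floor) yields missing points with reason
codes, never fabricated values.

Feature parameters
------------------
12 FP: firing interval/rate, first amplitude (E3−E4), second amplitude
(E6−E8), durations E1E8, E1E3, E2E3, E3E4, E4E8, E4E6, E6E7, E6E8 (plus the
optional E6E8 slope).  8 MB: beating interval/rate, beating amplitude
(M3 − baseline), durations M1M5, M1M2, M1M3, M2M3, M3M4.  16 FP–MB: the
signed times E_i→M_j for i in {1,4,6,8}, j in {1,2,3,4}.  Intervals are
measured peak-to-peak (E3→E3, M3→M3) between consecutive beats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .detect import BeatEvent
from .synth import Recording

__all__ = [
    "FPPoints",
    "MBPoints",
    "BeatPair",
    "FP_PARAMS",
    "MB_PARAMS",
    "FPMB_PARAMS",
    "ALL_PARAMS",
    "edge_crossing",
    "extract_fp_points",
    "extract_mb_points",
    "pair_beats",
    "compute_feature_vector",
    "summarize_epoch",
]

FP_PARAMS = (
    "firing_interval",
    "firing_rate",
    "first_amplitude",
    "second_amplitude",
    "E1E8",
    "E1E3",
    "E2E3",
    "E3E4",
    "E4E8",
    "E4E6",
    "E6E7",
    "E6E8",
)
MB_PARAMS = (
    "beating_interval",
    "beating_rate",
    "beating_amplitude",
    "M1M5",
    "M1M2",
    "M1M3",
    "M2M3",
    "M3M4",
)
FPMB_PARAMS = tuple(f"E{i}M{j}" for i in (1, 4, 6, 8) for j in (1, 2, 3, 4))
#: the 36 named parameters plus the optional E6E8 slope
ALL_PARAMS = FP_PARAMS + MB_PARAMS + FPMB_PARAMS
OPTIONAL_PARAMS = ("E6E8_slope",)

FP_POINT_NAMES = ("E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8")
MB_POINT_NAMES = ("M1", "M2", "M3", "M4", "M5")


@dataclass
class FPPoints:
    """E1–E8 of one beat: times (s), values (µV), baseline, missing reasons."""

    times: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)
    baseline: float = float("nan")
    missing: dict = field(default_factory=dict)

    def time(self, name: str) -> float:
        return self.times.get(name, float("nan"))

    def value(self, name: str) -> float:
        return self.values.get(name, float("nan"))


@dataclass
class MBPoints:
    """M1–M5 of one beat: times (s), values (Ω), baseline, missing reasons."""

    times: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)
    baseline: float = float("nan")
    missing: dict = field(default_factory=dict)

    def time(self, name: str) -> float:
        return self.times.get(name, float("nan"))

    def value(self, name: str) -> float:
        return self.values.get(name, float("nan"))


@dataclass
class BeatPair:
    """One FP beat with its (optionally missing) paired MB beat."""

    fp_points: FPPoints
    mb_points: Optional[MBPoints] = None

    @property
    def pairing_lag(self) -> float:
        if self.mb_points is None:
            return float("nan")
        return self.mb_points.time("M3") - self.fp_points.time("E3")


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def edge_crossing(
    times: np.ndarray,
    values: np.ndarray,
    start_ref: float,
    end_ref: float,
    fraction: float,
    direction: str = "rising",
):
    """Time at which the signal crosses ``start_ref + fraction*(end_ref-start_ref)``.

    Rising edges take the first upward crossing; falling edges the last
    downward crossing; both linearly interpolated between samples.  Returns
    ``(time, None)`` or ``(nan, reason)`` when the level is never crossed.
    """
    if start_ref == end_ref:
        return float("nan"), "degenerate_refs"
    level = start_ref + fraction * (end_ref - start_ref)
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(v) < 2:
        return float("nan"), "segment_too_short"
    if direction == "rising":
        hits = np.flatnonzero((v[:-1] < level) & (v[1:] >= level))
        if len(hits) == 0:
            return float("nan"), "level_not_crossed"
        i = hits[0]
    elif direction == "falling":
        hits = np.flatnonzero((v[:-1] >= level) & (v[1:] < level))
        if len(hits) == 0:
            return float("nan"), "level_not_crossed"
        i = hits[-1]
    else:
        raise ValueError(f"direction must be rising/falling, got {direction!r}")
    dv = v[i + 1] - v[i]
    frac = 0.0 if dv == 0 else (level - v[i]) / dv
    return float(t[i] + frac * (t[i + 1] - t[i])), None


def _smooth(x: np.ndarray, fs: float, span_s: float) -> np.ndarray:
    w = int(round(span_s * fs))
    w = max(5, w + (w + 1) % 2)  # odd, >= 5
    if w >= len(x):
        return x.astype(float)
    return savgol_filter(x, w, 2)


def _noise_sd(x: np.ndarray) -> float:
    """Robust noise SD from first differences (insensitive to the waveform)."""
    d = np.diff(x)
    if len(d) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)


def _slice(trace: np.ndarray, fs: float, t0: float, t1: float):
    i0 = max(0, int(round(t0 * fs)))
    i1 = min(len(trace), int(round(t1 * fs)) + 1)
    idx = np.arange(i0, i1)
    return idx / fs, trace[idx]


def _interp_at(t: np.ndarray, v: np.ndarray, time: float) -> float:
    return float(np.interp(time, t, v))


def _refine_extremum(x: np.ndarray, idx: int, half: int, mode: str) -> int:
    """Sharpen an extremum located on the smoothed trace.

    Smoothing shifts an extremum that sits between segments of unequal
    curvature; the unsmoothed extremum within +- half a smoothing window of
    the candidate removes that bias.
    """
    lo = max(0, idx - half)
    hi = min(len(x), idx + half + 1)
    seg = x[lo:hi]
    off = int(np.argmax(seg)) if mode == "max" else int(np.argmin(seg))
    return lo + off


# ---------------------------------------------------------------------------
# FP extraction
# ---------------------------------------------------------------------------


def extract_fp_points(
    recording: Recording,
    event: BeatEvent,
    smooth_span: float = 0.0015,
    baseline_window: float = 0.050,
) -> FPPoints:
    """Localize E1–E8 for one detected FP beat.

    E3 is the window maximum near the anchor; E4 the first prominent minimum
    after E3; E6 the first prominent maximum after E4; E8 the first prominent
    minimum after E6, falling back to the 90%-return-to-baseline crossing
    when the second wave has no distinct valley.  E1/E2 (and E5, E7) come
    from fractional edge crossings.  The pre-onset baseline is the median of
    a 50 ms window just before the rising-edge onset (the last crossing of
    baseline + 5% amplitude before E3).
    """
    fs = recording.fs_fp
    t, x = _slice(recording.fp, fs, event.window_start, event.window_end)
    if event.polarity_flipped:
        x = -x
    out = FPPoints()
    if len(x) < 10:
        out.missing = {n: "window_too_short" for n in FP_POINT_NAMES}
        return out
    xs = _smooth(x, fs, smooth_span)
    sd = _noise_sd(x)
    half = max(2, int(round(smooth_span * fs)) // 2)

    # E3: refine the detector's anchor on the smoothed trace
    m = (t >= event.anchor_time - 0.01) & (t <= event.anchor_time + 0.01)
    if not np.any(m):
        m = np.ones_like(t, dtype=bool)
    i_e3 = np.flatnonzero(m)[0] + int(np.argmax(xs[m]))
    i_e3 = _refine_extremum(x, i_e3, half, "max")
    t_e3 = t[i_e3]

    # pre-onset baseline, iterated once through the 5%-amplitude onset
    pre = xs[t < t_e3]
    if len(pre) < 3:
        out.missing = {n: "no_pre_window" for n in FP_POINT_NAMES}
        return out
    base = float(np.median(pre))
    for _ in range(2):
        amp = xs[i_e3] - base
        if amp <= 0:
            out.missing = {n: "no_rising_edge" for n in FP_POINT_NAMES}
            return out
        below = np.flatnonzero(xs[:i_e3] <= base + 0.05 * amp)
        if len(below) == 0:
            break
        onset_t = t[below[-1]]
        bw = xs[(t >= onset_t - baseline_window) & (t < onset_t)]
        if len(bw) >= 3:
            base = float(np.median(bw))
    out.baseline = base
    amp = xs[i_e3] - base

    out.times["E3"] = t_e3
    out.values["E3"] = float(xs[i_e3])

    # E1, E2: fractional crossings on the rising edge (baseline -> E3)
    rise_t, rise_v = t[: i_e3 + 1], xs[: i_e3 + 1]
    for name, frac in (("E1", 0.10), ("E2", 0.50)):
        tt, reason = edge_crossing(rise_t, rise_v, base, xs[i_e3], frac, "rising")
        if reason is None:
            out.times[name] = tt
            out.values[name] = base + frac * amp
        else:
            out.missing[name] = reason

    floor = max(5.0 * sd, 1e-4)

    # E4: the valley is the global minimum after E3 (always deeper than the
    # second wave's terminal undershoot for any physiological amplitude mix)
    i_e4 = _refine_extremum(x, i_e3 + int(np.argmin(xs[i_e3:])), half, "min")
    if xs[i_e4] >= base - max(3.0 * sd, 0.02 * amp):
        for name in ("E4", "E5", "E6", "E7", "E8"):
            out.missing[name] = "no_valley"
        return out
    out.times["E4"] = t[i_e4]
    out.values["E4"] = float(xs[i_e4])

    # E6: the second peak is the global maximum after the valley; it must
    # clear the baseline by more than the noise floor to count as present
    if i_e4 + 2 >= len(xs):
        for name in ("E5", "E6", "E7", "E8"):
            out.missing[name] = "second_wave_absent"
        return out
    i_e6 = _refine_extremum(x, i_e4 + 2 + int(np.argmax(xs[i_e4 + 2 :])), half, "max")
    if xs[i_e6] - base <= floor:
        for name in ("E5", "E6", "E7", "E8"):
            out.missing[name] = "second_wave_absent"
        return out
    out.times["E6"] = t[i_e6]
    out.values["E6"] = float(xs[i_e6])

    # E5: 50% of the second rising edge (E4 -> E6)
    tt, reason = edge_crossing(
        t[i_e4 : i_e6 + 1], xs[i_e4 : i_e6 + 1], xs[i_e4], xs[i_e6], 0.50, "rising"
    )
    if reason is None:
        out.times["E5"] = tt
        out.values["E5"] = float(xs[i_e4] + 0.5 * (xs[i_e6] - xs[i_e4]))
    else:
        out.missing["E5"] = reason

    # E8: first prominent minimum after E6; fallback = the first crossing of
    # 90% return to baseline (a return detector, not an edge fraction, so
    # the earliest crossing is the right boundary under noise)
    post3 = xs[i_e6:]
    mins2, _ = find_peaks(-post3, prominence=floor)
    if len(mins2) > 0:
        i_e8 = _refine_extremum(x, i_e6 + mins2[0], half, "min")
        out.times["E8"] = t[i_e8]
        out.values["E8"] = float(xs[i_e8])
    else:
        level_frac = xs[i_e6] - 0.90 * (xs[i_e6] - base)
        drops = np.flatnonzero((post3[:-1] >= level_frac) & (post3[1:] < level_frac))
        if len(drops):
            i = i_e6 + drops[0]
            dv = xs[i + 1] - xs[i]
            fr = 0.0 if dv == 0 else (level_frac - xs[i]) / dv
            out.times["E8"] = float(t[i] + fr * (t[i + 1] - t[i]))
            out.values["E8"] = level_frac
        else:
            out.missing["E8"] = "second_valley_absent"

    # E7: 50% of the second falling edge (E6 -> E8)
    if "E8" in out.times:
        seg = (t >= out.times["E6"]) & (t <= out.times["E8"] + 1.0 / fs)
        tt, reason = edge_crossing(
            t[seg], xs[seg], out.values["E6"], out.values["E8"], 0.50, "falling"
        )
        if reason is None:
            out.times["E7"] = tt
            out.values["E7"] = out.values["E6"] + 0.5 * (
                out.values["E8"] - out.values["E6"]
            )
        else:
            out.missing["E7"] = reason
    else:
        out.missing["E7"] = "second_valley_absent"
    return out


# ---------------------------------------------------------------------------
# MB extraction
# ---------------------------------------------------------------------------


def extract_mb_points(
    recording: Recording,
    event: BeatEvent,
    smooth_span: float = 0.015,
    baseline_window: float = 0.200,
    min_amplitude_sd: float = 6.0,
) -> MBPoints:
    """Localize M1–M5 for one detected MB beat.

    M3 is the window maximum near the anchor; M1/M2 are rising crossings of
    10%/50% of (peak − pre-onset baseline); M4/M5 are falling crossings of
    50%/90% of (peak − post-beat baseline).  A bump whose amplitude does not
    clear ``min_amplitude_sd`` noise SDs is reported entirely missing.
    """
    fs = recording.fs_mb
    t, x = _slice(recording.mb, fs, event.window_start, event.window_end)
    if event.polarity_flipped:
        x = -x
    out = MBPoints()
    if len(x) < 10:
        out.missing = {n: "window_too_short" for n in MB_POINT_NAMES}
        return out
    xs = _smooth(x, fs, smooth_span)
    sd = _noise_sd(x)
    half = max(2, int(round(smooth_span * fs)) // 2)

    m = (t >= event.anchor_time - 0.03) & (t <= event.anchor_time + 0.03)
    if not np.any(m):
        m = np.ones_like(t, dtype=bool)
    i_m3 = np.flatnonzero(m)[0] + int(np.argmax(xs[m]))
    i_m3 = _refine_extremum(x, i_m3, half, "max")
    t_m3 = t[i_m3]

    # pre-onset baseline from the early 40% of the pre-peak window, then
    # refined through the 5%-amplitude onset crossing
    n_pre = int(0.4 * i_m3)
    if n_pre < 3:
        out.missing = {n: "no_pre_window" for n in MB_POINT_NAMES}
        return out
    base = float(np.median(xs[:n_pre]))
    for _ in range(2):
        amp = xs[i_m3] - base
        if amp <= 0:
            out.missing = {n: "bump_below_noise" for n in MB_POINT_NAMES}
            return out
        below = np.flatnonzero(xs[:i_m3] <= base + 0.05 * amp)
        if len(below) == 0:
            break
        onset_t = t[below[-1]]
        bw = xs[(t >= onset_t - baseline_window) & (t < onset_t)]
        if len(bw) >= 3:
            base = float(np.median(bw))
    amp = xs[i_m3] - base
    if amp <= max(min_amplitude_sd * sd, 1e-9):
        out.missing = {n: "bump_below_noise" for n in MB_POINT_NAMES}
        return out
    out.baseline = base
    out.times["M3"] = t_m3
    out.values["M3"] = float(xs[i_m3])

    rise_t, rise_v = t[: i_m3 + 1], xs[: i_m3 + 1]
    for name, frac in (("M1", 0.10), ("M2", 0.50)):
        tt, reason = edge_crossing(rise_t, rise_v, base, xs[i_m3], frac, "rising")
        if reason is None:
            out.times[name] = tt
            out.values[name] = base + frac * amp
        else:
            out.missing[name] = reason

    # post-beat baseline: median of the last quarter of the window
    n_post = len(x) - int(0.75 * (len(x) - i_m3)) - i_m3
    tail = xs[-max(3, (len(x) - i_m3) // 4) :]
    post_base = float(np.median(tail))
    fall_t, fall_v = t[i_m3:], xs[i_m3:]
    for name, frac in (("M4", 0.50), ("M5", 0.90)):
        tt, reason = edge_crossing(
            fall_t, fall_v, xs[i_m3], post_base, frac, "falling"
        )
        if reason is None:
            out.times[name] = tt
            out.values[name] = xs[i_m3] + frac * (post_base - xs[i_m3])
        else:
            out.missing[name] = reason
    return out


# ---------------------------------------------------------------------------
# pairing and parameters
# ---------------------------------------------------------------------------


def pair_beats(
    fp_events: Sequence[BeatEvent],
    mb_events: Sequence[BeatEvent],
    max_lag: float = 0.5,
):
    """Greedy nearest-forward matching of FP beats to MB beats.

    Each FP beat takes the earliest unpaired MB beat whose peak follows the
    FP fast-spike peak by at most ``max_lag`` seconds (excitation precedes
    contraction).  Returns ``(pairs, unpaired_fp, unpaired_mb)`` where pairs
    is a list of ``(fp_event, mb_event)``.
    """
    pairs = []
    unpaired_fp = []
    used = [False] * len(mb_events)
    j = 0
    for fe in fp_events:
        match = None
        for k in range(j, len(mb_events)):
            if used[k]:
                continue
            lag = mb_events[k].anchor_time - fe.anchor_time
            if lag < 0:
                continue
            if lag > max_lag:
                break
            match = k
            break
        if match is None:
            unpaired_fp.append(fe)
        else:
            used[match] = True
            j = match
            pairs.append((fe, mb_events[match]))
    unpaired_mb = [e for e, u in zip(mb_events, used) if not u]
    return pairs, unpaired_fp, unpaired_mb


def _dur(points, a: str, b: str) -> float:
    ta, tb = points.time(a), points.time(b)
    return tb - ta


def compute_feature_vector(
    pair: BeatPair, prev_pair: Optional[BeatPair] = None
) -> dict:
    """The 36 named parameters (plus E6E8_slope) for one beat; NaN = missing."""
    fp = pair.fp_points
    mb = pair.mb_points
    out = {name: float("nan") for name in ALL_PARAMS + OPTIONAL_PARAMS}

    if prev_pair is not None:
        iv = fp.time("E3") - prev_pair.fp_points.time("E3")
        out["firing_interval"] = iv
        if iv and not math.isnan(iv) and iv > 0:
            out["firing_rate"] = 60.0 / iv
        if mb is not None and prev_pair.mb_points is not None:
            biv = mb.time("M3") - prev_pair.mb_points.time("M3")
            out["beating_interval"] = biv
            if biv and not math.isnan(biv) and biv > 0:
                out["beating_rate"] = 60.0 / biv

    out["first_amplitude"] = fp.value("E3") - fp.value("E4")
    out["second_amplitude"] = fp.value("E6") - fp.value("E8")
    for name in ("E1E8", "E1E3", "E2E3", "E3E4", "E4E8", "E4E6", "E6E7", "E6E8"):
        out[name] = _dur(fp, name[:2], name[2:])
    d68 = out["E6E8"]
    if d68 and not math.isnan(d68) and d68 > 0:
        out["E6E8_slope"] = (fp.value("E8") - fp.value("E6")) / d68

    if mb is not None:
        out["beating_amplitude"] = mb.value("M3") - mb.baseline
        for name in ("M1M5", "M1M2", "M1M3", "M2M3", "M3M4"):
            out[name] = _dur(mb, name[:2], name[2:])
        for name in FPMB_PARAMS:
            out[name] = mb.time(name[2:]) - fp.time(name[:2])
    return out


def summarize_epoch(vectors: Sequence[dict] | pd.DataFrame) -> pd.DataFrame:
    """Per-parameter mean, SD and n over the beats of one epoch.

    SD uses ddof=1 and is 0 by convention when only one beat carries the
    parameter.  Raises on an empty input.
    """
    if isinstance(vectors, pd.DataFrame):
        df = vectors
    else:
        df = pd.DataFrame(list(vectors))
    if len(df) == 0:
        raise ValueError("summarize_epoch needs at least one feature vector")
    cols = [c for c in ALL_PARAMS + OPTIONAL_PARAMS if c in df.columns]
    rows = []
    for c in cols:
        vals = df[c].dropna()
        n = len(vals)
        mean = float(vals.mean()) if n else float("nan")
        sd = float(vals.std(ddof=1)) if n > 1 else (0.0 if n == 1 else float("nan"))
        rows.append({"parameter": c, "mean": mean, "sd": sd, "n": n})
    return pd.DataFrame(rows).set_index("parameter")
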