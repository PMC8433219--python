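"""Readers and writers for recordings, events and feature tables.

Everything is flat delimited text (CSV/TSV) with a JSON sidecar for
structured metadata, chosen for bit-exact diffing in tests.  A recording is
either one CSV with columns ``time_s, fp_uV, mb_ohm`` (MB resampled onto
the FP clock) or a split pair of per-modality files; the sidecar records
which, plus sampling rates, metadata and any simulator ground truth.
"""

from __future__ import annotations

import json
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import BeatEvent
from .synth import Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_feature_table",
    "read_feature_table",
]

_MAX_TIME_JITTER = 1e-6  # s, max deviation from a uniform clock


class RecordingParseError(ValueError):
    pass


def write_recording(rec: Recording, basepath: str, split: bool = True) -> str:
    """Write a recording plus its JSON sidecar; returns the sidecar path.

    ``split=True`` writes ``<base>_fp.csv``/``<base>_mb.csv`` (exact
    round trip at native rates); ``split=False`` writes one
    ``<base>.csv`` with the MB trace linearly resampled onto the FP clock.
    """
    base, _ = os.path.splitext(basepath)
    files = {}
    if split:
        for tag, t, v, col in (
            ("fp", rec.fp_time, rec.fp, "fp_uV"),
            ("mb", rec.mb_time, rec.mb, "mb_ohm"),
        ):
            path = f"{base}_{tag}.csv"
            pd.DataFrame({"time_s": t, col: v}).to_csv(
                path, index=False, float_format="%.17g"
            )
            files[tag] = os.path.basename(path)
    else:
        t = rec.fp_time
        mb_on_fp = np.interp(t, rec.mb_time, rec.mb)
        path = f"{base}.csv"
        pd.DataFrame({"time_s": t, "fp_uV": rec.fp, "mb_ohm": mb_on_fp}).to_csv(
            path, index=False, float_format="%.17g"
        )
        files["combined"] = os.path.basename(path)
    sidecar = {
        "format": "cardioems-recording-v1",
        "split": split,
        "files": files,
        "fs_fp": rec.fs_fp,
        "fs_mb": rec.fs_mb if split else rec.fs_fp,
        "metadata": rec.metadata,
        "ground_truth": rec.ground_truth,
    }
    sidecar_path = f"{base}.json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return sidecar_path


def _validate_time(time_s: np.ndarray, fs: float, path: str) -> None:
    if len(time_s) < 2:
        return
    dt = np.diff(time_s)
    bad = np.flatnonzero(dt <= 0)
    if len(bad):
        raise RecordingParseError(
            f"{path}: non-monotone time at line {bad[0] + 2}"
        )
    jitter = np.abs(time_s - np.arange(len(time_s)) / fs - time_s[0])
    worst = int(np.argmax(jitter))
    if jitter[worst] > _MAX_TIME_JITTER:
        raise RecordingParseError(
            f"{path}: timestamp at line {worst + 2} deviates "
            f"{jitter[worst]:.3g} s from a uniform {fs} Hz clock"
        )


def _read_columns(path: str, required: Sequence[str]) -> pd.DataFrame:
    # round_trip parsing: written values must come back bit-identical
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordingParseError(f"{path}: missing column(s) {missing}")
    return df


def read_recording(sidecar_path: str) -> Recording:
    """Load a recording written by :func:`write_recording`, with validation."""
    with open(sidecar_path) as fh:
        sc = json.load(fh)
    d = os.path.dirname(os.path.abspath(sidecar_path))
    fs_fp, fs_mb = float(sc["fs_fp"]), float(sc["fs_mb"])
    if sc.get("split", False):
        fp_df = _read_columns(os.path.join(d, sc["files"]["fp"]), ["time_s", "fp_uV"])
        mb_df = _read_columns(os.path.join(d, sc["files"]["mb"]), ["time_s", "mb_ohm"])
        _validate_time(fp_df["time_s"].to_numpy(), fs_fp, sc["files"]["fp"])
        _validate_time(mb_df["time_s"].to_numpy(), fs_mb, sc["files"]["mb"])
        fp = fp_df["fp_uV"].to_numpy()
        mb = mb_df["mb_ohm"].to_numpy()
    else:
        df = _read_columns(
            os.path.join(d, sc["files"]["combined"]), ["time_s", "fp_uV", "mb_ohm"]
        )
        _validate_time(df["time_s"].to_numpy(), fs_fp, sc["files"]["combined"])
        fp = df["fp_uV"].to_numpy()
        mb = df["mb_ohm"].to_numpy()
    return Recording(
        fp=fp,
        mb=mb,
        fs_fp=fs_fp,
        fs_mb=fs_mb,
        metadata=sc.get("metadata") or {},
        ground_truth=sc.get("ground_truth"),
    )


_EVENT_COLS = ["channel", "kind", "anchor_time_s", "window_start_s", "window_end_s"]


def write_events(events: Sequence[BeatEvent], path: str) -> None:
    rows = [
        {
            "channel": e.channel,
            "kind": e.signal_kind,
            "anchor_time_s": e.anchor_time,
            "window_start_s": e.window_start,
            "window_end_s": e.window_end,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_events(path: str) -> list[BeatEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        BeatEvent(
            anchor_time=r.anchor_time_s,
            window_start=r.window_start_s,
            window_end=r.window_end_s,
            channel=int(r.channel),
            signal_kind=r.kind,
        )
        for r in df.itertuples()
    ]


def write_feature_table(df: pd.DataFrame, path: str) -> None:
    """Beat-level (or summary) feature table as TSV; missing cells stay empty."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="")


def read_feature_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
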