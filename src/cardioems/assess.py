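"""Dose-quantitative, time-dependent, stability and visual drug assessment.

All operations consume tidy beat-level or summary tables (pandas DataFrames
whose columns are the feature-parameter names plus metadata columns such as
``channel``, ``concentration`` and ``time_min``) and express drug effects as
signed percent change against the pre-dose vehicle baseline — the standard
effect metric for multi-well cardiomyocyte assays.  The replicate unit is
the channel (well); channel means are aggregated before percent change, and
the spread reported is the SD of per-channel paired percent changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import ALL_PARAMS, FP_PARAMS, FPMB_PARAMS, MB_PARAMS

__all__ = [
    "ConditionSummary",
    "DoseResponseTable",
    "FluctuationResult",
    "percent_change",
    "condition_summaries",
    "fluctuation_metric",
    "dose_response_table",
    "time_course_table",
    "heatmap_matrix",
    "HeatmapMatrix",
    "radar_data",
    "LIDOCAINE_VISUALIZED_PARAMS",
    "LIDOCAINE_TIME_PARAMS",
]

#: the lidocaine heat-map parameter set: 2 FP + 3 MB + 6 FP-MB parameters
LIDOCAINE_VISUALIZED_PARAMS = (
    "second_amplitude",
    "E4E6",
    "beating_amplitude",
    "M1M3",
    "M2M3",
    "E1M2",
    "E1M3",
    "E1M4",
    "E4M2",
    "E4M3",
    "E4M4",
)
#: the lidocaine time-dependent set adds E3E4 (3 FP + 3 MB + 6 FP-MB = 12)
LIDOCAINE_TIME_PARAMS = ("E3E4",) + LIDOCAINE_VISUALIZED_PARAMS


def percent_change(baseline: float, treated: float):
    """Signed percent change ``100 * (treated - baseline) / baseline``.

    Returns ``(value, None)`` or ``(nan, reason)`` for a zero or missing
    baseline (missingness is data, not an error).
    """
    if baseline is None or (isinstance(baseline, float) and math.isnan(baseline)):
        return float("nan"), "missing_baseline"
    if treated is None or (isinstance(treated, float) and math.isnan(treated)):
        return float("nan"), "missing_treated"
    if baseline == 0:
        return float("nan"), "zero_baseline"
    return 100.0 * (treated - baseline) / baseline, None


def _pc(baseline, treated) -> float:
    return percent_change(baseline, treated)[0]


@dataclass
class ConditionSummary:
    """Across-channel summary of one condition (drug, concentration, time)."""

    key: dict
    means: pd.Series  # per-parameter across-channel mean of channel means
    sds: pd.Series
    n: pd.Series  # channels contributing per parameter


@dataclass
class FluctuationResult:
    max_abs_percent: float
    table: pd.DataFrame  # parameters x timepoints, signed percent change
    excluded: list = field(default_factory=list)


@dataclass
class DoseResponseTable:
    """Per-parameter percent change vs baseline across an ordered dose grid."""

    percent: pd.DataFrame  # parameters x doses
    sd: pd.DataFrame  # SD of per-channel percent changes
    n: pd.DataFrame
    monotone: pd.Series  # per-parameter: '+', '-' or '' (Spearman sign)
    axis_name: str = "concentration"


@dataclass
class HeatmapMatrix:
    values: pd.DataFrame  # parameters x conditions; NaN = explicit missing
    normalization: str
    flagged: list = field(default_factory=list)  # degenerate (zero-variance) rows


def _channel_means(
    beats: pd.DataFrame, params: Sequence[str], group_cols: Sequence[str]
) -> pd.DataFrame:
    cols = [c for c in params if c in beats.columns]
    return beats.groupby(list(group_cols), dropna=False)[cols].mean().reset_index()


def condition_summaries(
    beats: pd.DataFrame,
    params: Sequence[str] = ALL_PARAMS,
    condition_cols: Sequence[str] = ("drug", "concentration", "time_min"),
    channel_col: str = "channel",
) -> list[ConditionSummary]:
    """Mean ± SD per parameter per condition, with the channel as replicate."""
    params = [c for c in params if c in beats.columns]
    per_ch = _channel_means(beats, params, list(condition_cols) + [channel_col])
    out = []
    for key, grp in per_ch.groupby(list(condition_cols), dropna=False):
        key_d = dict(zip(condition_cols, key if isinstance(key, tuple) else (key,)))
        out.append(
            ConditionSummary(
                key=key_d,
                means=grp[params].mean(),
                sds=grp[params].std(ddof=1),
                n=grp[params].notna().sum(),
            )
        )
    return out


def fluctuation_metric(
    beats: pd.DataFrame,
    params: Sequence[str],
    time_col: str = "time_min",
    baseline_time: float = 0.0,
    channel_col: str = "channel",
) -> FluctuationResult:
    """Maximum absolute percent change over timepoints and parameters.

    The standard stability statistic for vehicle-control studies: channel
    means are aggregated per timepoint, each post-baseline timepoint is
    expressed as percent change against the baseline timepoint, and the
    maximum absolute value over the parameter set is reported.  Parameters
    missing everywhere are excluded (and listed), not imputed.
    """
    params = [c for c in params if c in beats.columns]
    times = sorted(t for t in beats[time_col].dropna().unique())
    if baseline_time not in times or len(times) < 2:
        raise ValueError("need a baseline timepoint and at least one other")
    per_ch = _channel_means(beats, params, [time_col, channel_col])
    agg = per_ch.groupby(time_col)[params].mean()
    excluded = [p for p in params if agg[p].isna().all()]
    rows = {}
    for p in params:
        if p in excluded:
            continue
        base = agg.loc[baseline_time, p]
        rows[p] = {
            t: _pc(base, agg.loc[t, p]) for t in times if t != baseline_time
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    max_abs = float(np.nanmax(np.abs(table.to_numpy()))) if len(table) else float("nan")
    if excluded:
        warnings.warn(f"fluctuation_metric: all-missing parameters {excluded}")
    return FluctuationResult(max_abs_percent=max_abs, table=table, excluded=excluded)


def _response_table(
    beats: pd.DataFrame,
    params: Sequence[str],
    axis_col: str,
    baseline_value: float,
    channel_col: str,
    axis_values: Optional[Sequence[float]] = None,
) -> DoseResponseTable:
    params = [c for c in params if c in beats.columns]
    present = sorted(v for v in beats[axis_col].dropna().unique())
    if axis_values is None:
        axis_values = [v for v in present if v != baseline_value]
    missing_axis = [v for v in axis_values if v not in present]
    if missing_axis or baseline_value not in present:
        gaps = missing_axis + ([baseline_value] if baseline_value not in present else [])
        raise ValueError(f"missing {axis_col} levels in the data: {gaps}")

    per_ch = _channel_means(beats, params, [axis_col, channel_col])
    agg = per_ch.groupby(axis_col)[params].mean()
    base_ch = per_ch[per_ch[axis_col] == baseline_value].set_index(channel_col)

    pc_mean = pd.DataFrame(index=params, columns=list(axis_values), dtype=float)
    pc_sd = pd.DataFrame(index=params, columns=list(axis_values), dtype=float)
    n_tab = pd.DataFrame(index=params, columns=list(axis_values), dtype=float)
    for v in axis_values:
        lvl_ch = per_ch[per_ch[axis_col] == v].set_index(channel_col)
        for p in params:
            pc_mean.loc[p, v] = _pc(agg.loc[baseline_value, p], agg.loc[v, p])
            paired = [
                _pc(base_ch.loc[ch, p], lvl_ch.loc[ch, p])
                for ch in lvl_ch.index
                if ch in base_ch.index
            ]
            paired = [x for x in paired if not math.isnan(x)]
            pc_sd.loc[p, v] = float(np.std(paired, ddof=1)) if len(paired) > 1 else 0.0
            n_tab.loc[p, v] = len(paired)

    monotone = pd.Series("", index=params, dtype=object)
    if len(axis_values) >= 3:
        for p in params:
            row = pc_mean.loc[p].to_numpy(dtype=float)
            if np.isnan(row).any():
                continue
            rho = stats.spearmanr(np.asarray(axis_values, float), row).statistic
            if rho >= 1.0 - 1e-9:
                monotone[p] = "+"
            elif rho <= -1.0 + 1e-9:
                monotone[p] = "-"
    return DoseResponseTable(
        percent=pc_mean, sd=pc_sd, n=n_tab, monotone=monotone, axis_name=axis_col
    )


def dose_response_table(
    beats: pd.DataFrame,
    params: Sequence[str] = ALL_PARAMS,
    dose_col: str = "concentration",
    baseline_dose: float = 0.0,
    doses: Optional[Sequence[float]] = None,
    channel_col: str = "channel",
) -> DoseResponseTable:
    """Percent change vs the vehicle baseline across an ordered dose series."""
    return _response_table(beats, params, dose_col, baseline_dose, channel_col, doses)


def time_course_table(
    beats: pd.DataFrame,
    params: Sequence[str] = ALL_PARAMS,
    time_col: str = "time_min",
    baseline_time: float = 0.0,
    timepoints: Optional[Sequence[float]] = None,
    channel_col: str = "channel",
) -> DoseResponseTable:
    """Percent change vs the pre-dose baseline across timepoints at fixed dose."""
    return _response_table(beats, params, time_col, baseline_time, channel_col, timepoints)


def heatmap_matrix(
    table: DoseResponseTable | pd.DataFrame, normalization: str = "percent"
) -> HeatmapMatrix:
    """Parameter x condition drug-fingerprint matrix.

    ``percent`` keeps the signed percent changes; ``zscore`` standardizes
    each parameter row.  Missing cells (vanished parameters, e.g. the MB
    points at high Ca-blocker doses) stay missing; zero-variance rows under
    zscore become all-missing and are flagged.
    """
    values = (table.percent if isinstance(table, DoseResponseTable) else table).copy()
    flagged: list = []
    if normalization == "percent":
        pass
    elif normalization == "zscore":
        arr = values.to_numpy(dtype=float)
        mu = np.nanmean(arr, axis=1, keepdims=True)
        sd = np.nanstd(arr, axis=1, ddof=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            arr = np.where(sd > 0, (arr - mu) / sd, np.nan)
        flagged = [p for p, s in zip(values.index, sd.ravel()) if not s > 0]
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return HeatmapMatrix(values=values, normalization=normalization, flagged=flagged)


def radar_data(
    tables_by_timepoint: dict,
    params: Optional[Sequence[str]] = None,
) -> dict:
    """Min-max normalize each parameter across the dose series per timepoint.

    Input: ``{timepoint: DataFrame(parameters x doses)}`` (e.g. the
    ``percent`` members of per-timepoint dose-response tables).  Output has
    the same shape with every value scaled to [0, 1] within its parameter
    row; a parameter constant across doses is fixed at 0.5.
    """
    out = {}
    for tp, table in tables_by_timepoint.items():
        values = table.percent if isinstance(table, DoseResponseTable) else table
        if params is not None:
            missing = [p for p in params if p not in values.index]
            if missing:
                raise ValueError(f"radar parameters missing from table: {missing}")
            values = values.loc[list(params)]
        arr = values.to_numpy(dtype=float)
        lo = np.nanmin(arr, axis=1, keepdims=True)
        hi = np.nanmax(arr, axis=1, keepdims=True)
        span = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(span > 0, (arr - lo) / span, 0.5)
        out[tp] = pd.DataFrame(norm, index=values.index, columns=values.columns)
    return out
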