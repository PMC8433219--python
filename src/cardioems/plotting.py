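"""Figure rendering: drug-fingerprint heat maps and radar charts."""

from __future__ import annotations

import math

import numpy as np

from .assess import HeatmapMatrix

__all__ = ["plot_heatmap", "plot_radar", "plot_recording"]


def plot_heatmap(matrix: HeatmapMatrix, path: str, cmap: str = "RdBu_r"):
    """Render a parameter x condition heat map; missing cells stay blank."""
    import matplotlib.pyplot as plt

    values = matrix.values
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * values.shape[1], 1.0 + 0.35 * values.shape[0])
    )
    arr = values.to_numpy(dtype=float)
    vmax = np.nanmax(np.abs(arr)) if np.isfinite(arr).any() else 1.0
    im = ax.imshow(arr, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(values.shape[1]), [str(c) for c in values.columns])
    ax.set_yticks(range(values.shape[0]), list(values.index))
    fig.colorbar(im, ax=ax, label=matrix.normalization)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_radar(radar: dict, path: str):
    """One polar panel per timepoint, one line per dose, one axis per parameter."""
    import matplotlib.pyplot as plt

    tps = list(radar)
    fig, axes = plt.subplots(
        1,
        len(tps),
        figsize=(4.2 * len(tps), 4.2),
        subplot_kw={"projection": "polar"},
    )
    if len(tps) == 1:
        axes = [axes]
    for ax, tp in zip(axes, tps):
        table = radar[tp]
        n = table.shape[0]
        angles = [2 * math.pi * i / n for i in range(n)] + [0.0]
        for dose in table.columns:
            vals = table[dose].to_list()
            ax.plot(angles, vals + vals[:1], label=str(dose), linewidth=1.2)
        ax.set_xticks(angles[:-1], list(table.index), fontsize=7)
        ax.set_ylim(0, 1)
        ax.set_title(f"t = {tp} min", fontsize=9)
    axes[-1].legend(fontsize=7, loc="upper right", bbox_to_anchor=(1.35, 1.1))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_recording(rec, path: str, t0: float = 0.0, t1: float | None = None):
    """Stacked FP/MB trace view of one recording epoch."""
    import matplotlib.pyplot as plt

    t1 = t1 if t1 is not None else min(rec.duration, t0 + 5.0)
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(9, 4))
    tf, tm = rec.fp_time, rec.mb_time
    mf = (tf >= t0) & (tf <= t1)
    mm = (tm >= t0) & (tm <= t1)
    ax1.plot(tf[mf], rec.fp[mf], lw=0.5, color="crimson")
    ax1.set_ylabel("FP (µV)")
    ax2.plot(tm[mm], rec.mb[mm], lw=0.8, color="seagreen")
    ax2.set_ylabel("MB (Ω)")
    ax2.set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
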