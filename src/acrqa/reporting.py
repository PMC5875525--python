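"""Trend plots: per-metric time series with baseline segments.

Each plot shows the metric over sessions, a ±1 SD band per baseline
segment around the segment mean, and vertical markers where the
baseline was reset (maintenance / recalibration / tube replacement).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .qa_program import MeasurementHistory

__all__ = ["plot_trends"]


def plot_trends(
    history: MeasurementHistory | pd.DataFrame,
    out_dir,
    metrics: list[str] | None = None,
) -> list[Path]:
    """One PNG per metric; separate lines per (machine, protocol).

    Returns the written paths; empty histories raise.
    """
    df = history.df if isinstance(history, MeasurementHistory) else history
    if df.empty:
        raise ValueError("empty history: nothing to plot")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for metric in metrics or sorted(df["metric"].unique()):
        sub = df[df["metric"] == metric]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(7, 4))
        for (machine, protocol), grp in sub.groupby(["machine", "protocol"], sort=False):
            grp = grp.sort_values("date", kind="stable").reset_index(drop=True)
            x = range(len(grp))
            ax.plot(x, grp["value"], marker="o", label=f"{machine} / {protocol}")
            for seg, seg_grp in grp.groupby("segment"):
                if len(seg_grp) >= 2:
                    mean = seg_grp["value"].mean()
                    sd = seg_grp["value"].std(ddof=1)
                    ax.fill_between(
                        [seg_grp.index.min(), seg_grp.index.max()],
                        mean - sd,
                        mean + sd,
                        alpha=0.15,
                    )
            boundaries = grp.index[grp["segment"].diff() > 0]
            for b in boundaries:
                ax.axvline(b - 0.5, color="k", linestyle="--", linewidth=1)
        ax.set_xlabel("session")
        ax.set_ylabel(metric)
        ax.set_title(f"{metric} over time (dashed = baseline reset)")
        ax.legend(fontsize=7)
        path = out / f"trend_{metric}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
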