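"""Optional figures: ratio box plots and dose-response curves.

Matplotlib is imported lazily and the Agg backend is forced, so plotting
works headless and costs nothing when unused.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_ratio_boxes(records: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    """Box plot of fit/measured integral ratios per peak function.

    One box per function kind over the converged fits; the optimal ratio
    1.0 is marked with a dashed line, means with dotted markers.
    """
    plt = _pyplot()
    ok = records[records.status == "converged"]
    kinds = sorted(ok.kind.unique())
    data = [ok[ok.kind == k].ratio.to_numpy() for k in kinds]
    fig, ax = plt.subplots(figsize=(1.6 * max(len(kinds), 2) + 1, 4))
    ax.boxplot(data, tick_labels=kinds, showmeans=True, meanline=True)
    ax.axhline(1.0, linestyle="--", color="green", linewidth=1)
    ax.set_ylabel("integral ratio (fit / measured)")
    if title:
        ax.set_title(title)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_dose_response(
    series: pd.DataFrame,
    fits: dict,
    path: str | Path,
) -> Path:
    """Normalized responses versus log dose with fitted 5PL curves.

    ``series`` is a (dose, mean_response, ci95_half) table; ``fits`` maps a
    label to a converged :class:`~halofit.doseresponse.DoseResponseFit`.
    Error bars show the 95 % CIs of the per-dose means.
    """
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(
        series.dose, series.mean_response,
        yerr=series.ci95_half.fillna(0.0) if hasattr(series.ci95_half, "fillna")
        else series.ci95_half,
        fmt="o", markersize=4, capsize=3, label="data",
    )
    grid = np.geomspace(series.dose.min(), series.dose.max(), 200)
    for label, fit in fits.items():
        ax.plot(grid, fit.predict(grid), "--", label=label)
    ax.set_xscale("log")
    ax.set_xlabel("dose")
    ax.set_ylabel("normalized response")
    ax.legend()
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
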