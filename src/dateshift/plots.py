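"""Figure helpers for the trade-off report.

All functions return a matplotlib Figure and never call ``show()``; use
``fig.savefig(...)`` to export SVG/PNG.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_weekly_series(series_by_label: dict[str, np.ndarray], title: str = ""):
    """Overlay weekly admission-count series (one line per scheme/Δt)."""
    fig, ax = plt.subplots(figsize=(8, 4))
    for label, series in series_by_label.items():
        ax.plot(np.arange(len(series)), series, label=label, lw=1.2)
    ax.set_xlabel("week")
    ax.set_ylabel("weekly admissions")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_km_curves(curves_by_label: dict[str, pd.DataFrame], title: str = "Kaplan-Meier"):
    """Overlay Kaplan-Meier step curves (columns: time, survival)."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for label, curve in curves_by_label.items():
        ax.step(curve["time"], curve["survival"], where="post", label=label, lw=1.2)
    ax.set_xlabel("days since diagnosis")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_uniqueness_heatmap(matrix: pd.DataFrame, title: str = "Uniqueness"):
    """Heatmap of the (Δt, Δt_birth) uniqueness matrix."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    ax.set_xlabel(matrix.columns.name or "delta_t_birth")
    ax.set_ylabel(matrix.index.name or "delta_t")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="uniqueness")
    fig.tight_layout()
    return fig


def plot_minimisation_scatter(tradeoff: pd.DataFrame, title: str = "Success vs cohort size"):
    """Success rate vs cohort size, one marker shape per scheme.

    Expects the trade-off table of ``run_experiment`` filtered to the
    random-target scenario.
    """
    fig, ax = plt.subplots(figsize=(7, 5))
    markers = {"base": "o", "birth": "s", "stay": "^"}
    for scheme, grp in tradeoff.groupby("scheme"):
        ax.scatter(
            grp["n_cohort"],
            grp["p_success"],
            marker=markers.get(scheme, "x"),
            c=np.log10(grp["delta_t"] + 1),
            cmap="plasma",
            label=scheme,
            alpha=0.8,
        )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("cohort size")
    ax.set_ylabel("P(success)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
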