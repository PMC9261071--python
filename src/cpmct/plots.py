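"""Forest-plot visualization of the analysis.

One figure per run: panel (a) scatters the raw data colored by cluster so
the litter structure is visible, and one forest panel per contrast type
shows the simultaneous intervals with a solid zero line and dashed relevance
limits — the plot a scientist reads to decide whether a change point is
biologically relevant, not merely significant.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .dataio import ExpressionDataset
from .detect import ChangePointReport, RelevanceConfig

__all__ = ["plot_analysis"]


def _scatter_panel(ax, ds: ExpressionDataset) -> None:
    tp_idx = ds.timepoint_index() + 1
    clusters = ds.clusters
    cmap = plt.get_cmap("tab20")
    colors = {c: cmap(i % 20) for i, c in enumerate(clusters)}
    rng = np.random.default_rng(0)  # fixed jitter for reproducible figures
    jitter = rng.uniform(-0.18, 0.18, size=ds.n_obs)
    ax.scatter(
        tp_idx + jitter,
        ds.observations["value"],
        c=[colors[c] for c in ds.observations["cluster"]],
        s=14,
        alpha=0.8,
        linewidths=0,
    )
    ax.set_xticks(range(1, ds.n_timepoints + 1))
    ax.set_xticklabels(ds.timepoint_order, rotation=45, fontsize=7)
    ax.set_xlabel("time point")
    ax.set_ylabel("expression (analysis scale)")
    ax.set_title("a) data (colors = clusters)", loc="left", fontsize=9)


def _forest_panel(ax, report: ChangePointReport, cfg: RelevanceConfig, title: str) -> None:
    rows = report.rows
    y = np.arange(len(rows))[::-1]  # first contrast on top, table order
    ax.hlines(y, rows["lower"], rows["upper"], color="black", lw=1.2)
    ax.plot(rows["estimate"], y, "o", color="black", ms=3.5)
    ax.axvline(0.0, color="black", lw=0.8)
    ax.axvline(cfg.lower_limit, color="red", lw=0.8, ls="--")
    ax.axvline(cfg.upper_limit, color="red", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(rows["label"], fontsize=7)
    ax.set_xlabel("effect estimate")
    ax.set_title(title, loc="left", fontsize=9)


def plot_analysis(
    ds: ExpressionDataset,
    reports: dict[str, ChangePointReport],
    cfg: RelevanceConfig | None = None,
    path=None,
):
    """Data scatter plus one CI forest panel per contrast type.

    ``reports`` maps contrast type to its classified report; panels appear
    in the order changepoint, sequen, mcdermott (those present). When
    ``path`` is given the figure is saved and closed, otherwise returned.
    """
    cfg = cfg or RelevanceConfig()
    order = [t for t in ("changepoint", "sequen", "mcdermott") if t in reports]
    n_panels = 1 + len(order)
    ncols = 2
    nrows = (n_panels + 1) // 2
    fig, axes = plt.subplots(nrows, ncols, figsize=(9, 3.6 * nrows))
    axes = np.atleast_1d(axes).ravel()
    _scatter_panel(axes[0], ds)
    panel_letters = "bcd"
    for i, ctype in enumerate(order):
        _forest_panel(
            axes[i + 1], reports[ctype], cfg, f"{panel_letters[i]}) {ctype} contrast"
        )
    for ax in axes[n_panels:]:
        ax.set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
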