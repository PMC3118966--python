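"""MA-plot diagnostics."""

from __future__ import annotations

import numpy as np

from .normalization import DEFAULT_DEGREE, DEFAULT_SPAN, MAArray, composite_weight, fit_loess
from .restriction import ControlProbeSet


def ma_plot(
    ma: MAArray,
    controls: ControlProbeSet | None = None,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    ax=None,
):
    """MA plot of one array with the three LOESS normalization curves.

    Biological probes are drawn grey, internal control probes red; the
    global (blue), control (red) and composite (cyan) LOESS curves are
    overlaid where computable.  Returns the matplotlib Axes.
    """
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(7, 5))
    present = ma.present
    A, M = ma.A[present], ma.M[present]
    ax.scatter(A, M, s=2, c="0.6", alpha=0.4, linewidths=0, label="probes")
    grid = np.linspace(np.min(A), np.max(A), 200)
    f_all = fit_loess(A, M, span, degree)
    ax.plot(grid, f_all(grid), color="tab:blue", lw=2, label="global LOESS")
    if controls is not None:
        is_ctrl = np.isin(ma.probe_ids, list(controls.probe_ids)) & ma.present
        if is_ctrl.sum() >= 10:
            ax.scatter(ma.A[is_ctrl], ma.M[is_ctrl], s=6, c="tab:red", linewidths=0,
                       label="control probes")
            f_ctrl = fit_loess(ma.A[is_ctrl], ma.M[is_ctrl], span, degree)
            ax.plot(grid, f_ctrl(grid), color="tab:red", lw=2, label="control LOESS")
            a = composite_weight(grid, A)
            ax.plot(grid, a * f_ctrl(grid) + (1 - a) * f_all(grid), color="tab:cyan",
                    lw=2, label="composite LOESS")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("A = (log2 R + log2 G) / 2")
    ax.set_ylabel("M = log2(R / G)")
    ax.set_title(f"MA plot: {ma.array_id}")
    ax.legend(loc="best", fontsize=8)
    return ax


def per_factor_mean_plot(by_norm, by_bg, path=None):
    """Line plots of per-factor mean T.stat and AUC versus threshold."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    for row, (table, factor) in enumerate(((by_norm, "normalization"), (by_bg, "background"))):
        for col, stat in enumerate(("T_stat", "AUC")):
            ax = axes[row][col]
            for level, sub in table.groupby(factor):
                sub = sub.sort_values("p0")
                ax.plot(sub["p0"], sub[stat], marker="o", label=str(level))
            ax.set_xlabel("p-value threshold p0")
            ax.set_ylabel(f"mean {stat}")
            ax.set_title(f"{stat} by {factor}")
            ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
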