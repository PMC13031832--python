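"""Figure helpers: truth-vs-estimate scatters, RMSE boxplots, KDE overlays."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.stats import gaussian_kde

__all__ = [
    "plot_identifiability_scatter",
    "plot_rmse_boxplots",
    "plot_marginal_kdes",
]


def plot_identifiability_scatter(report, path: str | None = None):
    """One panel per parameter: truth (x) vs posterior mean (y) per combo."""
    names = list(report.correlation.index)
    fig, axes = plt.subplots(1, len(names), figsize=(3.2 * len(names), 3.2))
    for ax, name in zip(np.atleast_1d(axes), names):
        for combo in report.combos:
            sub = report.records[report.records.combo == combo]
            ax.scatter(
                sub[f"truth_{name}"], sub[f"mean_{name}"], s=14, label=combo,
                alpha=0.75,
            )
        lims = ax.get_xlim()
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_title(name)
        ax.set_xlabel("truth")
    np.atleast_1d(axes)[0].set_ylabel("posterior mean")
    np.atleast_1d(axes)[-1].legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_rmse_boxplots(rmse_records, path: str | None = None):
    """Three panels (S1, S2, APD field RMSE), one box per measurement combo.

    ``rmse_records`` is a DataFrame with columns combo, rmse_S1, rmse_S2,
    rmse_APD.
    """
    types = ["S1", "S2", "APD"]
    combos = list(dict.fromkeys(rmse_records["combo"]))
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    for ax, typ in zip(axes, types):
        data = [
            rmse_records.loc[rmse_records.combo == c, f"rmse_{typ}"].dropna()
            for c in combos
        ]
        ax.boxplot(data, tick_labels=combos)
        ax.set_title(f"{typ} field RMSE")
        ax.set_ylabel("ms")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_marginal_kdes(
    sample_sets: dict[str, np.ndarray],
    names: tuple[str, ...],
    truth: np.ndarray | None = None,
    path: str | None = None,
):
    """Overlay marginal KDEs of several posterior samples (e.g. EnKF vs MCMC)."""
    d = len(names)
    fig, axes = plt.subplots(1, d, figsize=(3.0 * d, 3.0))
    for j, (ax, name) in enumerate(zip(np.atleast_1d(axes), names)):
        for label, samples in sample_sets.items():
            x = np.asarray(samples)[:, j]
            if np.std(x) > 0:
                grid = np.linspace(x.min(), x.max(), 200)
                ax.plot(grid, gaussian_kde(x)(grid), label=label)
        if truth is not None:
            ax.axvline(truth[j], color="k", ls="--", lw=0.8)
        ax.set_title(name)
    np.atleast_1d(axes)[-1].legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
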