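"""Figure helpers: washout curves, violin summaries and cohort scatter."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_washout(ax, times, laa_tr_series, period: float = 1.0, label=None):
    """Volume-averaged LAA residence time vs time, with the T_R = t line."""
    ax.plot(times, laa_tr_series, label=label)
    tmax = max(times)
    ax.plot([0, tmax], [0, tmax], "k--", lw=0.8, label="$T_R = t$")
    ax.set_xlabel("t (s)")
    ax.set_ylabel("LAA $\\langle T_R \\rangle$ (s)")
    return ax


def plot_violin(ax, samples_by_case: dict, ylabel: str):
    """Violin summaries of pooled voxel distributions per case."""
    keys = list(samples_by_case)
    data = [np.asarray(samples_by_case[k]) for k in keys]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(np.arange(1, len(keys) + 1), keys, rotation=45)
    ax.set_ylabel(ylabel)
    return ax


def plot_cohort_scatter(ax, rows, label_key="group"):
    """K vs T_R scatter, one marker per case; solid = moving, open = fixed."""
    for row in rows:
        filled = row.get("mode", "moving") == "moving"
        color = "tab:red" if row[label_key] == "pos" else "tab:blue"
        ax.scatter(row["tr_mean"], row["k_mean"],
                   facecolors=color if filled else "none",
                   edgecolors=color)
    ax.set_xlabel("LAA mean $T_R$ (s)")
    ax.set_ylabel("LAA mean $K$ (cm$^2$/s$^2$)")
    return ax


def save_case_figures(outdir, result, metrics_obj):
    """Write the washout curve and distribution summaries for one run."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    times = [s.t for s in result.snapshots]
    series = [s.laa_tr.mean() for s in result.snapshots]
    plot_washout(ax, times, series)
    fig.tight_layout()
    fig.savefig(outdir / "washout.png", dpi=120)
    plt.close(fig)
    if metrics_obj.tr_density is not None:
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        for ax, dens, lab in zip(axes, (metrics_obj.tr_density,
                                        metrics_obj.k_density),
                                 ("$T_R$ (s)", "$K$ (cm$^2$/s$^2$)")):
            if dens is not None:
                ax.fill_between(dens[0], dens[1], alpha=0.5)
            ax.set_xlabel(lab)
        fig.tight_layout()
        fig.savefig(outdir / "distributions.png", dpi=120)
        plt.close(fig)
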