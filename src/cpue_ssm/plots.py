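"""Quick-look figures for trajectories, growth rates, and climate effects."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_trajectories", "plot_period_growth", "plot_climate_effects"]


def plot_trajectories(trajectories: pd.DataFrame, out: str | Path) -> Path:
    """Per-taxon log-CPUE trajectories with 95% bands, one panel per taxon."""
    taxa = trajectories["taxon"].unique()
    ncol = 2
    nrow = int(np.ceil(len(taxa) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(9, 2.2 * nrow), sharex=True, squeeze=False)
    for ax, taxon in zip(axes.ravel(), taxa):
        sub = trajectories[trajectories["taxon"] == taxon]
        ax.fill_between(
            sub["year"], np.log(sub["ci95_low"]), np.log(sub["ci95_high"]),
            alpha=0.3, color="c", lw=0,
        )
        ax.plot(sub["year"], np.log(sub["median"]), color="b")
        ax.set_title(taxon, fontsize=9)
        ax.set_ylabel("log CPUE")
    for ax in axes.ravel()[len(taxa):]:
        ax.set_visible(False)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def plot_period_growth(growth: pd.DataFrame, out: str | Path) -> Path:
    """Point + interval plot of period-average growth rates per taxon."""
    taxa = growth["taxon"].unique()
    ncol = 2
    nrow = int(np.ceil(len(taxa) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(9, 2.0 * nrow), squeeze=False)
    for ax, taxon in zip(axes.ravel(), taxa):
        sub = growth[growth["taxon"] == taxon]
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.vlines(sub["period"], sub["ci95_low"], sub["ci95_high"], color="k", lw=1)
        ax.vlines(sub["period"], sub["ci50_low"], sub["ci50_high"], color="salmon", lw=4)
        ax.plot(sub["period"], sub["median"], "ko")
        ax.set_title(taxon, fontsize=9)
        ax.set_xticks(sub["period"])
    for ax in axes.ravel()[len(taxa):]:
        ax.set_visible(False)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def plot_climate_effects(post, out: str | Path) -> Path:
    """Temperature-effect coefficients per taxon plus the community mean."""
    gam = post.theta_component("gamma").reshape(-1, len(post.taxa))
    mu_g = post.flat("mu_beta")[:, 3]
    labels = list(post.taxa) + ["community"]
    series = [gam[:, i] for i in range(len(post.taxa))] + [mu_g]
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.axhline(0.0, color="grey", lw=0.5)
    for pos, x in enumerate(series):
        lo, l50, med, h50, hi = np.percentile(x, [2.5, 25, 50, 75, 97.5])
        ax.vlines(pos, lo, hi, color="k", lw=1)
        ax.vlines(pos, l50, h50, color="salmon", lw=4)
        ax.plot(pos, med, "ko")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("temperature effect")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
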