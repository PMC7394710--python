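"""Minimal diagnostic plots: eigengap profiles and character-analysis heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_eigengap_profiles", "plot_correlation_heatmap"]


def plot_eigengap_profiles(eigengap_df: pd.DataFrame, dest: str | Path, max_panels: int = 8) -> Path:
    """Bar profile of eigengap vs K, one panel per gamma (tidy table from eigengap_table)."""
    gammas = sorted(eigengap_df["gamma"].unique())[:max_panels]
    fig, axes = plt.subplots(len(gammas), 1, figsize=(6, 1.6 * len(gammas)), sharex=True, squeeze=False)
    for ax, gamma in zip(axes[:, 0], gammas):
        sub = eigengap_df[eigengap_df["gamma"] == gamma]
        colors = ["tab:red" if p else "tab:gray" for p in sub["is_peak"]]
        ax.bar(sub["K"], sub["gap"], color=colors)
        ax.set_ylabel(f"γ={gamma:g}", fontsize=8)
    axes[-1, 0].set_xlabel("K")
    fig.suptitle("Eigengap profiles (peaks highlighted)")
    fig.tight_layout()
    path = Path(dest)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_correlation_heatmap(corr_df: pd.DataFrame, dest: str | Path) -> Path:
    """Character x eigenvector Pearson-r heatmap; non-significant cells are blanked."""
    pivot_r = corr_df.pivot(index="character", columns="eigenvector", values="r")
    sig = corr_df.pivot(index="character", columns="eigenvector", values="significant").astype(bool)
    shown = pivot_r.where(sig)
    fig, ax = plt.subplots(figsize=(1 + 0.5 * shown.shape[1], 0.3 * shown.shape[0] + 1.5))
    im = ax.imshow(np.ma.masked_invalid(shown.to_numpy()), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(shown.shape[1]), shown.columns)
    ax.set_yticks(range(shown.shape[0]), shown.index, fontsize=7)
    ax.set_xlabel("eigenvector (ascending eigenvalue)")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    path = Path(dest)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
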