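"""Minimal figure helpers (TSS profile curve, DMP heatmap)."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .profiles import BinProfile


def plot_tss_profile(profile: BinProfile, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 3))
    x = profile.offsets + profile.bin_bp / 2
    ax.plot(x, profile.mean_ml, lw=1.5)
    ax.axvline(0, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("mean ML")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dmp_heatmap(matrix: pd.DataFrame, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r",
                   vmin=0, vmax=1, interpolation="nearest")
    ax.set_xticks(range(matrix.shape[1]), labels=list(matrix.columns), rotation=90)
    ax.set_yticks([])
    ax.set_ylabel(f"{matrix.shape[0]} promoters")
    fig.colorbar(im, ax=ax, label="ML")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
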