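"""Heatmap rendering of MPS tables and PCA loadings."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def mps_heatmap(mps: pd.DataFrame, path: str | Path, *, title: str = "MPS") -> Path:
    """Render a test-group x training-class MPS heatmap to an image file."""
    plt = _plt()
    fig, ax = plt.subplots(
        figsize=(max(6, 0.45 * len(mps.columns)), max(4, 0.4 * len(mps.index)))
    )
    im = ax.imshow(mps.to_numpy(float), aspect="auto", cmap="viridis", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(len(mps.columns)), mps.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(mps.index)), mps.index, fontsize=7)
    ax.set_xlabel("training class")
    ax.set_ylabel("test group")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="median probability of similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def loadings_heatmap(loadings: pd.DataFrame, path: str | Path) -> Path:
    """Render a feature x component loadings heatmap to an image file."""
    plt = _plt()
    v = float(np.abs(loadings.to_numpy(float)).max())
    fig, ax = plt.subplots(figsize=(6, max(6, 0.06 * len(loadings.index))))
    im = ax.imshow(loadings.to_numpy(float), aspect="auto", cmap="RdBu_r", vmin=-v, vmax=v)
    ax.set_xticks(range(len(loadings.columns)), loadings.columns)
    ax.set_yticks(range(0, len(loadings.index), 6), loadings.index[::6], fontsize=5)
    ax.set_xlabel("component")
    ax.set_title("PCA loadings")
    fig.colorbar(im, ax=ax, label="loading")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
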