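"""Optional figures: ROC curves, TSS meta-profiles, volcano plots, UMAP.

Requires matplotlib (``pip install cfpromoter[plot]``); umap-learn is
optional for the embedding. All functions return the Axes so callers can
compose panels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_roc(scores, labels, ax=None, label: str | None = None):
    from sklearn.metrics import roc_curve

    from .classify import _as_binary, auc_mann_whitney

    ax = _ax(ax)
    y = _as_binary(labels)
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, float))
    ax.plot(fpr, tpr, label=f"{label or 'ROC'} (AUC {auc_mann_whitney(scores, y):.3f})")
    ax.plot([0, 1], [0, 1], ls=":", c="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    return ax


def plot_meta_profile(profiles: dict[str, pd.DataFrame], ax=None):
    """Overlay TSS meta-profiles, e.g. housekeeping vs non-constitutive."""
    ax = _ax(ax)
    for name, prof in profiles.items():
        ax.plot(prof["offset"], prof["value"], label=name)
    ax.axvline(0, ls=":", c="grey")
    ax.set_xlabel("offset from TSS (bp)")
    ax.set_ylabel("normalized coverage")
    ax.legend()
    return ax


def plot_volcano(volcano: pd.DataFrame, ax=None):
    ax = _ax(ax)
    sig = volcano["significant"].to_numpy(bool)
    ax.scatter(volcano.loc[~sig, "log2_fc"], volcano.loc[~sig, "neg_log10_fdr"], s=6, c="grey")
    ax.scatter(volcano.loc[sig, "log2_fc"], volcano.loc[sig, "neg_log10_fdr"], s=8, c="crimson")
    ax.set_xlabel("log2 fold change (ALN-positive / ALN-negative)")
    ax.set_ylabel("-log10 FDR")
    return ax


def umap_embedding(matrix, labels=None, seed: int = 0, ax=None):
    """2-D UMAP of samples on (typically differential) features."""
    import umap

    emb = umap.UMAP(random_state=seed).fit_transform(matrix.values.to_numpy(float))
    ax = _ax(ax)
    if labels is None:
        ax.scatter(emb[:, 0], emb[:, 1], s=12)
    else:
        for lv in pd.unique(pd.Series(labels)):
            m = np.asarray(labels) == lv
            ax.scatter(emb[m, 0], emb[m, 1], s=12, label=str(lv))
        ax.legend()
    ax.set_xlabel("UMAP1")
    ax.set_ylabel("UMAP2")
    return ax
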