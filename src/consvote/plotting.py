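"""Optional plots: annotated ROC curve and a PCA chemical-space view."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .roc import RocCurve, ThresholdResult


def plot_roc(curve: RocCurve, opt: ThresholdResult | None = None,
             path: str | Path | None = None, label: str | None = None):
    """ROC curve with the distance-to-corner optimum annotated."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(curve.fpr, curve.tpr,
            label=label or f"AUC = {curve.auc:.2f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    if opt is not None:
        ax.plot([0, opt.fpr_at_opt], [1, opt.tpr_at_opt], c="tab:red", lw=0.8)
        ax.scatter([opt.fpr_at_opt], [opt.tpr_at_opt], zorder=3,
                   facecolors="none", edgecolors="tab:blue",
                   label=f"optimum (d = {opt.distance:.2f}, "
                         f"t = {opt.threshold:.2f})")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_chemical_space(values: np.ndarray, groups, path: str | Path | None
                        = None):
    """First two principal components of a feature matrix, colored by group."""
    X = np.asarray(values, dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    pcs = X @ vt[:2].T
    fig, ax = plt.subplots(figsize=(5, 5))
    groups = np.asarray(groups)
    for g in np.unique(groups):
        m = groups == g
        ax.scatter(pcs[m, 0], pcs[m, 1], s=8, alpha=0.5, label=str(g))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
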