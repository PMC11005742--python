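"""Optional diagnostic plots (requires matplotlib, the ``plot`` extra)."""

from __future__ import annotations

import numpy as np

from .dann import CLASS_ORDER


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_roc(rocs: dict[str, dict], path) -> None:
    """ROC curves per sweep type, one panel."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 4))
    for name, roc in rocs.items():
        ax.plot(roc["fpr"], roc["tpr"], label=f"{name} (AUC {roc['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_confusion(conf: dict, path) -> None:
    """Column-normalised confusion heatmap (true on x, predicted on y)."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(conf["rates"], vmin=0, vmax=1, cmap="Blues")
    ax.set_xticks(range(5), CLASS_ORDER, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(5), CLASS_ORDER, fontsize=7)
    ax.set_xlabel("true label")
    ax.set_ylabel("predicted label")
    for i in range(5):
        for j in range(5):
            ax.text(j, i, f"{conf['rates'][i, j]:.2f}", ha="center", va="center",
                    fontsize=6, color="black")
    fig.colorbar(im, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca(proj_source: np.ndarray, proj_target: np.ndarray, evr, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(*proj_source[:, :2].T, s=6, alpha=0.5, label="source")
    ax.scatter(*proj_target[:, :2].T, s=6, alpha=0.5, label="target")
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_domain_scores(hist: dict, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 3))
    centers = 0.5 * (hist["edges"][:-1] + hist["edges"][1:])
    ax.bar(centers, hist["hist"], width=np.diff(hist["edges"]), alpha=0.8)
    ax.axvline(0.5, color="k", ls=":")
    ax.set_xlabel("domain-discriminator score")
    ax.set_ylabel("fragments")
    ax.set_title(f"mass below 0.5: {hist['mass_below_half']:.2f}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
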