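"""Optional figures: biomarker heatmap, PCA scatter, reference dendrogram.

Convenience visualisations mirroring the classifier's three views; the
calls themselves never depend on these.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram, linkage

from .containers import DDI, TrainingSet
from .projection import PCAAxisClassifier


def heatmap(training: TrainingSet, profiles, path: str | Path) -> None:
    """Genes x conditions heatmap: training profiles then test conditions."""
    test = np.column_stack([p.log2fc.loc[training.genes].to_numpy()
                            for p in profiles]) if profiles else \
        np.empty((len(training.genes), 0))
    data = np.column_stack([training.X.to_numpy().T, test])
    labels = list(training.X.index) + [p.condition for p in profiles]
    fig, ax = plt.subplots(figsize=(max(6, 0.22 * data.shape[1]), 9))
    vmax = np.abs(data).max() or 1.0
    im = ax.imshow(data, aspect="auto", cmap="RdYlGn_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=4)
    ax.set_ylabel("biomarker gene")
    fig.colorbar(im, label="log2 fold change vs control")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_scatter(training: TrainingSet, profiles, path: str | Path) -> None:
    model = PCAAxisClassifier().fit(training.X, training.y)
    scores = model.training_scores_
    fig, ax = plt.subplots(figsize=(7, 6))
    for label, color in ((DDI, "tab:red"), ("non-DDI", "tab:blue")):
        mask = model.training_labels_ == label
        ax.scatter(scores[mask, 0], scores[mask, 1], c=color, label=label, s=25)
    if profiles:
        test = model.transform(np.vstack(
            [p.log2fc.loc[training.genes].to_numpy() for p in profiles]))
        ax.scatter(test[:, 0], test[:, 1], c="tab:green", marker="x",
                   label="test conditions", s=35)
    ax.axvline(0.0, color="k", lw=1, ls="--")
    ax.set_xlabel("PC1 score (line at 0 divides DDI / non-DDI)")
    ax.set_ylabel("PC2 score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def reference_dendrogram(training: TrainingSet, path: str | Path) -> None:
    Z = linkage(training.X.to_numpy(), method="average", metric="euclidean")
    fig, ax = plt.subplots(figsize=(10, 5))
    dendrogram(Z, labels=list(training.X.index), ax=ax, leaf_font_size=6)
    ax.set_ylabel("Euclidean distance (average linkage)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_all(training: TrainingSet, profiles, out_dir: str | Path) -> None:
    out = Path(out_dir)
    heatmap(training, profiles, out / "heatmap.png")
    pca_scatter(training, profiles, out / "pca.png")
    reference_dendrogram(training, out / "dendrogram.png")
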