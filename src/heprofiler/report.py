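"""Presentation layer: t-SNE embeddings, clustered heatmaps, polar
histograms, confidence plots.  Every plotting helper also returns (and can
write) the underlying numbers so figures are regenerable and testable
without image comparison."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.manifold import TSNE

__all__ = [
    "Embedding",
    "tsne_embed",
    "clustered_heatmap",
    "polar_histogram",
    "save_confidence_plot",
]


@dataclass
class Embedding:
    coords: np.ndarray  # (n, dims)
    labels: np.ndarray
    perplexity: float
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords, columns=[f"tsne{i + 1}" for i in range(self.coords.shape[1])]
        )
        df["label"] = self.labels
        return df


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    return (X[:, keep] - mu[keep]) / sd[keep]


def tsne_embed(
    X: np.ndarray | pd.DataFrame,
    labels: np.ndarray | None = None,
    dims: int = 2,
    perplexity: float = 30.0,
    seed: int = 0,
) -> Embedding:
    """t-SNE of z-scored features; deterministic given the seed."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(f"perplexity {perplexity} too large for n={n}")
    Z = _zscore(X)
    coords = TSNE(
        n_components=dims, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(Z)
    lab = np.asarray(labels) if labels is not None else np.array([""] * n)
    return Embedding(coords=coords, labels=lab, perplexity=perplexity, seed=seed)


def clustered_heatmap(
    X: pd.DataFrame,
    labels: np.ndarray | None = None,
    out_png: str | Path | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Average-linkage hierarchical clustering of z-scored features.

    Returns (row order, column order, normalized matrix); constant
    features are dropped with a warning.  Optionally writes the figure.
    """
    import warnings

    vals = X.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    if (sd == 0).any():
        warnings.warn(f"dropping {(sd == 0).sum()} constant feature(s)")
    cols = X.columns[sd > 0]
    Z = (vals[:, sd > 0] - vals[:, sd > 0].mean(axis=0)) / sd[sd > 0]
    norm = pd.DataFrame(Z, index=X.index, columns=cols)

    row_order = leaves_list(linkage(Z, method="average", metric="euclidean"))
    col_order = leaves_list(linkage(Z.T, method="average", metric="euclidean"))

    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 6))
        im = ax.imshow(
            Z[np.ix_(row_order, col_order)], aspect="auto", cmap="RdBu_r",
            vmin=-3, vmax=3,
        )
        ax.set_xlabel("features (clustered)")
        ax.set_ylabel("samples (clustered)")
        fig.colorbar(im, ax=ax, label="z-score")
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return row_order, col_order, norm


def polar_histogram(angles: np.ndarray, n_bins: int = 18) -> tuple[np.ndarray, np.ndarray]:
    """Bin angles into n_bins partitioning (-pi, pi]; returns (counts, edges)."""
    a = np.asarray(angles, dtype=float)
    if a.size and not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    # wrap into (-pi, pi]
    a = -((-a + np.pi) % (2 * np.pi) - np.pi)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(a, bins=edges)
    # histogram's rightmost bin is closed on both sides, matching (-pi, pi]
    return counts, edges


def save_confidence_plot(
    probabilities: np.ndarray,
    labels: np.ndarray,
    positive_class: str,
    out_png: str | Path,
) -> pd.DataFrame:
    """Per-sample positive-class confidence plot; returns the numbers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.DataFrame(dict(confidence=probabilities, label=labels)).sort_values(
        ["label", "confidence"], ignore_index=True
    )
    fig, ax = plt.subplots(figsize=(8, 3))
    for lab, grp in df.groupby("label"):
        ax.scatter(grp.index, grp.confidence, s=8, label=str(lab))
    ax.set_ylabel(f"P({positive_class})")
    ax.set_xlabel("sample (sorted)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return df
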