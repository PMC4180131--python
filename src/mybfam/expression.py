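"""Organ-expression analysis from RNA-seq count matrices.

Counts are normalised with median-of-ratios size factors (the DESeq
estimator): each gene with no zero count provides a reference value (its
geometric mean across samples), and a sample's factor is the median of
its count-to-reference ratios. Presence calls compare normalised values
against a threshold (default: any signal counts as expressed, matching a
"no detected expression = black" heatmap convention). Gene ordering for
the heatmap comes from centroid-linkage hierarchical clustering of
log2-transformed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    gene_ids: list[str]
    samples: list[str]
    counts: np.ndarray  # genes x samples, non-negative integers

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError("counts shape does not match gene/sample labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if not self.samples:
            raise ValueError("need at least one sample")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.samples)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(gene_ids=list(df.index), samples=list(df.columns),
                   counts=df.to_numpy())


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    reference(g) = geometric mean of gene g across samples, over genes
    with no zero count; factor(s) = median over those genes of
    counts(g, s) / reference(g).
    """
    counts = cm.counts.astype(float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; supply a "
            "pseudo-reference or filter samples"
        )
    sub = counts[all_positive]
    log_ref = np.log(sub).mean(axis=1)
    ratios = sub / np.exp(log_ref)[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=cm.samples, name="size_factor")


def normalize(cm: CountMatrix, sf: pd.Series) -> pd.DataFrame:
    """counts(g, s) / factor(s)."""
    if set(sf.index) != set(cm.samples):
        raise ValueError("size-factor samples do not match count matrix")
    frame = cm.to_frame().astype(float)
    return frame.div(sf[frame.columns], axis=1)


@dataclass
class PresenceMatrix:
    calls: pd.DataFrame  # boolean genes x organs
    threshold: float
    per_organ: dict[str, int] = field(default_factory=dict)
    in_all: int = 0
    in_any: int = 0
    nowhere: int = 0


def presence_calls(nm: pd.DataFrame, threshold: float = 0.0) -> PresenceMatrix:
    """Boolean expressed/not-expressed calls: normalised value > threshold.

    Tallies: per-organ expressed counts, expressed-in-all, expressed-in-
    at-least-one, and expressed-nowhere.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    calls = nm > threshold
    return PresenceMatrix(
        calls=calls,
        threshold=threshold,
        per_organ={s: int(calls[s].sum()) for s in calls.columns},
        in_all=int(calls.all(axis=1).sum()),
        in_any=int(calls.any(axis=1).sum()),
        nowhere=int((~calls.any(axis=1)).sum()),
    )


@dataclass
class ClusterResult:
    """Centroid-linkage agglomeration record.

    `merges` lists (cluster_i, cluster_j, height, new_cluster_id) with
    original rows numbered 0..n-1 and merged clusters n, n+1, ...
    (i < j). `order` is the dendrogram leaf order as gene ids.
    """

    order: list[str]
    merges: list[tuple[int, int, float, int]]
    log_values: pd.DataFrame


def cluster_genes(nm: pd.DataFrame, pseudo: float = 1.0) -> ClusterResult:
    """Centroid-linkage hierarchical clustering of log2(value + pseudo)
    rows under Euclidean distance.

    At each step the globally closest pair of cluster centroids merges;
    ties break on the lowest (i, j) cluster-index pair. Centroid linkage
    is not monotone — merge heights may decrease (permitted). A single
    gene returns the identity ordering.
    """
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    log_values = np.log2(nm + pseudo)
    n = len(log_values)
    if n == 0:
        raise ValueError("empty matrix")
    if n == 1:
        return ClusterResult(order=list(nm.index), merges=[], log_values=log_values)

    centroids = {i: log_values.iloc[i].to_numpy(dtype=float) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    leaf_order = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(centroids) > 1:
        best = None
        ids = sorted(centroids)
        for a_pos, i in enumerate(ids):
            for j in ids[a_pos + 1:]:
                dist = float(np.linalg.norm(centroids[i] - centroids[j]))
                key = (dist, i, j)
                if best is None or key < best:
                    best = key
        dist, i, j = best
        centroid = (sizes[i] * centroids[i] + sizes[j] * centroids[j]) / (
            sizes[i] + sizes[j]
        )
        centroids[next_id] = centroid
        sizes[next_id] = sizes[i] + sizes[j]
        leaf_order[next_id] = leaf_order[i] + leaf_order[j]
        for k in (i, j):
            del centroids[k], sizes[k]
        merges.append((i, j, dist, next_id))
        next_id += 1

    order_idx = leaf_order[next_id - 1]
    return ClusterResult(order=[nm.index[i] for i in order_idx],
                         merges=merges, log_values=log_values)


def export_heatmap(
    nm: pd.DataFrame,
    order: list[str],
    path=None,
    pseudo: float = 1.0,
    image_path=None,
) -> pd.DataFrame:
    """Reordered log2 heatmap table (zero normalised signal maps to the
    table minimum = "black"); optional TSV and best-effort image export."""
    if set(order) != set(nm.index):
        raise ValueError("ordering does not cover the matrix rows")
    table = np.log2(nm + pseudo).loc[order]
    if path is not None:
        table.to_csv(path, sep="\t", index_label="gene_id")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, max(3, len(table) / 8)))
        ax.imshow(table.to_numpy(), aspect="auto", cmap="cividis",
                  interpolation="nearest")
        ax.set_xticks(range(len(table.columns)), table.columns, rotation=90)
        ax.set_yticks([])
        fig.tight_layout()
        fig.savefig(image_path, dpi=120)
        plt.close(fig)
    return table
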