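"""Verification stage: average-linkage hierarchical clustering of samples
and genes on the discriminative gene set, k-cut, and nearest-neighbour
rescue of samples falling between dendrogram branches.

Distances are Euclidean on per-gene standardized values, which makes them
monotone in (1 - Pearson correlation) across samples; linkage is UPGMA.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .core import ClusterAssignment, ExpressionMatrix, UNASSIGNED

log = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Agglomeration record: scipy linkage matrix plus the leaf identifiers.

    ``merges`` has n-1 rows (left, right, height, size); heights are
    recorded exactly as computed by average linkage.
    """

    merges: np.ndarray
    items: list[str]
    axis: str

    @property
    def n_leaves(self) -> int:
        return len(self.items)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.merges, columns=["left", "right", "height", "size"])
        df.to_csv(path, sep="\t", index_label="merge")


def hcluster(m: ExpressionMatrix, axis: str = "samples",
             metric: str = "euclidean") -> Dendrogram:
    """UPGMA (average linkage) dendrogram over samples or genes.

    The input is expected per-gene standardized; ``metric`` may be
    "euclidean" (default) or "correlation".
    """
    if axis not in ("samples", "genes"):
        raise ValueError("axis must be 'samples' or 'genes'")
    x = m.values.T if axis == "samples" else m.values
    items = m.samples if axis == "samples" else m.genes
    if len(items) < 2:
        raise ValueError(f"need at least 2 {axis} to cluster")
    z = linkage(x, method="average", metric=metric)
    return Dendrogram(merges=z, items=list(items), axis=axis)


def cut_k(d: Dendrogram, k: int, min_cluster_size: int = 1) -> ClusterAssignment:
    """Cut the dendrogram into k groups at the standard k-cluster level.

    Groups smaller than ``min_cluster_size`` are marked UNASSIGNED — these
    are the samples "in between" branches, candidates for rescue.  Surviving
    groups are labelled 1..K in decreasing size (ties by smallest member).
    """
    if not (1 <= k <= d.n_leaves):
        raise ValueError("k must be in 1..n_leaves")
    raw = fcluster(d.merges, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=d.items)
    sizes = labels.value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_cluster_size]
    order = sorted(keep, key=lambda c: (-sizes[c],
                                        min(labels.index[labels == c])))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    out = labels.map(lambda c: relabel.get(c, UNASSIGNED))
    return ClusterAssignment.from_labels(out, provenance="hierarchical")


def rescue_by_pca_nn(assign: ClusterAssignment,
                     scores: pd.DataFrame) -> ClusterAssignment:
    """Give every unassigned sample the label of its nearest assigned
    neighbour in PCA score space (provenance ``nn_rescue``).

    Already-assigned labels are never changed; the operation is idempotent.
    """
    labels = assign.labels.copy()
    prov = assign.provenance.copy()
    assigned = labels.index[labels != UNASSIGNED]
    if len(assigned) == 0:
        raise ValueError("no assigned samples to rescue from")
    unassigned = labels.index[labels == UNASSIGNED]
    if len(unassigned) == 0:
        return ClusterAssignment(labels, prov)
    d = cdist(scores.loc[unassigned].to_numpy(),
              scores.loc[assigned].to_numpy())
    nearest = np.argmin(d, axis=1)  # ties: first (smallest index) wins
    for s, j in zip(unassigned, nearest):
        labels[s] = labels[assigned[j]]
        prov[s] = "nn_rescue"
    return ClusterAssignment(labels, prov)


def gene_clusters(m: ExpressionMatrix, k_genes: int = 5,
                  metric: str = "euclidean") -> ClusterAssignment:
    """Cut the gene-axis dendrogram into ``k_genes`` groups."""
    dend = hcluster(m, axis="genes", metric=metric)
    return cut_k(dend, k_genes)
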