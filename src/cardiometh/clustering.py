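"""Rank transform and bottom-up hierarchical clustering of samples.

Before clustering, every gene's methylation values are replaced by the rank
of each sample among all samples for that gene (rank 1 = lowest
methylation), which removes gene-specific scale. Pairwise Euclidean
distances between samples in rank space then feed a standard agglomerative
(bottom-up) clustering.

The agglomeration is implemented directly rather than delegated so that the
merge order is fully deterministic: when several cluster pairs tie at the
minimal linkage distance, the pair with the smallest (i, j) node indices is
merged first. Node numbering follows the usual convention: leaves are
0..n-1 and the cluster created by merge t is node n+t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Dendrogram",
    "rank_transform",
    "euclidean_distance_matrix",
    "agglomerative_cluster",
]

LINKAGES = ("complete", "average", "single")


@dataclass
class Dendrogram:
    """Merge list of an agglomerative clustering.

    ``merges`` has one row per merge: (node_a, node_b, height, size), with
    node_a < node_b; leaves are nodes 0..n_leaves-1 and merge t creates node
    n_leaves + t.
    """

    merges: np.ndarray  # (n-1, 4) float
    n_leaves: int
    labels: list[str]
    linkage: str

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels (0..n_clusters-1) obtained by undoing the
        last ``n_clusters - 1`` merges."""
        if not 1 <= n_clusters <= self.n_leaves:
            raise ValueError("n_clusters out of range")
        members = {i: [i] for i in range(self.n_leaves)}
        for t, (a, b, _h, _s) in enumerate(self.merges[: self.n_leaves - n_clusters]):
            node = self.n_leaves + t
            members[node] = members.pop(int(a)) + members.pop(int(b))
        labels = np.empty(self.n_leaves, dtype=int)
        for lab, node in enumerate(sorted(members)):
            labels[members[node]] = lab
        return labels

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order of the dendrogram."""
        children = {
            self.n_leaves + t: (int(a), int(b))
            for t, (a, b, _h, _s) in enumerate(self.merges)
        }

        def walk(node: int) -> list[int]:
            if node < self.n_leaves:
                return [node]
            a, b = children[node]
            return walk(a) + walk(b)

        root = self.n_leaves + len(self.merges) - 1
        return walk(root) if self.merges.size else [0]

    def to_newick(self) -> str:
        children = {
            self.n_leaves + t: (int(a), int(b), float(h))
            for t, (a, b, h, _s) in enumerate(self.merges)
        }
        heights = {i: 0.0 for i in range(self.n_leaves)}
        for node, (_a, _b, h) in children.items():
            heights[node] = h

        def walk(node: int) -> str:
            if node < self.n_leaves:
                return self.labels[node]
            a, b, h = children[node]
            return f"({walk(a)}:{h - heights[a]:g},{walk(b)}:{h - heights[b]:g})"

        root = self.n_leaves + len(self.merges) - 1
        return walk(root) + ";" if self.merges.size else self.labels[0] + ";"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["node_a", "node_b", "height", "size"])


def rank_transform(gene_matrix: pd.DataFrame, ties: str = "average") -> pd.DataFrame:
    """Rank samples within each gene row (1 = lowest methylation).

    ``ties='average'`` assigns tied samples their average rank;
    ``ties='competition'`` emulates strict integer ranking, ordering tied
    samples by their column position (documented, deterministic).
    """
    if gene_matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = gene_matrix.to_numpy(dtype=float)
    if ties == "average":
        R = stats.rankdata(X, axis=1)
    elif ties == "competition":
        R = np.argsort(np.argsort(X, axis=1, kind="stable"), axis=1) + 1.0
    else:
        raise ValueError("ties must be 'average' or 'competition'")
    return pd.DataFrame(R, index=gene_matrix.index, columns=gene_matrix.columns)


def euclidean_distance_matrix(rank_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples (columns) over genes."""
    X = rank_matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values not allowed")
    D = squareform(pdist(X.T, metric="euclidean"))
    return pd.DataFrame(D, index=rank_matrix.columns, columns=rank_matrix.columns)


def _linkage_dist(D: np.ndarray, a: list[int], b: list[int], linkage: str) -> float:
    block = D[np.ix_(a, b)]
    if linkage == "complete":
        return float(block.max())
    if linkage == "average":
        return float(block.mean())
    return float(block.min())  # single


def agglomerative_cluster(dist: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Bottom-up clustering of a symmetric distance matrix.

    At each step the pair of clusters with minimal linkage distance is
    merged; ties are broken by the smallest (i, j) node index pair. The
    naive O(n^3) recomputation is deliberate — cohort sizes are tens of
    samples and exact reproducibility of the merge sequence matters more
    than speed here.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    D = dist.to_numpy(dtype=float)
    n = D.shape[0]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must have zero diagonal")
    labels = [str(c) for c in dist.columns]
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = np.zeros((n - 1, 4))
    for t in range(n - 1):
        best = None
        nodes = sorted(active)
        for ii, i in enumerate(nodes):
            for j in nodes[ii + 1 :]:
                d = _linkage_dist(D, active[i], active[j], linkage)
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        node = n + t
        active[node] = active.pop(i) + active.pop(j)
        merges[t] = (i, j, d, len(active[node]))
    return Dendrogram(merges=merges, n_leaves=n, labels=labels, linkage=linkage)
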