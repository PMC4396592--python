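"""Two-way clustering of the coefficient table and network export.

Rows (proteins) and columns (miRNAs) of the coefficient table are ordered
by agglomerative complete-linkage clustering under Pearson-correlation
distance, flat co-regulation blocks are extracted by cutting each tree at a
fixed number of clusters, and the significant cells are exported as a SIF
edge list.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .univariate import AssociationMatrix

__all__ = [
    "ClusterTree",
    "ClusterAssignment",
    "correlation_distance",
    "hierarchical_cluster",
    "extract_clusters",
    "two_way_cluster",
    "export_network",
    "suggest_k",
]


@dataclass
class ClusterTree:
    """Agglomerative merge tree over named leaves."""

    linkage: np.ndarray      # scipy (n-1, 4) linkage matrix
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_nested(self):
        """Serialize as nested lists: leaves are ids, merges are
        ``[left, right, height]``."""
        nodes: list = list(self.leaf_ids)
        for left, right, height, _ in self.linkage:
            nodes.append([nodes[int(left)], nodes[int(right)], float(height)])
        return nodes[-1] if len(nodes) > len(self.leaf_ids) else nodes[0]

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_nested(), handle)


@dataclass
class ClusterAssignment:
    """Flat partitions of rows and columns with their merge trees."""

    row_labels: dict[str, int]
    col_labels: dict[str, int]
    row_tree: ClusterTree | None = None
    col_tree: ClusterTree | None = None


def correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """Pairwise d(i, j) = 1 - Pearson(row_i, row_j).

    Rows of zero variance are assigned distance 1 to every other row
    (uncorrelated convention) and 0 to themselves.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered * centered).sum(axis=1))
    flat = norms == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance row(s); distance set to 1",
            UserWarning,
            stacklevel=2,
        )
    safe = np.where(flat, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return dist


def hierarchical_cluster(
    dist: np.ndarray, leaf_ids: list[str] | None = None, linkage: str = "complete"
) -> ClusterTree:
    """Agglomerative clustering of a precomputed distance matrix."""
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(D.shape[0])]
    if len(leaf_ids) != D.shape[0]:
        raise ValueError("leaf_ids length must match the matrix size")
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(Z, list(leaf_ids))


def extract_clusters(tree: ClusterTree, k: int) -> dict[str, int]:
    """Cut the tree into exactly k flat clusters.

    Labels are renumbered 0..k-1 in order of first appearance along the
    leaf order, making the assignment deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > tree.n_leaves:
        raise ValueError(f"k = {k} exceeds {tree.n_leaves} leaves")
    raw = hierarchy.cut_tree(tree.linkage, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    labels = {}
    for leaf, lab in zip(tree.leaf_ids, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel)
        labels[leaf] = relabel[lab]
    return labels


def two_way_cluster(
    assoc: AssociationMatrix, row_k: int, col_k: int
) -> ClusterAssignment:
    """Cluster proteins (rows) and miRNAs (columns) of the full coefficient
    table — significant and nonsignificant cells alike."""
    row_tree = hierarchical_cluster(
        correlation_distance(assoc.beta), assoc.protein_ids
    )
    col_tree = hierarchical_cluster(
        correlation_distance(assoc.beta.T), assoc.mirna_ids
    )
    return ClusterAssignment(
        row_labels=extract_clusters(row_tree, row_k),
        col_labels=extract_clusters(col_tree, col_k),
        row_tree=row_tree,
        col_tree=col_tree,
    )


def export_network(
    assoc: AssociationMatrix,
    threshold: float = 0.0,
    require_significant: bool = True,
) -> list[tuple[str, str, str]]:
    """Edges (mirna, "pos"|"neg", protein) for cells passing the filter:
    |beta| > threshold and (optionally) significance."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mask = np.abs(assoc.beta) > threshold
    if require_significant:
        mask &= assoc.significant
    edges = []
    for i, j in zip(*np.nonzero(mask)):
        sign = "pos" if assoc.beta[i, j] > 0 else "neg"
        edges.append((assoc.mirna_ids[j], sign, assoc.protein_ids[i]))
    return edges


def write_sif(edges: list[tuple[str, str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for mirna, sign, protein in edges:
            handle.write(f"{mirna}\t{sign}\t{protein}\n")


def suggest_k(
    matrix: np.ndarray,
    k_max: int,
    metric: str = "correlation",
    n_refs: int = 10,
    seed: int = 0,
) -> int:
    """Gap-statistic choice of the cluster count for complete-linkage
    clustering: smallest k with gap(k) >= gap(k+1) - se(k+1)."""
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    k_max = min(k_max, n)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")

    def dispersion(data: np.ndarray, k: int) -> float:
        if metric == "correlation":
            D = correlation_distance(data)
        else:
            diff = data[:, None, :] - data[None, :, :]
            D = np.sqrt((diff * diff).sum(axis=2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            tree = hierarchical_cluster(D)
        labels = np.array(
            [extract_clusters(tree, k)[leaf] for leaf in tree.leaf_ids]
        )
        total = 0.0
        for c in range(k):
            members = np.nonzero(labels == c)[0]
            if members.size > 1:
                sub = D[np.ix_(members, members)]
                total += (sub ** 2).sum() / (2.0 * members.size)
        return total

    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ks = np.arange(1, k_max + 1)
    log_w = np.array([np.log(max(dispersion(X, k), 1e-300)) for k in ks])
    ref_log_w = np.empty((n_refs, k_max))
    for b in range(n_refs):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_log_w[b] = [np.log(max(dispersion(ref, k), 1e-300)) for k in ks]
    gap = ref_log_w.mean(axis=0) - log_w
    se = ref_log_w.std(axis=0, ddof=1) * np.sqrt(1 + 1.0 / n_refs)
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            return int(ks[i])
    return int(ks[-1])
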