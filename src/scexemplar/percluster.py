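"""Per-dataset clustering and rank-normalized cluster centroids.

Each scRNA-seq dataset is clustered on its own (Louvain communities on a
shared-nearest-neighbor graph over the top principal components of log1p,
library-size-normalized counts).  Cells are then rank-normalized — within each
cell, genes are ranked ascending by expression with average ranks for ties, so
the zero block forms one tied group — and a cluster's *rank centroid* is the
per-gene mean of its members' ranks.  Ranking makes the centroid invariant to
any strictly monotone per-cell distortion, which is the property the
cross-dataset comparison relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix

log = logging.getLogger(__name__)

SMALL_CLUSTER_FLAG = 10  # clusters below this size are kept but flagged


@dataclass
class ClusterAssignment:
    dataset_id: str
    cell_ids: list[str]
    labels: np.ndarray  # contiguous integer cluster ids, one per cell

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.cell_ids):
            raise ValueError("one label per cell required")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster ids must be contiguous 0..n-1")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    def members(self, cluster: int) -> list[str]:
        return [c for c, l in zip(self.cell_ids, self.labels) if l == cluster]


@dataclass
class RankCentroid:
    """Per-gene average within-cell rank over one cluster's cells."""

    cluster_uid: str
    avg_rank: pd.Series  # indexed by gene id
    n_cells: int
    dataset_id: str = ""

    def __post_init__(self) -> None:
        g = len(self.avg_rank)
        if g == 0:
            raise ValueError("empty centroid")
        vals = self.avg_rank.to_numpy()
        if vals.min() < 1 - 1e-9 or vals.max() > g + 1e-9:
            raise ValueError("avg_rank entries must lie in [1, G]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.avg_rank.index)


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary integer labels to 0..n-1, ordered by decreasing size
    (ties broken by first appearance)."""
    labels = np.asarray(labels, dtype=int)
    uniq, counts = np.unique(labels, return_counts=True)
    first_pos = {u: int(np.argmax(labels == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-counts[list(uniq).index(u)], first_pos[u]))
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[l] for l in labels], dtype=int)


def _snn_graph(X: np.ndarray, k: int) -> nx.Graph:
    """Shared-nearest-neighbor graph: edge weight = Jaccard overlap of the two
    cells' k-NN sets (self included), pruned below 1/15 as is conventional."""
    n = X.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k, n)).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = [set(row) | {i} for i, row in enumerate(idx)]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = inter / union
            if w >= 1 / 15:
                g.add_edge(i, j, weight=w)
    return g


def _group_singletons(labels: np.ndarray, graph: nx.Graph, pcs: np.ndarray) -> np.ndarray:
    """Merge single-cell communities into their best-connected neighboring
    cluster (nearest cluster in PC space for fully isolated cells), mirroring
    the grouping of singletons that the conventional recipe applies."""
    labels = labels.copy()
    uniq, counts = np.unique(labels, return_counts=True)
    multi = set(uniq[counts > 1])
    if not multi:
        return labels
    for cell in np.where(np.isin(labels, list(uniq[counts == 1])))[0]:
        weights: dict[int, float] = {}
        for nbr, attrs in graph[cell].items():
            l = labels[nbr]
            if l in multi:
                weights[l] = weights.get(l, 0.0) + attrs["weight"]
        if weights:
            labels[cell] = max(weights.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        else:  # isolated node: nearest non-singleton cell in PC space
            others = np.where(np.isin(labels, list(multi)))[0]
            d = np.linalg.norm(pcs[others] - pcs[cell], axis=1)
            labels[cell] = labels[others[np.argmin(d)]]
    return labels


def cluster_dataset(
    em: ExpressionMatrix,
    knn_k: int = 20,
    resolution: float = 0.8,
    n_pcs: int = 50,
    seed: int = 0,
    precomputed_labels: pd.Series | None = None,
) -> ClusterAssignment:
    """Louvain clustering of one dataset, or validation of supplied labels.

    Counts are scaled to 10k per cell and log1p-transformed before PCA; the
    SNN graph uses ``knn_k`` neighbors.  Deterministic given ``seed``.
    """
    cells = em.column_ids
    if precomputed_labels is not None:
        aligned = precomputed_labels.reindex(cells)
        if aligned.isna().any():
            missing = aligned.index[aligned.isna()][:5].tolist()
            raise ValueError(f"precomputed labels missing for cells {missing}")
        return ClusterAssignment(em.dataset_id, cells, _relabel_contiguous(aligned.to_numpy()))

    if em.unit != "counts":
        raise ValueError(f"clustering expects counts, got unit={em.unit!r}")
    n = em.n_columns
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    if n <= knn_k:
        raise ValueError(
            f"dataset has {n} cells but knn_k={knn_k}; pass a smaller knn_k"
        )

    X = em.data.to_numpy(dtype=float).T  # cells x genes
    libsize = X.sum(axis=1, keepdims=True)
    libsize[libsize == 0] = 1.0
    X = np.log1p(X / libsize * 1e4)

    n_comp = min(n_pcs, n - 1, X.shape[1])
    if np.allclose(X, X[0]):  # all cells identical: no structure, one cluster
        return ClusterAssignment(em.dataset_id, cells, np.zeros(n, dtype=int))
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(X)

    graph = _snn_graph(pcs, knn_k)
    communities = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    labels = np.empty(n, dtype=int)
    for cid, comm in enumerate(communities):
        for node in comm:
            labels[node] = cid
    labels = _group_singletons(labels, graph, pcs)
    return ClusterAssignment(em.dataset_id, cells, _relabel_contiguous(labels))


def rank_normalize_cells(em: ExpressionMatrix) -> ExpressionMatrix:
    """Within-cell ascending ranks with average ties; output values in [1, G]."""
    if em.unit not in ("counts", "TPM"):
        raise ValueError(f"rank normalization expects counts or TPM, got {em.unit!r}")
    ranks = rankdata(em.data.to_numpy(dtype=float), method="average", axis=0)
    ranked = pd.DataFrame(ranks, index=em.data.index, columns=em.data.columns)
    return ExpressionMatrix(ranked, unit="rank", dataset_id=em.dataset_id)


def compute_rank_centroid(
    ranked: ExpressionMatrix,
    member_cell_ids: list[str],
    cluster_uid: str | None = None,
    min_cells: int = 50,
) -> RankCentroid:
    """Arithmetic mean of member rank vectors.

    Emits a warning below ``min_cells`` members: subsampling experiments show
    centroid stability saturates around 50 cells.
    """
    if ranked.unit != "rank":
        raise ValueError("compute_rank_centroid expects a rank-normalized matrix")
    if len(member_cell_ids) == 0:
        raise ValueError("member set is empty")
    missing = [c for c in member_cell_ids if c not in ranked.data.columns]
    if missing:
        raise KeyError(f"member cell ids not in matrix: {missing[:5]}")
    sub = ranked.data[list(member_cell_ids)]
    n = sub.shape[1]
    if n < min_cells:
        log.warning(
            "cluster %s has only %d cells (< %d); centroid may be unstable",
            cluster_uid, n, min_cells,
        )
    uid = cluster_uid or f"{ranked.dataset_id}:cluster"
    return RankCentroid(uid, sub.mean(axis=1), n_cells=n, dataset_id=ranked.dataset_id)


def centroids_for_assignment(
    ranked: ExpressionMatrix, assignment: ClusterAssignment, min_cells: int = 50
) -> list[RankCentroid]:
    """Rank centroid for every cluster of one dataset, uid = ``dataset:cN``."""
    out = []
    for c in range(assignment.n_clusters):
        members = assignment.members(c)
        if len(members) < SMALL_CLUSTER_FLAG:
            log.warning("cluster %s:c%d has %d cells (flagged, kept)",
                        assignment.dataset_id, c, len(members))
        out.append(
            compute_rank_centroid(
                ranked, members, f"{assignment.dataset_id}:c{c}", min_cells=min_cells
            )
        )
    return out
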