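"""Meta-clustering of cluster centroids into cell-type exemplars.

Centroid pairs whose RTKE score exceeds the empirical threshold form a
weighted graph; Louvain communities of that graph are the *exemplars*.  A
centroid with no supra-threshold partner stays a singleton exemplar — a cell
type seen in only one dataset is still a cell type.  Exemplar centroids are
the unweighted per-gene mean of their member rank centroids (a cell-count-
weighted mean is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .percluster import RankCentroid
from .rtke import SimilarityMatrix


@dataclass
class ClusterGraph:
    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ExemplarSignature:
    exemplar_id: str
    member_cluster_uids: list[str]
    avg_rank: pd.Series
    n_datasets: int
    annotation: str | None = None


def build_cluster_graph(sm: SimilarityMatrix, threshold: float) -> ClusterGraph:
    """All centroids as nodes; undirected edges strictly above ``threshold``,
    weighted by the RTKE score.  No self-loops."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    g = nx.Graph()
    uids = sm.cluster_uids
    g.add_nodes_from(uids)
    m = sm.scores.to_numpy()
    for i in range(len(uids)):
        for j in range(i + 1, len(uids)):
            if m[i, j] > threshold:
                g.add_edge(uids[i], uids[j], weight=float(m[i, j]))
    return ClusterGraph(g, threshold)


def metacluster(cg: ClusterGraph, seed: int = 0, resolution: float = 1.0) -> dict[str, str]:
    """Louvain communities on the weighted supra-threshold graph.

    Returns cluster_uid -> exemplar_id.  Exemplar ids are X1..Xn in order of
    decreasing member count, ties by smallest member uid; isolated nodes come
    out as singleton exemplars.
    """
    if cg.graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    communities = nx.community.louvain_communities(
        cg.graph, weight="weight", resolution=resolution, seed=seed
    )
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    mapping: dict[str, str] = {}
    for rank, comm in enumerate(ordered, start=1):
        for uid in comm:
            mapping[uid] = f"X{rank}"
    return mapping


def exemplar_centroid(
    members: list[RankCentroid],
    exemplar_id: str = "X1",
    weighted_by_cells: bool = False,
) -> ExemplarSignature:
    """Average the member rank centroids into one exemplar signature."""
    if len(members) == 0:
        raise ValueError("an exemplar needs at least one member")
    genes = list(members[0].avg_rank.index)
    for m in members[1:]:
        if list(m.avg_rank.index) != genes:
            raise ValueError("member centroids must share one gene universe")
    stack = np.vstack([m.avg_rank.to_numpy() for m in members])
    if weighted_by_cells:
        w = np.array([m.n_cells for m in members], dtype=float)
        avg = (stack * w[:, None]).sum(axis=0) / w.sum()
    else:
        avg = stack.mean(axis=0)
    return ExemplarSignature(
        exemplar_id=exemplar_id,
        member_cluster_uids=[m.cluster_uid for m in members],
        avg_rank=pd.Series(avg, index=genes),
        n_datasets=len({m.dataset_id for m in members}),
    )


def exemplars_from_membership(
    centroids: list[RankCentroid],
    membership: dict[str, str],
    weighted_by_cells: bool = False,
) -> list[ExemplarSignature]:
    """Assemble ExemplarSignatures for a metacluster() membership mapping."""
    by_uid = {c.cluster_uid: c for c in centroids}
    missing = set(membership) - set(by_uid)
    if missing:
        raise KeyError(f"membership references unknown centroids: {sorted(missing)[:5]}")
    groups: dict[str, list[RankCentroid]] = {}
    for uid, ex in membership.items():
        groups.setdefault(ex, []).append(by_uid[uid])
    out = []
    for ex_id in sorted(groups, key=lambda x: int(x.lstrip("X"))):
        out.append(exemplar_centroid(groups[ex_id], ex_id, weighted_by_cells))
    return out


def exemplar_matrix(exemplars: list[ExemplarSignature]) -> pd.DataFrame:
    """Genes x exemplars DataFrame of exemplar avg_rank vectors."""
    return pd.DataFrame({e.exemplar_id: e.avg_rank for e in exemplars})
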