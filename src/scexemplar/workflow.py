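"""End-to-end orchestration: datasets -> exemplar signatures -> signature
matrix.  Thin glue over the stage modules; every step is also reachable on
its own."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import RunConfig
from .io import ExpressionMatrix
from .metacluster import (
    ExemplarSignature,
    build_cluster_graph,
    exemplar_matrix,
    exemplars_from_membership,
    metacluster,
)
from .percluster import (
    ClusterAssignment,
    RankCentroid,
    centroids_for_assignment,
    cluster_dataset,
    rank_normalize_cells,
)
from .rtke import SimilarityMatrix, empirical_threshold, pairwise_rtke
from .signatures import signature_matrix_from_exemplars


@dataclass
class ExemplarRun:
    assignments: dict[str, ClusterAssignment]
    centroids: list[RankCentroid]
    similarity: SimilarityMatrix
    threshold: float
    membership: dict[str, str]          # cluster_uid -> exemplar id
    exemplars: list[ExemplarSignature]
    exemplar_matrix: pd.DataFrame       # genes x exemplars
    signature_matrix: pd.DataFrame      # signature genes x exemplars


def derive_exemplars(
    datasets: list[ExpressionMatrix],
    config: RunConfig | None = None,
    precomputed_labels: dict[str, pd.Series] | None = None,
    edge_quantile: float | None = None,
    seed: int | None = None,
) -> ExemplarRun:
    """Cluster every dataset, build rank centroids, link them by RTKE above
    the empirical threshold, Louvain meta-cluster into exemplars, and select
    signature genes.

    ``edge_quantile`` overrides the config's quantile position for the edge
    threshold (useful for small compendia where same-type pairs are not a
    rare tail of the score distribution).
    """
    config = config or RunConfig()
    seed = config.rng_seed if seed is None else seed
    precomputed_labels = precomputed_labels or {}

    assignments: dict[str, ClusterAssignment] = {}
    centroids: list[RankCentroid] = []
    for em in datasets:
        asg = cluster_dataset(
            em, seed=seed, precomputed_labels=precomputed_labels.get(em.dataset_id)
        )
        assignments[em.dataset_id] = asg
        ranked = rank_normalize_cells(em)
        centroids.extend(
            centroids_for_assignment(ranked, asg, min_cells=config.min_cells_per_cluster)
        )

    sim = pairwise_rtke(centroids, fraction=config.top_k_fraction)
    quantile = edge_quantile if edge_quantile is not None else config.edge_quantile
    threshold = empirical_threshold(sim, quantile)
    graph = build_cluster_graph(sim, threshold)
    membership = metacluster(graph, seed=seed)
    exemplars = exemplars_from_membership(centroids, membership)
    ex_matrix = exemplar_matrix(exemplars)
    sig = signature_matrix_from_exemplars(ex_matrix, config.signature_gene_fraction)
    return ExemplarRun(
        assignments=assignments,
        centroids=centroids,
        similarity=sim,
        threshold=threshold,
        membership=membership,
        exemplars=exemplars,
        exemplar_matrix=ex_matrix,
        signature_matrix=sig,
    )
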