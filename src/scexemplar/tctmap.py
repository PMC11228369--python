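"""Tumor cell-type (TCT) map: 2-D layout of samples by exemplar-score
similarity, spatial clustering, and per-disease cluster comparisons.

Samples are connected in a k-nearest-neighbor graph (k = 15) by Pearson
correlation of their exemplar-score vectors and laid out with a seeded
force-directed (Fruchterman-Reingold) algorithm — the same class of layout
as the DrL engine, whose exact positions are not part of the contract.
Clusters on the 2-D plane come from HDBSCAN (minimum cluster size 20 for the
primary map, 50 for comparison maps); HDBSCAN noise points are reported as
"unassigned" and excluded from ARI and survival comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from sklearn.cluster import HDBSCAN
from sklearn.metrics import adjusted_rand_score

from .grouping import GroupAssignment
from .survival import SOSResult, fit_sos, fit_subtype_corrected_sos

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class MapLayout:
    coords: pd.DataFrame  # sample_ids x (x, y)
    seed: int
    knn_k: int

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coords.index)


@dataclass
class SpatialClustering:
    labels: pd.Series  # sample -> 'c0', 'c1', ... or 'unassigned'
    min_cluster_size: int

    @property
    def n_clusters(self) -> int:
        return self.labels[self.labels != UNASSIGNED].nunique()

    @property
    def n_unassigned(self) -> int:
        return int((self.labels == UNASSIGNED).sum())


def layout_samples(
    scores: pd.DataFrame,
    seed: int = 0,
    knn_k: int = 15,
    iterations: int = 100,
) -> MapLayout:
    """Force-directed 2-D layout of a samples x exemplars score matrix."""
    if scores.shape[0] < 10:
        raise ValueError("need at least 10 samples to lay out")
    X = scores.to_numpy(dtype=float)
    if np.ptp(X) == 0:
        raise ValueError("constant score matrix: no structure to lay out")
    # rows with zero variance cannot enter a correlation; jitter-free guard
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("samples with constant score vectors cannot be laid out")
    corr = np.corrcoef(X)
    np.fill_diagonal(corr, -np.inf)
    k = min(knn_k, len(scores) - 1)
    g = nx.Graph()
    g.add_nodes_from(scores.index)
    for i, s in enumerate(scores.index):
        nbrs = np.argpartition(-corr[i], k)[:k]
        for j in nbrs:
            w = (1.0 + corr[i, j]) / 2.0  # map [-1,1] -> [0,1]
            if w > 0:
                g.add_edge(s, scores.index[j], weight=float(w))
    pos = nx.spring_layout(g, weight="weight", seed=seed, iterations=iterations)
    coords = pd.DataFrame(
        [(pos[s][0], pos[s][1]) for s in scores.index],
        index=scores.index, columns=["x", "y"],
    )
    return MapLayout(coords, seed=seed, knn_k=knn_k)


def spatial_clusters(layout: MapLayout, min_cluster_size: int = 20) -> SpatialClustering:
    """HDBSCAN on the 2-D coordinates; noise -> 'unassigned'."""
    xy = layout.coords.to_numpy()
    if len(xy) < min_cluster_size:
        labels = pd.Series(UNASSIGNED, index=layout.coords.index)
        return SpatialClustering(labels, min_cluster_size)
    raw = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(xy)
    labels = pd.Series(
        [UNASSIGNED if l < 0 else f"c{l}" for l in raw], index=layout.coords.index
    )
    return SpatialClustering(labels, min_cluster_size)


def adjusted_rand_index(
    labels_a: pd.Series, labels_b: pd.Series, exclude_unassigned: bool = True
) -> float:
    """Standard pair-counting ARI; samples unassigned in either labeling are
    dropped first.  Two single-cluster labelings agree perfectly (ARI 1)."""
    a, b = labels_a.align(labels_b, join="inner")
    if exclude_unassigned:
        keep = (a != UNASSIGNED) & (b != UNASSIGNED)
        a, b = a[keep], b[keep]
    if len(a) == 0:
        raise ValueError("no co-assigned samples")
    if a.nunique() == 1 and b.nunique() == 1:
        return 1.0
    return float(adjusted_rand_score(a, b))


def cluster_survival_comparisons(
    clustering: SpatialClustering,
    diseases: pd.Series,
    survival: pd.DataFrame,
    subtype_col: str | None = "subtype",
    min_disease_samples: int = 5,
) -> list[SOSResult]:
    """Per-disease Cox comparisons of each qualifying map cluster against the
    disease's largest cluster.

    A cluster qualifies for a disease when it holds >= 5 samples of that
    disease; the comparison is subtype-corrected when ``subtype_col`` is
    given (set it to None inside per-subtype reruns).
    """
    labels = clustering.labels
    labels, diseases = labels.align(diseases, join="inner")
    results: list[SOSResult] = []
    for disease in sorted(diseases.unique()):
        mask = (diseases == disease) & (labels != UNASSIGNED)
        counts = labels[mask].value_counts()
        counts = counts[counts >= min_disease_samples]
        if len(counts) < 2:
            log.info("disease %s occupies < 2 qualifying clusters; skipped", disease)
            continue
        main = counts.index[0]
        for other in counts.index[1:]:
            sel = mask & labels.isin([main, other])
            grp = pd.Series(
                np.where(labels[sel] == other, "up", "down"), index=labels[sel].index
            )
            ga = GroupAssignment(list(grp.index), grp, "median")
            if subtype_col is not None:
                res = fit_subtype_corrected_sos(
                    ga, survival, subtype_col=subtype_col,
                    cohort=disease, exemplar=f"{other}_vs_{main}",
                )
            else:
                res = fit_sos(ga, survival, cohort=disease,
                              exemplar=f"{other}_vs_{main}")
            results.append(res)
    return results


def differential_exemplars(
    scores: pd.DataFrame,
    cluster_a_ids: list[str],
    cluster_b_ids: list[str],
    n_top: int = 3,
) -> pd.DataFrame:
    """Two-sample Student's t per exemplar (a vs b); the ``n_top`` most
    positive and most negative statistics, ties broken lexicographically."""
    if len(cluster_a_ids) < 3 or len(cluster_b_ids) < 3:
        raise ValueError("both clusters need >= 3 samples")
    A = scores.loc[cluster_a_ids]
    B = scores.loc[cluster_b_ids]
    rows = []
    for ex in scores.columns:
        a, b = A[ex].to_numpy(), B[ex].to_numpy()
        if a.var() == 0 and b.var() == 0:
            log.info("exemplar %s has zero variance in both clusters; skipped", ex)
            continue
        stat, p = ttest_ind(a, b, equal_var=True)
        rows.append({"exemplar": ex, "t": float(stat), "p": float(p)})
    if not rows:
        raise ValueError("no exemplar with non-zero variance")
    df = pd.DataFrame(rows)
    df = df.sort_values(["t", "exemplar"], ascending=[False, True]).reset_index(drop=True)
    hi = df.head(n_top).assign(direction="highest")
    lo = df.tail(n_top).iloc[::-1].assign(direction="lowest")
    return pd.concat([hi, lo], ignore_index=True)


def plot_map(
    layout: MapLayout,
    clustering: SpatialClustering | None = None,
    path: str | None = None,
):
    """Static scatter of the map, colored by spatial cluster."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if clustering is None:
        ax.scatter(layout.coords["x"], layout.coords["y"], s=8)
    else:
        for lab, sub in layout.coords.groupby(clustering.labels):
            ax.scatter(sub["x"], sub["y"], s=8,
                       color="lightgrey" if lab == UNASSIGNED else None, label=lab)
        ax.legend(markerscale=2, fontsize=7, loc="best")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
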