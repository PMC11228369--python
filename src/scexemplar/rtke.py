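"""Reciprocal top-K enrichment (RTKE) similarity between rank centroids.

Two centroids are compared through their top-K gene sets (K = a fraction of
the shared gene universe, 10% by default).  The similarity is the -log10
upper-tail hypergeometric probability of observing at least the realized
overlap m between the two sets — symmetric by construction, zero when the
overlap is no better than guaranteed, and computed entirely in log space via
log-gamma sums so large universes never underflow to p = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import mannwhitneyu

from .percluster import RankCentroid

log = logging.getLogger(__name__)

MIN_UNIVERSE = 10
LN10 = math.log(10.0)


@dataclass
class SimilarityMatrix:
    scores: pd.DataFrame  # symmetric, cluster_uids x cluster_uids
    top_k_fraction: float
    gene_universe_size: int

    @property
    def cluster_uids(self) -> list[str]:
        return list(self.scores.index)

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangle scores, diagonal excluded."""
        m = self.scores.to_numpy()
        iu = np.triu_indices_from(m, k=1)
        return m[iu]


def top_k_genes(centroid: RankCentroid | pd.Series, fraction: float) -> list[str]:
    """The ceil(fraction*G) genes with largest avg_rank.

    Boundary ties are broken by lexicographic gene id so selection is
    deterministic; the returned list is itself sorted lexicographically.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    avg_rank = centroid.avg_rank if isinstance(centroid, RankCentroid) else centroid
    g = len(avg_rank)
    if g == 0:
        raise ValueError("empty centroid")
    k = math.ceil(fraction * g)
    order = sorted(avg_rank.items(), key=lambda kv: (-kv[1], kv[0]))
    return sorted(gene for gene, _ in order[:k])


def log_hypergeom_tail(m: int, G: int, K: int, n: int) -> float:
    """ln P(X >= m) for X ~ Hypergeometric(G population, K successes, n draws),
    summed from log-gamma point masses."""

    def logpmf(x: int) -> float:
        return (
            gammaln(K + 1) - gammaln(x + 1) - gammaln(K - x + 1)
            + gammaln(G - K + 1) - gammaln(n - x + 1) - gammaln(G - K - n + x + 1)
            - (gammaln(G + 1) - gammaln(n + 1) - gammaln(G - n + 1))
        )

    lo = max(0, K + n - G)
    hi = min(K, n)
    if m <= lo:
        return 0.0  # P = 1
    if m > hi:
        return -math.inf
    return float(logsumexp([logpmf(x) for x in range(m, hi + 1)]))


def _overlap_score(top_a: list[str], top_b: list[str], G: int) -> float:
    m = len(set(top_a) & set(top_b))
    return -log_hypergeom_tail(m, G, len(top_a), len(top_b)) / LN10


def _ranksum_score(a: pd.Series, b: pd.Series, top_a: list[str], top_b: list[str]) -> float:
    """Mutual rank-sum variant: each centroid's top set is tested for elevated
    ranks in the other centroid (one-sided Mann-Whitney); the two -log10
    p-values are averaged."""

    def one_way(values: pd.Series, top: list[str]) -> float:
        in_top = values.loc[top]
        rest = values.drop(index=top)
        p = mannwhitneyu(in_top, rest, alternative="greater").pvalue
        return -math.log10(max(p, 1e-300))

    return 0.5 * (one_way(b, top_a) + one_way(a, top_b))


def rtke_score(
    a: RankCentroid,
    b: RankCentroid,
    fraction: float = 0.10,
    method: str = "overlap",
) -> float:
    """RTKE similarity between two centroids on their shared gene universe."""
    av, bv = a.avg_rank, b.avg_rank
    if list(av.index) != list(bv.index):
        shared = av.index.intersection(bv.index)
        av, bv = av.loc[shared], bv.loc[shared]
    G = len(av)
    if G < MIN_UNIVERSE:
        raise ValueError(f"shared gene universe has {G} genes (< {MIN_UNIVERSE})")
    top_a = top_k_genes(av, fraction)
    top_b = top_k_genes(bv, fraction)
    if method == "overlap":
        return _overlap_score(top_a, top_b, G)
    if method == "ranksum":
        return _ranksum_score(av, bv, top_a, top_b)
    raise ValueError(f"unknown RTKE method {method!r}")


def pairwise_rtke(
    centroids: list[RankCentroid],
    fraction: float = 0.10,
    method: str = "overlap",
) -> SimilarityMatrix:
    """Full symmetric RTKE matrix over the gene intersection of all centroids.

    The diagonal holds each centroid's self-score (the maximum attainable for
    the universe).  Within-dataset pairs are included.
    """
    if len(centroids) < 2:
        raise ValueError("need at least 2 centroids")
    universe = centroids[0].avg_rank.index
    for c in centroids[1:]:
        universe = universe.intersection(c.avg_rank.index)
    G = len(universe)
    if G < MIN_UNIVERSE:
        raise ValueError(f"gene intersection across datasets has {G} genes (< {MIN_UNIVERSE})")
    uids = [c.cluster_uid for c in centroids]
    if len(set(uids)) != len(uids):
        raise ValueError("duplicate cluster_uids")

    restricted = [c.avg_rank.loc[universe] for c in centroids]
    tops = [top_k_genes(v, fraction) for v in restricted]
    n = len(centroids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if method == "overlap":
                s = _overlap_score(tops[i], tops[j], G)
            else:
                s = _ranksum_score(restricted[i], restricted[j], tops[i], tops[j])
            mat[i, j] = mat[j, i] = s
    return SimilarityMatrix(
        pd.DataFrame(mat, index=uids, columns=uids),
        top_k_fraction=fraction,
        gene_universe_size=G,
    )


def empirical_threshold(sm: SimilarityMatrix, quantile: float = 0.994) -> float:
    """Quantile of the off-diagonal score distribution (linear interpolation).

    ``quantile`` is the position: 0.994 keeps the upper 0.006 tail as edges.
    """
    if not 0 < quantile <= 1:
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    off = sm.offdiagonal()
    if off.size < 1:
        raise ValueError("no off-diagonal pairs")
    if np.ptp(off) == 0:
        log.warning("degenerate similarity distribution: all off-diagonal scores equal %g",
                    off[0])
        return float(off[0])
    return float(np.quantile(off, quantile, method="linear"))
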