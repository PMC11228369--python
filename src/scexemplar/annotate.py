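"""Exemplar annotation by gene-set enrichment.

Gene-set collections (GMT) are filtered to sets with more than 50 and fewer
than 100 member genes (sizes measured after deduplication and intersection
with the gene universe) — small enough to be specific, large enough to be
robust.  Each surviving set is scored against an exemplar by a preranked
running-sum enrichment statistic on the exemplar's avg_rank ordering; the
five best-scoring sets annotate the exemplar.

The hit weight is the gene's rank *standing* within the exemplar (exponent
1), not the raw avg_rank value, so the score is invariant to any strictly
monotone transform of avg_rank.  ``classic=True`` drops the weighting
entirely (equal hit increments).  No permutation p-values: the scores are
used only to rank sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

MIN_SET_SIZE = 50   # strict: size must be > 50
MAX_SET_SIZE = 100  # strict: size must be < 100


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, source: str = "") -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, genes...)."""
    from gseapy.parser import read_gmt as _read_gmt

    sets = {name: list(genes) for name, genes in _read_gmt(str(path)).items()}
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return GeneSetCollection(sets, source=source or Path(path).stem)


def filter_gene_sets(
    collection: GeneSetCollection, universe: list[str] | None = None
) -> GeneSetCollection:
    """Keep sets with 50 < size < 100 genes (deduplicated, intersected with
    the universe when given)."""
    uni = set(universe) if universe is not None else None
    kept: dict[str, list[str]] = {}
    for name, genes in collection.sets.items():
        dedup = sorted(set(genes))
        if uni is not None:
            dedup = [g for g in dedup if g in uni]
        if MIN_SET_SIZE < len(dedup) < MAX_SET_SIZE:
            kept[name] = dedup
    if not kept:
        raise ValueError(
            "no gene set has 50 < size < 100 after filtering; "
            "try a different collection"
        )
    return GeneSetCollection(kept, source=collection.source)


def enrichment_score(
    avg_rank: pd.Series, gene_set: list[str], classic: bool = False
) -> float:
    """Signed maximum deviation of the preranked running sum.

    Genes are walked in decreasing avg_rank order (ties by gene id); hits
    advance the sum by their normalized weight, misses retreat by
    1/(G - n_hits).
    """
    genes = avg_rank.index
    in_set = genes.isin(set(gene_set))
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise ValueError("gene set has no genes in the universe")
    G = len(genes)
    if n_hits == G:
        return 1.0
    values = np.asarray(avg_rank, dtype=float)
    order = np.lexsort((genes.to_numpy(), -values))
    hit = np.asarray(in_set)[order]
    if classic:
        w = np.ones(G)
    else:
        w = rankdata(values, method="average")[order]
    inc = np.where(hit, w, 0.0)
    inc_sum = inc.sum()
    step = np.where(hit, inc / inc_sum, -1.0 / (G - n_hits))
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def annotate_exemplar(
    avg_rank: pd.Series,
    collection: GeneSetCollection,
    top: int = 5,
    classic: bool = False,
    author_label: str | None = None,
) -> pd.DataFrame:
    """Score every set, rank descending (ties lexicographic by set name) and
    keep the top five.  An author-provided label, when available, is carried
    through as-is — it takes precedence over inferred annotations downstream.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    rows = []
    for name in sorted(collection.sets):
        genes_present = [g for g in collection.sets[name] if g in avg_rank.index]
        if not genes_present:
            log.info("gene set %s has no genes in the universe; skipped", name)
            continue
        es = enrichment_score(avg_rank, genes_present, classic=classic)
        rows.append({"set": name, "es": es, "n_genes": len(genes_present)})
    if not rows:
        raise ValueError("no gene set overlaps the exemplar's gene universe")
    df = pd.DataFrame(rows).sort_values(
        ["es", "set"], ascending=[False, True]
    ).reset_index(drop=True)
    out = df.head(top).copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    out["author_label"] = author_label or ""
    return out
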