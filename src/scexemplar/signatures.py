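"""Signature-gene selection by the max-minus-second-max gap score.

For every gene, the gap score is the difference between its value in the
highest exemplar and in the second-highest exemplar; genes with equal maxima
in two exemplars get gap 0.  The top fraction (20% by default) of genes by
gap, over the common gene universe, become the deconvolution signature genes.
Exemplar values here are average ranks — the pipeline is rank-based end to
end, so ranks are the expression scale at this stage.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def gap_scores(exemplar_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (gap, argmax exemplar) over a genes x exemplars matrix."""
    if exemplar_matrix.shape[1] < 2:
        raise ValueError("gap scores need at least 2 exemplars")
    vals = exemplar_matrix.to_numpy(dtype=float)
    part = np.sort(vals, axis=1)
    top, second = part[:, -1], part[:, -2]
    gap = top - second
    gap[np.isclose(top, second)] = 0.0
    argmax = exemplar_matrix.columns[np.argmax(vals, axis=1)]
    return pd.DataFrame(
        {"gap": gap, "argmax_exemplar": argmax}, index=exemplar_matrix.index
    )


def select_signature_genes(gaps: pd.DataFrame, fraction: float = 0.20) -> list[str]:
    """The ceil(fraction*G) genes with largest gap; boundary ties broken
    lexicographically by gene id.  Returns a lexicographically sorted list."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    g = len(gaps)
    k = math.ceil(fraction * g)
    if gaps["gap"].nunique() == 1:
        log.warning("all gap scores equal (%g); selection is lexicographic only",
                    gaps["gap"].iloc[0])
    order = sorted(gaps["gap"].items(), key=lambda kv: (-kv[1], kv[0]))
    return sorted(gene for gene, _ in order[:k])


def build_signature_matrix(
    exemplar_matrix: pd.DataFrame, selected_genes: list[str]
) -> pd.DataFrame:
    """Restrict the exemplar matrix to the selected signature genes
    (column order preserved)."""
    if len(selected_genes) == 0:
        raise ValueError("empty signature gene selection")
    missing = [g for g in selected_genes if g not in exemplar_matrix.index]
    if missing:
        raise KeyError(f"selected genes not in exemplar matrix: {missing[:5]}")
    return exemplar_matrix.loc[list(selected_genes)]


def signature_matrix_from_exemplars(
    exemplar_matrix: pd.DataFrame, fraction: float = 0.20
) -> pd.DataFrame:
    """gap_scores -> select_signature_genes -> build_signature_matrix."""
    gaps = gap_scores(exemplar_matrix)
    return build_signature_matrix(exemplar_matrix, select_signature_genes(gaps, fraction))
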