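"""Synthetic study inputs with recorded ground truth.

Three generators, all fully deterministic under a seed:

* ``simulate_compendium`` — several scRNA-seq count datasets sharing planted
  cell types.  Type profiles are log-normal baselines with disjoint
  upregulated marker blocks; every dataset applies its own strictly monotone
  power distortion plus gene-wise multiplicative factors (a batch-effect
  stand-in that preserves within-cell ranks, the invariant the rank-centroid
  pipeline exploits) and samples negative-binomial counts.
* ``simulate_mixtures`` — in-silico bulk mixtures: components are quantile
  normalized to a common reference, a designated tumor component receives an
  integer percentage drawn uniformly from 50-90, the remainder is split
  across the other components in non-negative integer percentages
  (symmetric-Dirichlet draw with largest-remainder rounding), and optional
  multiplicative log-normal noise is applied.
* ``simulate_survival`` — exponential event times whose hazard is multiplied
  by a planted hazard ratio for "up" samples, with independent uniform
  censoring tuned to an approximate target censoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ExpressionMatrix

DEFAULT_GENES = 300
DEFAULT_CELLS_PER_TYPE = 80
DEFAULT_MARKER_FRAC = 0.05
DEFAULT_MARKER_STRENGTH = 8.0
DEFAULT_DISPERSION = 0.3
DEFAULT_NOISE_CV = 0.1
TUMOR_FRAC_RANGE = (50, 90)  # integer percentages, inclusive


@dataclass
class CompendiumTruth:
    cell_types: dict[str, pd.Series]       # dataset_id -> cell_id -> type name
    type_profiles: pd.DataFrame            # genes x types, expected expression
    distortions: dict[str, float]          # dataset_id -> power exponent
    marker_blocks: dict[str, list[str]]    # type -> marker gene ids
    seed: int = 0

    def cluster_truth(self, assignments: dict) -> pd.Series:
        """Dominant planted type of every (dataset, cluster) pair, for
        comparing exemplar membership against truth."""
        out = {}
        for ds, asg in assignments.items():
            truth = self.cell_types[ds]
            for c in range(asg.n_clusters):
                members = asg.members(c)
                out[f"{ds}:c{c}"] = truth.loc[members].mode().iloc[0]
        return pd.Series(out)


@dataclass
class MixtureTruth:
    proportions: pd.DataFrame  # mixtures x components, integer percentages
    tumor_id: str
    seed: int = 0

    def fractions(self) -> pd.DataFrame:
        return self.proportions / 100.0


def simulate_compendium(
    n_types: int = 3,
    n_datasets: int = 4,
    n_genes: int = DEFAULT_GENES,
    cells_per_type: int = DEFAULT_CELLS_PER_TYPE,
    marker_frac: float = DEFAULT_MARKER_FRAC,
    marker_strength: float = DEFAULT_MARKER_STRENGTH,
    distortion: float = 1.0,
    dispersion: float = DEFAULT_DISPERSION,
    types_per_dataset: int | None = None,
    seed: int = 0,
) -> tuple[list[ExpressionMatrix], CompendiumTruth]:
    """Generate ``n_datasets`` count matrices sharing ``n_types`` cell types.

    ``distortion`` scales the dataset-specific batch effects: the power
    exponent is exp(U(-ln2, ln2) * distortion) (so in [0.5, 2] at level 1)
    and gene-wise factors are LogNormal(0, 0.3 * distortion).  At level 0
    every dataset sees the undistorted profiles.
    """
    if n_types < 2 or n_datasets < 1:
        raise ValueError("need n_types >= 2 and n_datasets >= 1")
    if n_genes < 200:
        raise ValueError("need n_genes >= 200")
    n_markers = int(np.ceil(marker_frac * n_genes))
    if n_markers * n_types > n_genes:
        raise ValueError("marker blocks exceed the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    types = [f"type{t}" for t in range(n_types)]

    baseline = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)
    profiles = pd.DataFrame(
        np.tile(baseline[:, None], (1, n_types)), index=genes, columns=types
    )
    marker_blocks: dict[str, list[str]] = {}
    for t, name in enumerate(types):
        block = genes[t * n_markers : (t + 1) * n_markers]
        profiles.loc[block, name] *= marker_strength
        marker_blocks[name] = block

    datasets, cell_types, distortions = [], {}, {}
    for d in range(n_datasets):
        ds_id = f"ds{d}"
        if types_per_dataset is None or types_per_dataset >= n_types:
            ds_types = types
        else:
            k = max(2, types_per_dataset)
            ds_types = sorted(rng.choice(types, size=k, replace=False))
        exponent = float(np.exp(rng.uniform(-np.log(2), np.log(2)) * distortion))
        gene_factor = rng.lognormal(mean=0.0, sigma=0.3 * distortion, size=n_genes)
        cols, labels, ids = [], [], []
        for name in ds_types:
            mean = profiles[name].to_numpy() ** exponent * gene_factor
            mean = mean / mean.sum() * 2000.0  # common library depth
            r = 1.0 / dispersion
            p = r / (r + mean)
            counts = rng.negative_binomial(r, p, size=(cells_per_type, n_genes))
            for i in range(cells_per_type):
                ids.append(f"{ds_id}_{name}_cell{i}")
                labels.append(name)
                cols.append(counts[i])
        data = pd.DataFrame(np.array(cols).T, index=genes, columns=ids)
        datasets.append(ExpressionMatrix(data, unit="counts", dataset_id=ds_id))
        cell_types[ds_id] = pd.Series(labels, index=ids)
        distortions[ds_id] = exponent
    truth = CompendiumTruth(cell_types, profiles, distortions, marker_blocks, seed)
    return datasets, truth


MIXTURE_COMPONENTS = (
    "tumor", "b_cells", "dendritic", "nk_cells", "endothelial",
    "fibroblasts", "macrophages", "mast_cells", "myocytes", "t_cells",
)


def simulate_component_centroids(
    components: tuple[str, ...] = MIXTURE_COMPONENTS,
    n_genes: int = 600,
    marker_frac: float = 0.08,
    marker_strength: float = DEFAULT_MARKER_STRENGTH,
    seed: int = 0,
) -> pd.DataFrame:
    """Pure cell-type expression centroids (genes x components) for the
    in-silico mixture protocol: a shared log-normal baseline with a disjoint
    upregulated marker block per component."""
    n_markers = int(np.ceil(marker_frac * n_genes))
    if n_markers * len(components) > n_genes:
        raise ValueError("marker blocks exceed the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    baseline = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)
    out = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(components))), index=genes,
        columns=list(components),
    )
    for t, name in enumerate(components):
        out.iloc[t * n_markers : (t + 1) * n_markers, t] *= marker_strength
    return out


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Map every column onto the mean-of-sorted-columns reference."""
    arr = df.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[order[:, j], j] = ref
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _integer_partition(total: int, n_parts: int, rng: np.random.Generator) -> np.ndarray:
    """Non-negative integers summing to ``total``: symmetric Dirichlet draw
    rounded with largest-remainder correction."""
    if n_parts == 0:
        return np.zeros(0, dtype=int)
    raw = rng.dirichlet(np.ones(n_parts)) * total
    floors = np.floor(raw).astype(int)
    short = total - floors.sum()
    remainders = raw - floors
    top_up = np.argsort(-remainders, kind="stable")[:short]
    floors[top_up] += 1
    return floors


def simulate_mixtures(
    centroids: pd.DataFrame,
    tumor_id: str,
    n: int = 200,
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int = 0,
) -> tuple[ExpressionMatrix, MixtureTruth]:
    """In-silico bulk mixtures from component expression centroids
    (genes x components)."""
    if centroids.shape[1] < 2:
        raise ValueError("need at least 2 components")
    if tumor_id not in centroids.columns:
        raise KeyError(f"tumor component {tumor_id!r} not among centroids")
    rng = np.random.default_rng(seed)
    qn = quantile_normalize(centroids)
    others = [c for c in qn.columns if c != tumor_id]
    lo, hi = TUMOR_FRAC_RANGE

    props = np.zeros((n, centroids.shape[1]), dtype=int)
    mixtures = np.zeros((centroids.shape[0], n))
    col_idx = {c: i for i, c in enumerate(qn.columns)}
    for m in range(n):
        tumor = int(rng.integers(lo, hi + 1))
        rest = _integer_partition(100 - tumor, len(others), rng)
        props[m, col_idx[tumor_id]] = tumor
        for c, v in zip(others, rest):
            props[m, col_idx[c]] = v
        mix = qn.to_numpy() @ (props[m] / 100.0)
        if noise_cv > 0:
            sig2 = np.log1p(noise_cv**2)
            noise = rng.lognormal(mean=-sig2 / 2, sigma=np.sqrt(sig2),
                                  size=len(mix))
            mix = mix * noise
        mixtures[:, m] = mix
    names = [f"mix{m:04d}" for m in range(n)]
    em = ExpressionMatrix(
        pd.DataFrame(mixtures, index=centroids.index, columns=names),
        unit="TPM", dataset_id="mixtures",
    )
    truth = MixtureTruth(
        pd.DataFrame(props, index=names, columns=qn.columns), tumor_id, seed
    )
    return em, truth


def _censor_horizon(hazards: np.ndarray, censor_frac: float) -> float:
    """Uniform-censoring horizon c with marginal P(censored) ~= censor_frac
    over a population of exponential event times with the given hazards.
    P(U < T) = (1 - exp(-h c)) / (h c) for U ~ Uniform(0, c), decreasing in c.
    """

    def p_cens(c: float) -> float:
        hc = hazards * c
        return float(np.mean((1.0 - np.exp(-hc)) / hc))

    h = float(np.mean(hazards))
    lo, hi = 1e-9 / h, 1e9 / h
    return brentq(lambda c: p_cens(c) - censor_frac, lo, hi)


def simulate_survival(
    groups: pd.Series,
    baseline_hazard: float = 1 / 1000.0,
    hr: float = 3.0,
    censor_frac: float = 0.2,
    subtype: pd.Series | None = None,
    subtype_hrs: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Survival records for samples labeled 'up'/'down' (and optionally by
    subtype with its own hazard multipliers)."""
    if hr <= 0 or baseline_hazard <= 0:
        raise ValueError("hazards must be positive")
    if not 0 <= censor_frac < 1:
        raise ValueError("censor_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    hazard = pd.Series(baseline_hazard, index=groups.index, dtype=float)
    hazard[groups == "up"] *= hr
    if subtype is not None and subtype_hrs:
        for level, mult in subtype_hrs.items():
            hazard[subtype == level] *= mult
    t_event = rng.exponential(1.0 / hazard.to_numpy())
    if censor_frac > 0:
        horizon = _censor_horizon(hazard.to_numpy(), censor_frac)
        t_cens = rng.uniform(0, horizon, size=len(groups))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(groups), dtype=int)
    out = pd.DataFrame(
        {
            "sample_id": groups.index,
            "time": np.maximum(time, 1e-9),
            "event": event,
            "cohort": "synthetic",
        }
    )
    if subtype is not None:
        out["subtype"] = subtype.loc[groups.index].to_numpy()
    return out
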