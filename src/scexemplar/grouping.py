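"""Patient stratification by the signature-cohort bimodality test.

For one exemplar's normalized deconvolution scores within one cohort, the
decision tree is:

1. fewer than 10 samples with a positive score -> the pair is *excluded*;
2. zeros in more than half the samples -> *zero split*: zero scores are
   "patients-down", positive scores "patients-up";
3. otherwise, 1- and 2-component Student-t mixtures are fit by EM and
   compared by BIC; if the 2-component model wins, samples above the upper
   component mean are "up", below the lower component mean are "down", and
   samples strictly between the two means stay unassigned;
4. otherwise the cohort is split at the median (exact-median samples go
   "down").

The t mixture uses fixed degrees of freedom nu = 4 by default (estimating nu
is unstable at cohort-sized n; a flag enables it), EM with 5 random restarts,
and BIC = -2*loglik + p*ln(n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp
from scipy.stats import t as t_dist

log = logging.getLogger(__name__)

RULES = ("bimodal", "median", "zero_split", "excluded")
MIN_SAMPLES = 20
MIN_POSITIVE = 10
_SIGMA_FLOOR_REL = 1e-8


@dataclass
class TMixtureFit:
    k: int
    mu: np.ndarray
    sigma: np.ndarray
    df: np.ndarray
    weight: np.ndarray
    loglik: float
    bic: float
    n: int
    converged: bool = True
    degenerate: bool = False

    def component_order(self) -> np.ndarray:
        return np.argsort(self.mu)


@dataclass
class GroupAssignment:
    sample_ids: list[str]
    labels: pd.Series  # 'up' / 'down' / 'unassigned'
    rule: str
    cutpoints: tuple[float, ...] = ()
    fits: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")
        bad = set(self.labels.unique()) - {"up", "down", "unassigned"}
        if bad:
            raise ValueError(f"invalid labels {bad}")
        if self.rule == "excluded" and (self.labels != "unassigned").any():
            raise ValueError("excluded rule implies all samples unassigned")

    @property
    def n_up(self) -> int:
        return int((self.labels == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.labels == "down").sum())


def _t_logpdf(x: np.ndarray, mu: float, sigma: float, df: float) -> np.ndarray:
    return t_dist.logpdf(x, df=df, loc=mu, scale=sigma)


def _estimate_df(tau: np.ndarray, u: np.ndarray, df_old: float) -> float:
    """ECME update for one component's degrees of freedom: solve the standard
    score equation on a bracketed grid (bisection via np.interp on f(nu))."""
    w = tau.sum()
    if w <= 0:
        return df_old
    c = 1.0 + (tau * (np.log(u) - u)).sum() / w + digamma((df_old + 1) / 2) - np.log(
        (df_old + 1) / 2
    )

    def f(nu: float) -> float:
        return -digamma(nu / 2) + np.log(nu / 2) + c

    grid = np.linspace(0.6, 200.0, 400)
    vals = np.array([f(v) for v in grid])
    sign_change = np.where(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        return float(grid[np.argmin(np.abs(vals))])
    i = sign_change[0]
    a, b = grid[i], grid[i + 1]
    for _ in range(50):
        mid = 0.5 * (a + b)
        if f(a) * f(mid) <= 0:
            b = mid
        else:
            a = mid
    return float(0.5 * (a + b))


def _em_once(
    x: np.ndarray,
    k: int,
    mu0: np.ndarray,
    df: float,
    estimate_df: bool,
    max_iter: int,
    tol: float,
) -> TMixtureFit:
    n = len(x)
    scale = max(float(x.std()), _SIGMA_FLOOR_REL)
    floor = _SIGMA_FLOOR_REL * max(1.0, float(np.abs(x).max()))
    mu = mu0.astype(float).copy()
    sigma = np.full(k, scale)
    nu = np.full(k, float(df))
    pi = np.full(k, 1.0 / k)
    ll_old, converged, degenerate = -np.inf, False, False
    for _ in range(max_iter):
        logp = np.stack(
            [np.log(pi[j]) + _t_logpdf(x, mu[j], sigma[j], nu[j]) for j in range(k)]
        )
        norm = logsumexp(logp, axis=0)
        ll = float(norm.sum())
        tau = np.exp(logp - norm)  # responsibilities, k x n
        delta2 = ((x[None, :] - mu[:, None]) / sigma[:, None]) ** 2
        u = (nu[:, None] + 1) / (nu[:, None] + delta2)  # gamma-scale weights
        tw = tau.sum(axis=1)
        pi = tw / n
        for j in range(k):
            wj = tau[j] * u[j]
            mu[j] = (wj * x).sum() / max(wj.sum(), 1e-300)
            var = (wj * (x - mu[j]) ** 2).sum() / max(tw[j], 1e-300)
            sigma[j] = np.sqrt(max(var, floor**2))
            if sigma[j] <= floor * 1.001:
                degenerate = True
            if estimate_df:
                nu[j] = _estimate_df(tau[j], u[j], nu[j])
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    p = (k - 1) + 2 * k + (k if estimate_df else 0)
    bic = -2 * ll_old + p * np.log(n)
    return TMixtureFit(
        k=k, mu=mu, sigma=sigma, df=nu, weight=pi,
        loglik=ll_old, bic=bic, n=n, converged=converged, degenerate=degenerate,
    )


def fit_t_mixture(
    values,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    df: float = 4.0,
    estimate_df: bool = False,
    n_restarts: int = 5,
) -> TMixtureFit:
    """EM fit of a k-component Student-t mixture (k in {1, 2}).

    Runs ``n_restarts`` seeded random initializations and keeps the best
    log-likelihood.  Constant input hits the scale floor and is returned with
    ``degenerate=True``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} finite values, got {len(x)}")
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    rng = np.random.default_rng(seed)
    best: TMixtureFit | None = None
    for r in range(n_restarts):
        if k == 1:
            mu0 = np.array([x.mean()])
        elif r == 0:
            mu0 = np.quantile(x, [0.25, 0.75])  # deterministic spread start
        else:
            mu0 = rng.choice(x, size=2, replace=False)
        fit = _em_once(x, k, mu0, df, estimate_df, max_iter, tol)
        if best is None or fit.loglik > best.loglik:
            best = fit
        if k == 1:
            break
    if not best.converged:
        log.warning("t-mixture EM (k=%d) did not converge in %d iterations", k, max_iter)
    return best


def is_bimodal(values, seed: int = 0, **fit_kwargs) -> tuple[bool, TMixtureFit, TMixtureFit]:
    """BIC comparison: bimodal iff BIC(k=2) < BIC(k=1)."""
    fit1 = fit_t_mixture(values, k=1, seed=seed, **fit_kwargs)
    fit2 = fit_t_mixture(values, k=2, seed=seed, **fit_kwargs)
    return fit2.bic < fit1.bic, fit1, fit2


def split_samples(
    scores: pd.Series,
    seed: int = 0,
    min_positive: int = MIN_POSITIVE,
    strict_high_rule: bool = False,
    **fit_kwargs,
) -> GroupAssignment:
    """Apply the bimodality decision tree to one (exemplar, cohort) score
    vector.  ``strict_high_rule`` additionally requires >= ``min_positive``
    non-zero scores inside the resulting "up" group."""
    scores = scores.astype(float)
    ids = list(scores.index)
    n = len(scores)
    unassigned = pd.Series("unassigned", index=scores.index)

    if n < MIN_SAMPLES:
        log.warning("only %d samples (< %d); pair excluded", n, MIN_SAMPLES)
        return GroupAssignment(ids, unassigned, "excluded")
    n_pos = int((scores > 0).sum())
    if n_pos < min_positive:
        return GroupAssignment(ids, unassigned, "excluded")

    n_zero = int((scores == 0).sum())
    if n_zero > 0.5 * n:
        labels = pd.Series(
            np.where(scores > 0, "up", "down"), index=scores.index
        )
        return GroupAssignment(ids, labels, "zero_split", cutpoints=(0.0,))

    bimodal, fit1, fit2 = is_bimodal(scores.to_numpy(), seed=seed, **fit_kwargs)
    fits = {"k1": fit1, "k2": fit2}
    if bimodal:
        lo, hi = np.sort(fit2.mu)
        labels = pd.Series("unassigned", index=scores.index)
        labels[scores > hi] = "up"
        labels[scores < lo] = "down"
        ga = GroupAssignment(ids, labels, "bimodal", cutpoints=(float(lo), float(hi)),
                             fits=fits)
    else:
        med = float(scores.median())
        labels = pd.Series(np.where(scores > med, "up", "down"), index=scores.index)
        ga = GroupAssignment(ids, labels, "median", cutpoints=(med,), fits=fits)

    if strict_high_rule:
        n_up_pos = int(((ga.labels == "up") & (scores > 0)).sum())
        if n_up_pos < min_positive:
            return GroupAssignment(ids, unassigned, "excluded", fits=fits)
    return ga


def split_all(
    scores: pd.DataFrame,
    cohorts: pd.Series,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Run split_samples for every (exemplar, cohort) pair.

    ``scores``: samples x exemplars normalized deconvolution scores;
    ``cohorts``: per-sample cohort label.  Returns a long table with columns
    cohort, exemplar, sample, label, rule, cutpoints.
    """
    rows = []
    for cohort in sorted(cohorts.unique()):
        members = cohorts.index[cohorts == cohort]
        for ex in scores.columns:
            ga = split_samples(scores.loc[members, ex], seed=seed, **kwargs)
            cut = ";".join(f"{c:.6g}" for c in ga.cutpoints)
            for s in ga.sample_ids:
                rows.append((cohort, ex, s, ga.labels[s], ga.rule, cut))
    return pd.DataFrame(
        rows, columns=["cohort", "exemplar", "sample", "label", "rule", "cutpoints"]
    )
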