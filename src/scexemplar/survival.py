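"""Signature outcome separation (SOS): survival difference between the
"patients-up" and "patients-down" groups of one exemplar in one cohort.

The naive SOS is a univariate Cox proportional-hazards model on the binary
group indicator; its p-value is the log-rank test (the Wald p is also kept).
The subtype-corrected SOS adds the published molecular subtype as a one-hot
categorical covariate (reference level = largest subtype) and reports the
Wald p of the group coefficient, since the log-rank test cannot adjust for
covariates.  Ties in event times use the Efron approximation (the lifelines
default).  HR > 1 means the "up" group fares worse.  BH FDR is applied across
all tested exemplar-cohort pairs per model family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .grouping import GroupAssignment

log = logging.getLogger(__name__)


@dataclass
class SOSResult:
    cohort: str
    exemplar: str
    n_up: int
    n_down: int
    hazard_ratio: float
    p_value: float          # log-rank (naive) or Wald (subtype-corrected)
    p_wald: float
    model: str              # 'naive' | 'subtype_corrected'
    q_value: float = np.nan
    flags: list = field(default_factory=list)

    @property
    def significant_05(self) -> bool:
        return bool(self.p_value < 0.05)

    @property
    def significant_001(self) -> bool:
        return bool(self.p_value < 0.001)


def _merged_frame(groups: GroupAssignment, survival: pd.DataFrame) -> pd.DataFrame:
    df = survival.set_index("sample_id") if "sample_id" in survival.columns else survival
    keep = groups.labels[groups.labels.isin(["up", "down"])]
    merged = df.loc[df.index.intersection(keep.index)].copy()
    merged["up"] = (keep.loc[merged.index] == "up").astype(int)
    return merged


def fit_sos(
    groups: GroupAssignment,
    survival: pd.DataFrame,
    cohort: str = "",
    exemplar: str = "",
) -> SOSResult:
    """Univariate Cox PH of up vs down; log-rank p-value."""
    df = _merged_frame(groups, survival)
    flags = []
    n_up = int((df["up"] == 1).sum())
    n_down = int((df["up"] == 0).sum())
    ev_up = int(df.loc[df["up"] == 1, "event"].sum())
    ev_down = int(df.loc[df["up"] == 0, "event"].sum())
    if min(n_up, n_down) == 0 or min(ev_up, ev_down) < 2:
        flags.append("unstable")
    if min(ev_up, ev_down) == 0:
        flags.append("zero_events_in_group")

    hr, p_wald = np.nan, np.nan
    try:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[["time", "event", "up"]], duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["up"]))
        p_wald = float(cph.summary.loc["up", "p"])
    except (ConvergenceError, ValueError):
        # complete separation or flat likelihood: ridge-penalized fallback
        flags.append("penalized_fallback")
        try:
            cph = CoxPHFitter(penalizer=0.1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df[["time", "event", "up"]], duration_col="time", event_col="event")
            hr = float(np.exp(cph.params_["up"]))
            p_wald = float(cph.summary.loc["up", "p"])
        except (ConvergenceError, ValueError):
            flags.append("fit_failed")

    up, down = df[df["up"] == 1], df[df["up"] == 0]
    if len(up) and len(down):
        p_lr = float(
            logrank_test(up["time"], down["time"], up["event"], down["event"]).p_value
        )
    else:
        p_lr = np.nan
    return SOSResult(cohort, exemplar, n_up, n_down, hr, p_lr, p_wald, "naive",
                     flags=flags)


def fit_subtype_corrected_sos(
    groups: GroupAssignment,
    survival: pd.DataFrame,
    subtype_col: str = "subtype",
    cohort: str = "",
    exemplar: str = "",
) -> SOSResult:
    """Cox PH with group + one-hot subtype (reference = largest subtype);
    Wald p of the group coefficient."""
    df = _merged_frame(groups, survival)
    if subtype_col not in df.columns:
        raise KeyError(f"survival table lacks a {subtype_col!r} column")
    levels = df[subtype_col].value_counts()
    if len(levels) < 2:
        res = fit_sos(groups, survival, cohort, exemplar)
        res.model = "subtype_corrected"
        res.flags.append("single_subtype_naive_equivalent")
        res.p_value = res.p_wald  # corrected family reports Wald p
        return res
    reference = levels.index[0]
    dummies = pd.get_dummies(df[subtype_col], prefix="st", dtype=float).drop(
        columns=f"st_{reference}"
    )
    X = pd.concat([df[["time", "event", "up"]], dummies], axis=1)

    n_up = int((df["up"] == 1).sum())
    n_down = int((df["up"] == 0).sum())
    flags = []
    # perfect collinearity: group constant within every subtype level
    if (df.groupby(subtype_col)["up"].nunique() <= 1).all():
        flags.append("subtype_collinear")
        return SOSResult(cohort, exemplar, n_up, n_down, np.nan, np.nan, np.nan,
                         "subtype_corrected", flags=flags)
    hr, p_wald = np.nan, np.nan
    try:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(X, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["up"]))
        p_wald = float(cph.summary.loc["up", "p"])
    except (ConvergenceError, ValueError):
        flags.append("penalized_fallback")
        try:
            cph = CoxPHFitter(penalizer=0.1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(X, duration_col="time", event_col="event")
            hr = float(np.exp(cph.params_["up"]))
            p_wald = float(cph.summary.loc["up", "p"])
        except (ConvergenceError, ValueError):
            flags.append("fit_failed")
    return SOSResult(cohort, exemplar, n_up, n_down, hr, p_wald, p_wald,
                     "subtype_corrected", flags=flags)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-invariant)."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(results: list[SOSResult]) -> list[SOSResult]:
    """BH within each model family across all exemplar-cohort pairs."""
    for model in {r.model for r in results}:
        fam = [r for r in results if r.model == model and np.isfinite(r.p_value)]
        if not fam:
            continue
        q = fdr_adjust([r.p_value for r in fam])
        for r, qi in zip(fam, q):
            r.q_value = float(qi)
    return results


def results_table(results: list[SOSResult]) -> pd.DataFrame:
    rows = [
        {
            "cohort": r.cohort, "exemplar": r.exemplar, "model": r.model,
            "n_up": r.n_up, "n_down": r.n_down, "HR": r.hazard_ratio,
            "p": r.p_value, "p_wald": r.p_wald, "q": r.q_value,
            "sig_05": r.significant_05, "sig_001": r.significant_001,
            "flags": ";".join(r.flags),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def km_summary(groups: GroupAssignment, survival: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit curves per group with at-risk counts."""
    df = _merged_frame(groups, survival)
    out = []
    for name, sub in df.groupby("up"):
        label = "up" if name == 1 else "down"
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"], label=label)
        ev = km.event_table
        surv = km.survival_function_[label]
        for t in ev.index:
            out.append(
                {
                    "group": label,
                    "time": float(t),
                    "at_risk": int(ev.loc[t, "at_risk"]),
                    "events": int(ev.loc[t, "observed"]),
                    "survival": float(surv.loc[t]),
                }
            )
    return pd.DataFrame(out)
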