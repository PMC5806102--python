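"""Survival evaluation: time-dependent ROC (NNE), KM, HR, concordance.

Time-dependent ROC follows the cumulative-case / dynamic-control
construction: at horizon t, cases are samples with an event by t and
controls are samples surviving past t.  Under right censoring these states
are not observed for everyone, so the conditional survival S(t | marker)
is estimated with a nearest-neighbor (NNE) smoother — a weighted
Kaplan-Meier over the symmetric neighborhood of each sample in marker
rank — and case/control probabilities are read off the smoothed bivariate
distribution.  This keeps the estimated curve monotone and invariant to
monotone transforms of the marker.

Group comparison (hazard ratio with Wald CI, log-rank p) and the
Kaplan-Meier estimator are delegated to lifelines; Harrell's concordance
index is computed by a vectorized pairwise routine with a leave-one-out
jackknife standard error, and C-index differences are compared by a paired
bootstrap over samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)


def default_span(n: int) -> float:
    """Conventional NNE smoothing span 0.25 * n^(-0.20)."""
    return 0.25 * n ** (-0.20)


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit survival curve: right-continuous step function, S(0)=1."""

    times: np.ndarray       # distinct event/censoring times, increasing
    survival: np.ndarray    # S(t) just after each time
    at_risk: np.ndarray

    def __call__(self, t: Union[float, np.ndarray]) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.r_[1.0, self.survival]
        return padded[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(surv: pd.DataFrame, mask=None) -> KMCurve:
    """Kaplan-Meier estimate for a (sub)group of a survival table."""
    from lifelines import KaplanMeierFitter

    sub = surv if mask is None else surv.loc[np.asarray(mask, dtype=bool)]
    if len(sub) == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], sub["event"])
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv_vals = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(times=times, survival=surv_vals, at_risk=table["at_risk"].to_numpy())


# ---------------------------------------------------------------------------
# Time-dependent ROC (nearest-neighbor estimator)


@dataclass
class TdROC:
    horizon: float
    span: float
    thresholds: np.ndarray  # ascending; classification rule is score >= threshold
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def _nne_conditional_survival(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray, t: float, span: float
) -> np.ndarray:
    """S(t | marker = score_i) for every i via neighborhood-weighted KM.

    The neighborhood of sample i is every j whose marker percentile lies
    within +/- span of i's (rectangular kernel on average ranks, self
    included).  Within each neighborhood a Kaplan-Meier product over event
    times <= t gives the smoothed conditional survival.
    """
    n = len(scores)
    pct = rankdata(scores, method="average") / n
    K = np.abs(pct[:, None] - pct[None, :]) < span  # n x n neighborhoods

    order = np.argsort(time, kind="mergesort")
    t_ord = time[order]
    e_ord = event[order]
    Ks = K[:, order].astype(float)

    starts = np.flatnonzero(np.r_[True, t_ord[1:] != t_ord[:-1]])
    distinct = t_ord[starts]
    relevant = distinct <= t
    if not relevant.any():
        return np.ones(n)

    cum = np.cumsum(Ks, axis=1)
    padded = np.hstack([np.zeros((n, 1)), cum])
    at_risk = cum[:, -1][:, None] - padded[:, starts]       # Y_i(s) per distinct time
    deaths = np.add.reduceat(Ks * e_ord, starts, axis=1)    # d_i(s)

    at_risk = at_risk[:, relevant]
    deaths = deaths[:, relevant]
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(at_risk > 0, 1.0 - deaths / np.maximum(at_risk, 1.0), 1.0)
    return np.prod(np.clip(factors, 0.0, 1.0), axis=1)


def td_roc_nne(
    scores, time, event, t: float, span: Optional[float] = None
) -> TdROC:
    """Cumulative/dynamic time-dependent ROC at horizon ``t`` via NNE.

    For threshold c (positive call: score >= c):

        TPR(c) = P(X >= c, T <= t) / P(T <= t)
        FPR(c) = P(X >= c, T > t)  / P(T > t)

    with P(X >= c, T > t) = mean_i S(t|x_i) 1{x_i >= c} from the smoothed
    conditional survival.  AUC is the trapezoid area under (FPR, TPR).
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(scores)
    if span is None:
        span = default_span(n)
    if not (0.0 < span <= 1.0):
        raise ValueError("span must lie in (0, 1]")
    if not ((time <= t) & (event == 1)).any():
        raise ValueError(f"no events observed by horizon t={t}")

    S_i = _nne_conditional_survival(scores, time, event, t, span)
    S_marginal = float(S_i.mean())
    if S_marginal >= 1.0 or S_marginal <= 0.0:
        raise ValueError("degenerate case/control mix at this horizon")

    thresholds = np.r_[np.unique(scores), np.inf]
    ge = scores[None, :] >= thresholds[:, None]      # thresholds x samples
    joint_surv = (ge * S_i[None, :]).mean(axis=1)    # P(X >= c, T > t)
    p_ge = ge.mean(axis=1)                            # P(X >= c)
    tpr = (p_ge - joint_surv) / (1.0 - S_marginal)
    fpr = joint_surv / S_marginal

    # sweep is monotone by construction; integrate along increasing FPR
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return TdROC(horizon=float(t), span=float(span), thresholds=thresholds,
                 tpr=tpr, fpr=fpr, auc=auc)


def optimal_cutoff(roc: TdROC) -> float:
    """Threshold closest (Euclidean) to the perfect corner (FPR 0, TPR 1).

    Distance ties break toward the lower threshold.
    """
    d2 = (1.0 - roc.tpr) ** 2 + roc.fpr**2
    best = int(np.flatnonzero(d2 == d2.min())[0])  # thresholds ascending
    return float(roc.thresholds[best])


def classify(scores, cutoff: float) -> np.ndarray:
    """score >= cutoff -> high risk (1); below -> low risk (0)."""
    return (np.asarray(scores, dtype=float) >= cutoff).astype(int)


# ---------------------------------------------------------------------------
# Group comparison


@dataclass
class GroupComparison:
    n_high: int
    n_low: int
    hazard_ratio: float
    ci_low: float
    ci_high: float
    logrank_p: float
    warning: bool = False  # set when a group has no events (HR unstable)


def group_hr(surv: pd.DataFrame, groups) -> GroupComparison:
    """Univariate Cox HR (high vs low, Breslow ties) with Wald 95% CI + log-rank p."""
    from lifelines import CoxPHFitter

    from .screening import logrank_test

    groups = np.asarray(groups, dtype=int)
    if groups.min() == groups.max():
        raise ValueError("both groups must be non-empty")
    event = surv["event"].to_numpy(dtype=int)
    warning = (event[groups == 1].sum() == 0) or (event[groups == 0].sum() == 0)
    if warning:
        logger.warning("a group has no events; hazard ratio is unstable")

    df = pd.DataFrame(
        {"high": groups, "time": surv["time"].to_numpy(), "event": event}
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary.loc["high"]
    _, p = logrank_test(surv["time"].to_numpy(), event, groups)
    return GroupComparison(
        n_high=int(groups.sum()),
        n_low=int((1 - groups).sum()),
        hazard_ratio=float(np.exp(summary["coef"])),
        ci_low=float(np.exp(summary["coef lower 95%"])),
        ci_high=float(np.exp(summary["coef upper 95%"])),
        logrank_p=float(p),
        warning=bool(warning),
    )


# ---------------------------------------------------------------------------
# Concordance


@dataclass
class ConcordanceResult:
    cindex: float
    se: float
    ci_low: float
    ci_high: float
    n_comparable: int


def _concordance_counts(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise numerator/denominator matrices for Harrell's C.

    Entry (i, j) is usable when sample i failed strictly before j's
    observed time (so i must be an event); concordance credit is 1 when the
    earlier-failing sample has the higher score, 0.5 on score ties.
    """
    comparable = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    s_diff = scores[:, None] - scores[None, :]
    credit = np.where(s_diff > 0, 1.0, np.where(s_diff == 0, 0.5, 0.0))
    return credit * comparable, comparable.astype(float)


def harrell_cindex(scores, time, event) -> ConcordanceResult:
    """Harrell's C with a leave-one-out jackknife standard error / 95% CI."""
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    num, den = _concordance_counts(scores, time, event)
    total_num, total_den = num.sum(), den.sum()
    if total_den == 0:
        raise ValueError("no comparable pairs")
    c = float(total_num / total_den)

    # removing sample k removes its row and column (diagonal is zero)
    num_k = total_num - num.sum(axis=1) - num.sum(axis=0)
    den_k = total_den - den.sum(axis=1) - den.sum(axis=0)
    valid = den_k > 0
    c_k = np.where(valid, num_k / np.maximum(den_k, 1.0), c)
    n = len(scores)
    se = float(np.sqrt((n - 1) / n * np.sum((c_k - c_k.mean()) ** 2)))
    z = norm.ppf(0.975)
    return ConcordanceResult(
        cindex=c,
        se=se,
        ci_low=max(0.0, c - z * se),
        ci_high=min(1.0, c + z * se),
        n_comparable=int(total_den),
    )


def _cindex_point(scores, time, event) -> float:
    num, den = _concordance_counts(scores, time, event)
    d = den.sum()
    return float(num.sum() / d) if d > 0 else np.nan


def compare_cindex(
    scores_a, scores_b, surv: pd.DataFrame, B: int = 1000, seed: int = 0
) -> tuple[float, float, dict]:
    """Paired-bootstrap comparison of two markers' Harrell C on one cohort.

    Samples are resampled with replacement B times; both C-indices are
    recomputed on each resample and the observed difference is referred to
    a normal approximation of the bootstrap spread (two-sided p).  Returns
    (delta = C_a - C_b, p, details).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    c_a = _cindex_point(scores_a, time, event)
    c_b = _cindex_point(scores_b, time, event)
    delta = c_a - c_b
    if np.array_equal(scores_a, scores_b):
        return 0.0, 1.0, {"c_a": c_a, "c_b": c_b, "bootstrap_se": 0.0}

    rng = np.random.default_rng(seed)
    n = len(time)
    deltas = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        deltas[b] = _cindex_point(scores_a[idx], time[idx], event[idx]) - _cindex_point(
            scores_b[idx], time[idx], event[idx]
        )
    deltas = deltas[np.isfinite(deltas)]
    se = float(deltas.std(ddof=1))
    if se == 0.0:
        p = 1.0
    else:
        p = float(2.0 * norm.sf(abs(delta) / se))
    return float(delta), p, {"c_a": c_a, "c_b": c_b, "bootstrap_se": se}


# ---------------------------------------------------------------------------
# Subgroups


StratumSelector = Union[Callable[[pd.Series], "pd.Series"], Sequence]


def subgroup_analysis(
    surv: pd.DataFrame,
    groups,
    clinical: pd.DataFrame,
    strata: Mapping[str, tuple[str, StratumSelector]],
) -> pd.DataFrame:
    """High-vs-low hazard ratios within clinical strata.

    ``strata`` maps a stratum label to (clinical column, selector) where the
    selector is either a callable on the column or a collection of accepted
    values.  Strata with fewer than 2 events are flagged and skipped (row
    retained with missing HR).
    """
    groups = np.asarray(groups, dtype=int)
    rows = []
    for label, (column, selector) in strata.items():
        if column not in clinical.columns:
            raise KeyError(f"unknown clinical column {column!r}")
        col = clinical[column]
        mask = col.apply(selector) if callable(selector) else col.isin(list(selector))
        mask = mask.to_numpy(dtype=bool)
        n_events = int(surv["event"].to_numpy()[mask].sum())
        base = {"stratum": label, "n": int(mask.sum()), "n_events": n_events}
        if n_events < 2 or mask.sum() == 0 or len(set(groups[mask])) < 2:
            logger.info("stratum %r skipped (too few events or one group)", label)
            rows.append({**base, "flagged": True, "hazard_ratio": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "logrank_p": np.nan,
                         "n_high": int(groups[mask].sum()),
                         "n_low": int((1 - groups[mask]).sum())})
            continue
        comp = group_hr(surv.loc[mask], groups[mask])
        rows.append({**base, "flagged": comp.warning,
                     "hazard_ratio": comp.hazard_ratio, "ci_low": comp.ci_low,
                     "ci_high": comp.ci_high, "logrank_p": comp.logrank_p,
                     "n_high": comp.n_high, "n_low": comp.n_low})
    return pd.DataFrame(rows)
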