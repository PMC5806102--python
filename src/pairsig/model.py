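"""Sparse pair-signature selection by L1-penalized Cox regression.

The design matrix is the binary pair-indicator matrix (pairs x samples).
An L1 (lasso) penalty path is fitted with glmnet-style coordinate descent
(`sksurv.linear_model.CoxnetSurvivalAnalysis`); the penalty is chosen by
K-fold cross-validated partial-likelihood deviance under the one-standard-
error rule: the largest penalty whose mean CV deviance is within one SE of
the minimum.  The resulting signature is the set of pairs with nonzero
coefficients, and a sample's risk score is the coefficient-weighted sum of
its pair indicators — a quantity invariant to strictly monotone per-sample
expression transforms.

Cross-validated deviance follows the Verweij–van Houwelingen construction:
for fold k with coefficients beta fitted on the complement,
``dev_k = -2 * (pl_all(beta) - pl_train(beta))`` with Breslow handling of
tied event times, the same quantity glmnet reports for Cox family CV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from . import evaluation
from .pairs import build_pair_matrix, pair_id, parse_pair_id

logger = logging.getLogger(__name__)


@dataclass
class SignatureModel:
    """An ordered list of (gene_a, gene_b, coefficient) plus a score cutoff.

    ``horizon`` is the time-dependent-ROC evaluation time in the survival
    table's native units (months by convention; 5 years = 60).
    """

    entries: list[tuple[str, str, float]]
    cutoff: Optional[float] = None
    horizon: Optional[float] = None

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _ in self.entries]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b, _ in self.entries:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, _, c in self.entries])


@dataclass
class FitDiagnostics:
    """Penalty path and cross-validation summary of a lasso-Cox fit."""

    alphas: np.ndarray                     # decreasing penalty values
    cv_mean_deviance: np.ndarray
    cv_se_deviance: np.ndarray
    n_nonzero: np.ndarray                  # nonzero coefficients per penalty
    chosen_alpha: float
    chosen_index: int
    min_index: int
    fold_assignments: np.ndarray
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "penalty": self.alphas,
                "mean_deviance": self.cv_mean_deviance,
                "se": self.cv_se_deviance,
                "n_nonzero": self.n_nonzero,
            }
        )


def breslow_partial_loglik(
    X: np.ndarray, beta: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Cox partial log-likelihood with Breslow tie handling.

    Every event at a tied time shares the full risk set {j : T_j >= t}.
    """
    eta = X @ beta
    order = np.argsort(-time, kind="mergesort")  # decreasing time
    eta_ord = eta[order]
    # running log-sum-exp over the growing risk set (samples with T >= t);
    # a single global shift is enough since eta is bounded here
    m = float(eta_ord.max())
    log_risk = np.log(np.cumsum(np.exp(eta_ord - m))) + m
    # with ties, all events at time t must see the complete risk set: take
    # the last (largest-index) entry among tied times
    t_ord = time[order]
    last_of_tie = np.r_[t_ord[1:] != t_ord[:-1], True]
    full_log_risk = np.empty_like(log_risk)
    idx = np.where(last_of_tie, np.arange(len(t_ord)), -1)
    # propagate the tie-final index backward
    for i in range(len(idx) - 2, -1, -1):
        if idx[i] == -1:
            idx[i] = idx[i + 1]
    full_log_risk = log_risk[idx]
    e_ord = event[order].astype(bool)
    return float(np.sum(eta_ord[e_ord] - full_log_risk[e_ord]))


def _coxnet_path(X, y, alphas=None, n_alphas=100, alpha_min_ratio=0.01, tol=1e-7):
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        alphas=None if alphas is None else list(alphas),
        n_alphas=n_alphas,
        alpha_min_ratio=alpha_min_ratio,
        fit_baseline_model=False,
        tol=tol,
        max_iter=100000,
    )
    model.fit(X, y)
    return model


def fit_penalized_cox(
    pair_matrix: pd.DataFrame,
    surv: pd.DataFrame,
    n_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
    alpha_min_ratio: float = 0.01,
    horizon: Optional[float] = None,
) -> tuple[SignatureModel, FitDiagnostics]:
    """Fit the lasso-Cox path and select pairs at the 1SE penalty.

    ``pair_matrix`` is pairs x samples with {0,1} entries and "A|B" pair
    ids; ``surv`` has columns time, event aligned to the matrix columns.
    Folds are stratified by event status and shuffled with ``seed`` so the
    deviance curve is reproducible.  The returned model carries no cutoff
    (set it from a time-dependent ROC downstream).
    """
    if list(pair_matrix.columns) != list(surv.index):
        raise ValueError("pair matrix and survival must be sample-aligned")
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events to fit")
    X = pair_matrix.to_numpy(dtype=float).T  # samples x pairs
    if np.all(X == X[0, :], axis=0).all():
        raise ValueError("all pair indicators are constant; nothing to fit")
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    path = _coxnet_path(X, y, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio)
    alphas = np.asarray(path.alphas_)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(time), dtype=int)
    fold_devs = np.full((n_folds, len(alphas)), np.nan)
    for k, (train, test) in enumerate(skf.split(X, event)):
        folds[test] = k
        sub = _coxnet_path(X[train], y[train], alphas=alphas)
        coefs = sub.coef_  # features x (possibly truncated) alphas
        for a_i, alpha in enumerate(np.asarray(sub.alphas_)):
            pos = int(np.argmin(np.abs(alphas - alpha)))  # map onto full path
            beta = coefs[:, a_i]
            pl_all = breslow_partial_loglik(X, beta, time, event)
            pl_train = breslow_partial_loglik(
                X[train], beta, time[train], event[train]
            )
            fold_devs[k, pos] = -2.0 * (pl_all - pl_train)

    # a fold's coordinate-descent path may stop early; aggregate over the
    # folds that reached each penalty and drop penalties no fold reached
    with np.errstate(invalid="ignore"):
        n_ok = np.sum(~np.isnan(fold_devs), axis=0)
        mean_dev = np.nanmean(np.where(np.isnan(fold_devs), np.nan, fold_devs), axis=0)
        se_dev = np.nanstd(fold_devs, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
    usable = n_ok == n_folds
    if not usable.any():
        raise RuntimeError("cross-validation produced no complete penalty column")
    masked = np.where(usable, mean_dev, np.inf)
    min_idx = int(np.argmin(masked))
    threshold = mean_dev[min_idx] + se_dev[min_idx]
    # alphas are decreasing: the 1SE penalty is the first (largest) alpha
    # whose mean deviance is under the threshold
    chosen_idx = int(np.flatnonzero(usable & (masked <= threshold))[0])
    chosen_alpha = float(alphas[chosen_idx])

    beta = path.coef_[:, chosen_idx]
    nonzero = np.flatnonzero(beta != 0.0)
    if len(nonzero) == 0:
        raise ValueError(
            "1SE penalty retained no pairs; the cohort carries no detectable "
            "pair-level signal at this sample size"
        )
    entries = []
    for j in nonzero:
        a, b = parse_pair_id(pair_matrix.index[j])
        entries.append((a, b, float(beta[j])))

    diagnostics = FitDiagnostics(
        alphas=alphas,
        cv_mean_deviance=mean_dev,
        cv_se_deviance=se_dev,
        n_nonzero=(path.coef_ != 0.0).sum(axis=0),
        chosen_alpha=chosen_alpha,
        chosen_index=chosen_idx,
        min_index=min_idx,
        fold_assignments=folds,
        seed=seed,
    )
    return SignatureModel(entries=entries, cutoff=None, horizon=horizon), diagnostics


def risk_score(model: SignatureModel, expr: pd.DataFrame) -> pd.Series:
    """Per-sample risk score: sum_k coef_k * I(expr[a_k] > expr[b_k]).

    Needs only the signature's genes; applicable to any cohort without
    renormalization.  Raises if any signature gene is absent, listing the
    missing symbols.
    """
    missing = sorted(set(model.genes) - set(expr.index))
    if missing:
        raise KeyError(f"signature genes absent from expression matrix: {missing}")
    m = build_pair_matrix(expr.loc[model.genes], model.pairs)
    scores = model.coefficients @ m.to_numpy(dtype=float)
    return pd.Series(scores, index=expr.columns, name="risk_score")


def _evaluate_scores(scores, surv, horizon, span=None) -> dict:
    roc = evaluation.td_roc_nne(
        scores, surv["time"].to_numpy(), surv["event"].to_numpy(), horizon, span=span
    )
    conc = evaluation.harrell_cindex(
        np.asarray(scores, dtype=float), surv["time"].to_numpy(), surv["event"].to_numpy()
    )
    return {"auc": roc.auc, "cindex": conc.cindex}


def sensitivity_leave_one_pair_out(
    model: SignatureModel,
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    span: Optional[float] = None,
) -> pd.DataFrame:
    """Re-evaluate the signature with each pair omitted in turn.

    Coefficients of the remaining pairs are left unchanged; the omitted
    pair simply drops out of the score.  Returns one row per signature
    entry with the omitted-score C-index and horizon AUC next to the full
    model's (columns cindex_full / auc_full).
    """
    if len(model.entries) < 2:
        raise ValueError("need at least 2 entries for a leave-one-out sweep")
    if model.horizon is None:
        raise ValueError("model.horizon must be set for AUC evaluation")
    full = _evaluate_scores(risk_score(model, expr).to_numpy(), surv, model.horizon, span)
    rows = []
    for i, (a, b, coef) in enumerate(model.entries):
        reduced = SignatureModel(
            entries=[e for j, e in enumerate(model.entries) if j != i],
            cutoff=model.cutoff,
            horizon=model.horizon,
        )
        res = _evaluate_scores(risk_score(reduced, expr).to_numpy(), surv, model.horizon, span)
        rows.append(
            {
                "omitted_pair": pair_id(a, b),
                "coefficient": coef,
                "cindex": res["cindex"],
                "auc": res["auc"],
                "cindex_full": full["cindex"],
                "auc_full": full["auc"],
            }
        )
    return pd.DataFrame(rows)


def pseudo_signature(
    prognostic_genes: Sequence[str],
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    n_pairs: int = 7,
    seed: int = 0,
    horizon: float = 60.0,
    span: Optional[float] = None,
) -> tuple[SignatureModel, dict]:
    """Random-pair control: sample 2*n_pairs genes, pair them, fit, evaluate.

    Genes are drawn without replacement from the screened prognostic list
    and paired consecutively; coefficients come from an unpenalized Cox fit
    on the n_pairs indicators.  The evaluation dict carries the horizon AUC
    and C-index, computed with the same machinery as the real signature —
    the control quantifies how much performance the pairing scheme alone
    can manufacture from prognostic genes chosen at random.
    """
    from lifelines import CoxPHFitter

    genes = list(prognostic_genes)
    if len(genes) < 2 * n_pairs:
        raise ValueError(f"need at least {2 * n_pairs} genes, got {len(genes)}")
    rng = np.random.default_rng(seed)
    sampled = list(rng.choice(genes, size=2 * n_pairs, replace=False))
    pairs = [(sampled[2 * i], sampled[2 * i + 1]) for i in range(n_pairs)]
    m = build_pair_matrix(expr.loc[sampled], pairs)
    df = pd.DataFrame(m.to_numpy(dtype=float).T, columns=m.index, index=m.columns)
    df["time"] = surv["time"].to_numpy()
    df["event"] = surv["event"].to_numpy()
    # constant indicators carry no information and break the fit; freeze at 0
    kept = [c for c in m.index if df[c].nunique() > 1]
    coefs: dict[str, float] = {}
    if kept:
        from lifelines.exceptions import ConvergenceError

        try:
            cph = CoxPHFitter(penalizer=0.0)
            cph.fit(df[kept + ["time", "event"]], duration_col="time", event_col="event")
        except ConvergenceError:
            # collinear or separating indicators: stabilize with a small ridge
            logger.warning("unpenalized pseudo-signature fit singular; adding ridge 0.1")
            cph = CoxPHFitter(penalizer=0.1, l1_ratio=0.0)
            cph.fit(df[kept + ["time", "event"]], duration_col="time", event_col="event")
        coefs = {c: float(cph.params_[c]) for c in kept}
    entries = [(a, b, coefs.get(pair_id(a, b), 0.0)) for a, b in pairs]
    model = SignatureModel(entries=entries, cutoff=None, horizon=horizon)
    scores = risk_score(model, expr)
    report = _evaluate_scores(scores.to_numpy(), surv, horizon, span)
    return model, report
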