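"""End-to-end orchestration: training, validation, manifests.

``run_training`` wires the stages together on a training cohort —
probe collapse (optional), expression/variance filtering, permutation
log-rank screening, pair enumeration, lasso-Cox selection, risk scoring,
time-dependent-ROC cutoff estimation and group evaluation — writing every
intermediate table plus a reproducibility manifest (parameters, seeds,
package versions; no timestamps, so reruns are byte-identical).

``run_validation`` applies a stored signature and cutoff to a new cohort
with no re-estimation of any kind.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, evaluation, io, model, pairs, preprocess, screening

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    expression_path: str = ""
    survival_path: str = ""
    annotation_path: Optional[str] = None
    signature_path: Optional[str] = None
    outdir: str = "pairsig_out"
    low_expression_fraction: float = 0.20
    low_variability_fraction: float = 0.20
    alpha: float = 0.05
    permutations: int = 1000
    n_folds: int = 10
    horizon: float = 60.0
    time_unit: str = "months"
    span: Optional[float] = None
    min_pair_fraction: float = 0.0
    event_map: Optional[dict] = None
    screen_seed: int = 0
    cv_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_training(self) -> None:
        for name in ("expression_path", "survival_path"):
            value = getattr(self, name)
            if not value:
                raise ValueError(f"config.{name} is required")
            if not Path(value).exists():
                raise FileNotFoundError(f"config.{name}: {value} does not exist")


def _manifest(config: PipelineConfig, stage_counts: dict) -> dict:
    return {
        "package": "pairsig",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stage_counts": stage_counts,
    }


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def _evaluate_groups(surv: pd.DataFrame, groups: np.ndarray, scores: np.ndarray,
                     outdir: Path, prefix: str) -> dict:
    comp = evaluation.group_hr(surv, groups)
    conc = evaluation.harrell_cindex(
        scores, surv["time"].to_numpy(), surv["event"].to_numpy()
    )
    for label, mask in (("high", groups == 1), ("low", groups == 0)):
        if mask.any():
            evaluation.km_estimate(surv, mask).to_frame().to_csv(
                outdir / f"{prefix}_km_{label}.tsv", sep="\t", index=False
            )
    return {
        "n_high": comp.n_high,
        "n_low": comp.n_low,
        "hazard_ratio": comp.hazard_ratio,
        "hr_ci": [comp.ci_low, comp.ci_high],
        "logrank_p": comp.logrank_p,
        "hr_warning": comp.warning,
        "cindex": conc.cindex,
        "cindex_ci": [conc.ci_low, conc.ci_high],
    }


def run_training(config: PipelineConfig) -> tuple[model.SignatureModel, dict]:
    """Fit a pair signature on a training cohort and fix its cutoff.

    Returns the signature (with cutoff and horizon set) and the evaluation
    report; all intermediates land in ``config.outdir``.
    """
    config.validate_training()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    bundle = io.load_cohort(
        config.expression_path, config.survival_path, event_map=config.event_map
    )
    expr, surv = bundle.expression, bundle.survival
    counts["samples"] = expr.shape[1]

    if config.annotation_path:
        annotation = io.read_annotation(config.annotation_path)
        expr = preprocess.collapse_probes(expr, annotation)
    counts["genes_input"] = expr.shape[0]

    expr = preprocess.filter_genes(
        expr, config.low_expression_fraction, config.low_variability_fraction
    )
    counts["genes_after_filter"] = expr.shape[0]

    screened = screening.screen_prognostic_genes(
        expr, surv, alpha=config.alpha, B=config.permutations, seed=config.screen_seed
    )
    screened.to_csv(outdir / "screened_genes.tsv", sep="\t", index=False)
    counts["genes_screened"] = len(screened)
    if len(screened) < 2:
        raise RuntimeError("screening: fewer than 2 prognostic genes; cannot form pairs")

    gene_list = screened["gene"].tolist()
    catalog = pairs.enumerate_pairs(gene_list)
    matrix = pairs.build_pair_matrix(expr.loc[gene_list], catalog)
    matrix = pairs.prune_degenerate_pairs(matrix, config.min_pair_fraction)
    counts["pairs_candidate"] = len(catalog)
    counts["pairs_after_prune"] = matrix.shape[0]

    signature, diagnostics = model.fit_penalized_cox(
        matrix, surv, n_folds=config.n_folds, seed=config.cv_seed, horizon=config.horizon
    )
    diagnostics.to_frame().to_csv(outdir / "cv_diagnostics.tsv", sep="\t", index=False)
    counts["pairs_selected"] = len(signature.entries)

    scores = model.risk_score(signature, expr)
    scores.rename_axis("sample_id").to_csv(outdir / "training_scores.tsv", sep="\t")

    roc = evaluation.td_roc_nne(
        scores.to_numpy(), surv["time"].to_numpy(), surv["event"].to_numpy(),
        config.horizon, span=config.span,
    )
    roc.to_frame().to_csv(outdir / "training_roc.tsv", sep="\t", index=False)
    signature.cutoff = evaluation.optimal_cutoff(roc)

    groups = evaluation.classify(scores.to_numpy(), signature.cutoff)
    report = {
        "stage": "training",
        "cutoff": signature.cutoff,
        "horizon": config.horizon,
        "time_unit": config.time_unit,
        "auc_at_horizon": roc.auc,
        **_evaluate_groups(surv, groups, scores.to_numpy(), outdir, "training"),
    }

    io.write_signature(signature, outdir / "signature.tsv")
    _write_json(report, outdir / "training_report.json")
    _write_json(_manifest(config, counts), outdir / "manifest.json")
    return signature, report


def run_validation(config: PipelineConfig, signature_path) -> dict:
    """Score a cohort with a stored signature and its frozen cutoff."""
    config.validate_training()
    sig_path = Path(signature_path)
    if not sig_path.exists():
        raise FileNotFoundError(f"signature file {sig_path} does not exist")
    signature = io.read_signature(sig_path)
    if signature.cutoff is None:
        raise ValueError(f"{sig_path}: sidecar with a cutoff is required for validation")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bundle = io.load_cohort(
        config.expression_path, config.survival_path, event_map=config.event_map
    )
    expr, surv = bundle.expression, bundle.survival
    scores = model.risk_score(signature, expr)
    scores.rename_axis("sample_id").to_csv(outdir / "validation_scores.tsv", sep="\t")
    groups = evaluation.classify(scores.to_numpy(), signature.cutoff)
    horizon = signature.horizon if signature.horizon is not None else config.horizon
    report = {
        "stage": "validation",
        "cutoff": signature.cutoff,
        "horizon": horizon,
        **_evaluate_groups(surv, groups, scores.to_numpy(), outdir, "validation"),
    }
    try:
        roc = evaluation.td_roc_nne(
            scores.to_numpy(), surv["time"].to_numpy(), surv["event"].to_numpy(),
            horizon, span=config.span,
        )
        report["auc_at_horizon"] = roc.auc
    except ValueError as exc:  # horizon past follow-up: report groups only
        logger.warning("validation ROC skipped: %s", exc)
        report["auc_at_horizon"] = None
    _write_json(report, outdir / "validation_report.json")
    return report
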