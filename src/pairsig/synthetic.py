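"""Synthetic expression/survival cohorts with planted prognostic gene pairs.

The generator emulates a log-scale microarray cohort (genes x samples) whose
survival is driven by a proportional-hazards model on binary within-sample
gene-order indicators: for each planted pair (A, B) with log-hazard
coefficient beta, a sample's hazard is multiplied by exp(beta) whenever its
expression of A exceeds that of B.  Because the signal lives entirely in
within-sample orderings, any strictly monotone per-sample distortion of the
expression values (a "batch effect") leaves the ground truth untouched —
which is exactly the invariance the downstream pair features are built to
exploit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

#: Named strictly increasing maps usable as per-sample batch distortions.
MONOTONE_DISTORTIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "exponential": np.exp,
    "cube": lambda x: x**3,
    "arsinh": np.arcsinh,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a simulated cohort.

    ``planted_pairs`` lists (gene index A, gene index B, beta) triples: the
    per-unit log-hazard contribution of the indicator I(expr_A > expr_B).
    ``baseline_scale`` is the mean event time (study time units; months by
    convention) of a sample with linear predictor zero under the exponential
    baseline.  ``censoring_rate`` is the target fraction of administratively
    censored samples.
    """

    n_samples: int = 300
    n_genes: int = 50
    planted_pairs: Sequence[tuple[int, int, float]] = field(default_factory=tuple)
    baseline_scale: float = 60.0
    censoring_rate: float = 0.4
    batch_shift: float = 0.0
    batch_scale: float = 1.0
    monotone_distortion: str = "identity"
    probes_per_gene: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.batch_scale <= 0:
            raise ValueError("batch_scale must be positive")
        if self.baseline_scale <= 0:
            raise ValueError("baseline_scale must be positive")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        if self.monotone_distortion not in MONOTONE_DISTORTIONS:
            raise ValueError(
                f"unknown distortion {self.monotone_distortion!r}; "
                f"known: {sorted(MONOTONE_DISTORTIONS)}"
            )
        for a, b, _beta in self.planted_pairs:
            if a == b:
                raise ValueError(f"planted pair ({a}, {b}) is degenerate")
            if not (0 <= a < self.n_genes and 0 <= b < self.n_genes):
                raise ValueError(f"planted pair ({a}, {b}) out of gene range")


@dataclass
class SyntheticCohort:
    """A generated cohort: expression (genes x samples), survival, truth."""

    expression: pd.DataFrame
    survival: pd.DataFrame  # index sample_id; columns time, event
    truth: list[tuple[str, str, float]]
    clinical: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.survival.index):
            raise ValueError("expression and survival sample ids must match in order")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _sample_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(n)]


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Simulate expression and survival under the planted-pair hazard model.

    Expression: gene g is i.i.d. Normal(mu_g, sd_g) across samples, with
    gene-level means drawn from U(5, 10) and SDs from U(0.4, 1.5) — a rough
    log2-intensity scale.  Genes that participate in a planted pair share a
    common mean (7.0) and SD (1.0) so their ordering indicator is close to
    Bernoulli(1/2) and actually informative.

    Survival: event time ~ Exponential with mean baseline_scale *
    exp(-eta_s), eta_s = sum_k beta_k * I(expr_Ak > expr_Bk).  Censoring is
    administrative, uniform on [0, tau], with tau solved so the realized
    expected censored fraction matches ``censoring_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    samples = _sample_names(config.n_samples)

    mu = rng.uniform(5.0, 10.0, size=config.n_genes)
    sd = rng.uniform(0.4, 1.5, size=config.n_genes)
    planted_idx = {i for a, b, _ in config.planted_pairs for i in (a, b)}
    for i in planted_idx:
        mu[i] = 7.0
        sd[i] = 1.0

    X = rng.normal(mu[:, None], sd[:, None], size=(config.n_genes, config.n_samples))
    expr = pd.DataFrame(X, index=genes, columns=samples)

    eta = np.zeros(config.n_samples)
    truth: list[tuple[str, str, float]] = []
    for a, b, beta in config.planted_pairs:
        eta += beta * (X[a] > X[b])
        truth.append((genes[a], genes[b], float(beta)))

    # exponential PH baseline: T = baseline_scale * E / exp(eta), E ~ Exp(1)
    event_time = config.baseline_scale * rng.exponential(size=config.n_samples) / np.exp(eta)

    if config.censoring_rate > 0.0:
        tau = _solve_censoring_tau(event_time, config.censoring_rate)
        cens_time = rng.uniform(0.0, tau, size=config.n_samples)
        time = np.minimum(event_time, cens_time)
        event = (event_time <= cens_time).astype(int)
    else:
        time = event_time
        event = np.ones(config.n_samples, dtype=int)
    time = np.maximum(time, 1e-9)  # guard against zero times

    survival = pd.DataFrame({"time": time, "event": event}, index=pd.Index(samples, name="sample_id"))

    clinical = pd.DataFrame(
        {
            "age": np.round(rng.normal(64.0, 10.0, size=config.n_samples)).astype(int),
            "sex": rng.choice(["male", "female"], size=config.n_samples, p=[0.66, 0.34]),
        },
        index=survival.index,
    )

    cohort = SyntheticCohort(expression=expr, survival=survival, truth=truth, clinical=clinical)
    if (
        config.batch_shift != 0.0
        or config.batch_scale != 1.0
        or config.monotone_distortion != "identity"
    ):
        cohort = apply_batch_transform(
            cohort, config.batch_shift, config.batch_scale, config.monotone_distortion
        )
    return cohort


def _solve_censoring_tau(event_time: np.ndarray, rate: float) -> float:
    """Horizon tau of U(0, tau) censoring giving expected censored fraction ``rate``.

    P(censored | T = t) = P(U < t) = min(t / tau, 1), so the expected rate is
    mean_i min(T_i / tau, 1), decreasing in tau; solved by bisection.
    """

    def expected_rate(tau: float) -> float:
        return float(np.mean(np.minimum(event_time / tau, 1.0)))

    lo, hi = 1e-9, float(event_time.max())
    if expected_rate(hi) >= rate:
        return hi  # even the loosest admissible tau censors more than asked; cap
    # expected_rate(lo) ~ 1 > rate >= expected_rate(hi)
    return float(brentq(lambda tau: expected_rate(tau) - rate, lo, hi * (1 + 1e-12)))


def apply_batch_transform(
    cohort: SyntheticCohort, shift: float, scale: float, distortion: str = "identity"
) -> SyntheticCohort:
    """Return a copy with every expression value mapped by x -> f(scale*x + shift).

    ``distortion`` names a strictly increasing map (see MONOTONE_DISTORTIONS),
    so within-sample gene orderings — and hence all pair indicators — are
    preserved exactly.  Survival is untouched.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    try:
        f = MONOTONE_DISTORTIONS[distortion]
    except KeyError:
        raise ValueError(
            f"unknown distortion {distortion!r}; known: {sorted(MONOTONE_DISTORTIONS)}"
        ) from None
    transformed = pd.DataFrame(
        f(scale * cohort.expression.to_numpy() + shift),
        index=cohort.expression.index,
        columns=cohort.expression.columns,
    )
    return replace(cohort, expression=transformed)


def generate_probe_matrix(
    cohort: SyntheticCohort, probes_per_gene: int, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand each gene into probe rows with probe-specific noise.

    Probe j of a gene carries the gene's values plus Normal(0, 0.05 + 0.4*j)
    noise, so probes of one gene have strictly increasing noise variance and
    the IQR-maximizing probe is, with overwhelming probability, the last one.
    Returns (probe matrix, annotation table with columns probe_id, gene_symbol).
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    genes = list(cohort.expression.index)
    n_samples = cohort.expression.shape[1]
    rows = []
    probe_ids = []
    annot = []
    for gene in genes:
        base = cohort.expression.loc[gene].to_numpy()
        for j in range(probes_per_gene):
            pid = f"{gene}_at{j}"
            noise_sd = 0.05 + 0.4 * j
            values = base if probes_per_gene == 1 else base + rng.normal(0, noise_sd, n_samples)
            rows.append(values)
            probe_ids.append(pid)
            annot.append((pid, gene))
    probes = pd.DataFrame(np.asarray(rows), index=probe_ids, columns=cohort.expression.columns)
    annotation = pd.DataFrame(annot, columns=["probe_id", "gene_symbol"])
    return probes, annotation


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write expression/survival/truth (and clinical, if any) as TSV files."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t")
    cohort.survival.to_csv(outdir / "survival.tsv", sep="\t")
    pd.DataFrame(cohort.truth, columns=["gene_a", "gene_b", "beta"]).to_csv(
        outdir / "truth.tsv", sep="\t", index=False
    )
    if cohort.clinical is not None:
        cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t")
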