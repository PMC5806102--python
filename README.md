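# pairsig

Rank-based gene-pair prognostic signatures for survival cohorts.

## The problem

Expression-based prognostic signatures usually combine absolute expression
levels, which makes them fragile: a model fitted on one microarray cohort
rarely transfers to another because of batch effects and normalization
differences.  `pairsig` implements the *relative expression ordering*
alternative: features are binary within-sample comparisons
`I(expr_A > expr_B)` for gene pairs (A, B), so a fitted signature and its
risk cutoff can be applied to any cohort that measures the same genes —
no renormalization, no batch correction.  The package targets survival
analysts working with bulk expression cohorts (e.g. GEO gastric-cancer
series) who want a risk score with an explicit formula and a frozen
high/low-risk cutoff.

## The method

Given a training cohort (genes × samples, per-sample follow-up time and
event status):

1. collapse probes to genes by maximal inter-quartile range;
2. drop the lowest 20% of genes by mean intensity, then the lowest 20% of
   survivors by standard deviation;
3. screen prognostic genes with a median-split log-rank test and
   permutation p-values;
4. form all G(G−1)/2 pair indicators of the screened genes;
5. select a sparse pair set by L1-penalized Cox regression
   (10-fold cross-validated partial-likelihood deviance, 1SE rule);
6. score samples by `score(s) = Σ_k c_k · I(expr_Ak(s) > expr_Bk(s))` and
   fix the cutoff from the time-dependent ROC (nearest-neighbor
   estimator) at the 5-year horizon — the threshold closest to the
   (FPR = 0, TPR = 1) corner;
7. evaluate with Kaplan–Meier curves, log-rank tests, hazard ratios,
   time-dependent AUC and Harrell's C-index (with paired-bootstrap
   comparison of competing markers).

A published seven-pair, twelve-gene gastric-cancer signature (cutoff
−0.154 at 60 months) ships as a read-only fixture for scoring and
validation.  A synthetic-cohort generator with planted prognostic pairs
makes every stage testable end to end; see `docs/methods.md` for the
model and all numerical conventions.

## Worked example

```python
import pairsig
from pairsig.synthetic import SyntheticConfig, generate_cohort
from pairsig.pairs import enumerate_pairs, build_pair_matrix, prune_degenerate_pairs
from pairsig.model import fit_penalized_cox, risk_score
from pairsig.evaluation import td_roc_nne, optimal_cutoff, classify, group_hr

# a 300-sample cohort whose survival is driven by two planted pair orderings
cfg = SyntheticConfig(n_samples=300, n_genes=30,
                      planted_pairs=((0, 1, 1.0), (2, 3, 1.0)), seed=1)
cohort = generate_cohort(cfg)

catalog = enumerate_pairs(list(cohort.expression.index))       # 435 pairs
matrix = prune_degenerate_pairs(build_pair_matrix(cohort.expression, catalog))
signature, diag = fit_penalized_cox(matrix, cohort.survival, seed=1)

scores = risk_score(signature, cohort.expression)
roc = td_roc_nne(scores.to_numpy(), cohort.survival["time"].to_numpy(),
                 cohort.survival["event"].to_numpy(), t=60.0)
cutoff = optimal_cutoff(roc)
groups = classify(scores.to_numpy(), cutoff)
print(len(signature.entries), round(roc.auc, 3), round(cutoff, 3))
print(group_hr(cohort.survival, groups))
```

prints (seed 1):

```
2 0.739 0.309
GroupComparison(n_high=143, n_low=157, hazard_ratio=2.335506495105294,
                ci_low=1.7183868286153738, ci_high=3.174250697134455,
                logrank_p=2.5551961043534834e-08, warning=False)
```

— the 1SE lasso kept exactly the two planted pairs, the 60-month AUC is
0.74, and the ROC-corner cutoff of 0.309 splits the cohort into 143
high-risk and 157 low-risk samples with a hazard ratio of 2.34 (95% CI
1.72–3.17, log-rank p ≈ 3e-8).  Scoring an exponentially batch-distorted
copy of the cohort reproduces every one of these numbers bit-for-bit.

The same flow is available from the shell:

```sh
pairsig simulate --n-samples 300 --n-genes 30 --planted "0,1,1.0;2,3,1.0" \
        --seed 1 --outdir cohort/
pairsig train --expression cohort/expression.tsv --survival cohort/survival.tsv \
        --outdir run/
pairsig validate --signature run/signature.tsv \
        --expression cohort/expression.tsv --survival cohort/survival.tsv \
        --outdir val/
```

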