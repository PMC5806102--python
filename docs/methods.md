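# Methods

## The model

`pairsig` builds prognostic signatures from *relative expression orderings*.
For a pair of genes (A, B) and a sample *s*, the feature is the binary
indicator

    I_AB(s) = 1  if  x_A(s) > x_B(s),   else 0   (ties score 0),

i.e. only which gene is higher within the sample matters, never by how
much.  A signature is a set of K pairs with Cox log-hazard coefficients
c_1..c_K, and a sample's risk score is

    score(s) = sum_k c_k * I_k(s).

Because every strictly increasing per-sample transform of the expression
vector leaves all orderings unchanged, the score — and every decision
derived from it (cutoff, risk group) — is *exactly* invariant to
monotone batch effects and normalization differences.  This invariance is
the method's central claim and is asserted bit-exactly in the test suite,
not approximately.

## Pipeline stages

1. **Probe collapse.**  When several probes map to one gene symbol, the
   probe with the largest inter-quartile range across samples represents
   the gene (ties break to the lexicographically smallest probe id).
   Probes mapping to multiple genes are dropped (a probe on both sides of
   pair indicators would leak information).

2. **Gene pre-filters.**  Genes are ranked by mean intensity and the
   lowest `floor(f1*G)` removed (default f1 = 0.20, the "unexpressed"
   tail); survivors are ranked by standard deviation and the lowest
   `floor(f2*G')` removed (default 0.20, the "uninformative" tail).  The
   two filters are applied sequentially, each on the current gene count;
   both fractions are configurable and 0 disables a filter.  Genes with
   missing values are dropped first — rank statistics need complete rows.

3. **Prognostic screening.**  Each gene is dichotomized at its median
   (values at or above the median are the "high" group; the boundary side
   is a fixed convention) and tested with the two-group log-rank statistic
   (1 df, ties pooled within an event time).  Significance uses a
   permutation p-value, p = (1 + #{perm >= obs}) / (B + 1), default
   B = 1000, α = 0.05, no multiplicity correction (the screen is a
   pre-filter for the penalized model, which does its own selection).  The
   statistic is computed by a vectorized counting-process routine; the test
   suite checks it to ~1e-15 against lifelines and a brute-force oracle.

4. **Pair features.**  All G(G−1)/2 unordered pairs of screened genes,
   slot order fixed by input order (the model's coefficient signs absorb
   orientation).  Constant pairs are pruned by default; an optional
   `min_fraction` removes pairs whose indicator frequency is ≤ f or
   ≥ 1−f.

5. **Penalized selection.**  L1-penalized Cox partial likelihood (Breslow
   ties) along a 100-value log-spaced penalty path down to 0.01× the
   smallest all-zero penalty, fitted with glmnet-style coordinate descent
   (scikit-survival's coxnet).  The penalty is chosen by 10-fold
   cross-validation, folds stratified by event status and seeded; the fold
   deviance is the Verweij–van Houwelingen quantity
   `-2 (pl_all(beta_k) - pl_train(beta_k))`, and the 1SE rule takes the
   largest penalty whose mean deviance is within one standard error of the
   minimum.  Folds whose path terminates early contribute only to the
   penalties they reached; penalties not reached by every fold are not
   eligible for selection.  If the 1SE penalty retains no pairs the fit
   raises rather than returning an empty signature.

6. **Cutoff.**  The risk-score cutoff is taken from the time-dependent ROC
   at the evaluation horizon (default 60 months = 5 years): the threshold
   whose (FPR, TPR) point is closest in Euclidean distance to (0, 1), ties
   toward the lower threshold.  Classification uses `score >= cutoff →
   high risk`.  The cutoff is estimated once on the training cohort and
   frozen; validation never re-estimates it.

## Time-dependent ROC (NNE)

Cumulative-case / dynamic-control ROC at horizon t: cases are events by t,
controls are survivors past t.  Under censoring, case/control status is
unobserved for some samples, so the conditional survival S(t | marker) is
estimated by a nearest-neighbor smoother: the neighborhood of sample *i*
is every sample whose marker percentile (average ranks / n) is within
± span of *i*'s, and a weighted Kaplan–Meier inside the neighborhood gives
S(t | x_i).  Default span is 0.25·n^(−0.20).  Then, for threshold c,

    TPR(c) = [P(X ≥ c) − P(X ≥ c, T > t)] / [1 − S(t)],
    FPR(c) =  P(X ≥ c, T > t) / S(t),

with the joint term averaged over the smoothed S(t | x_i).  AUC is the
trapezoid area.  Because the neighborhoods are defined on marker ranks the
estimator inherits the monotone-transform invariance of the features.  In
the no-censoring limit with a sub-rank span the estimator reduces exactly
to the empirical ROC of the binary event-by-t outcome (asserted against
scikit-learn in the tests).

## Evaluation statistics

- **KM / log-rank / HR.**  Kaplan–Meier curves and the high-vs-low hazard
  ratio come from lifelines (univariate Cox, Breslow ties, Wald 95% CI);
  the attached p-value is the permutation-free asymptotic log-rank p.
  A group with zero events flags the comparison as unstable.
- **Harrell's C.**  Usable pairs are (i, j) with T_i < T_j and sample i an
  event; score ties credit 0.5.  The standard error is a leave-one-out
  jackknife computed exactly in O(n²) from the pairwise credit and
  comparability row/column sums; the 95% CI is normal-theory, clipped to
  [0, 1].
- **C-index comparison.**  Paired bootstrap over samples: both markers'
  C are recomputed on each resample, and the observed ΔC is referred to a
  normal approximation of the bootstrap spread (two-sided).  A closed-form
  dependent-C variance would be tighter but less transparent; the
  bootstrap is exact in its assumptions and directly testable.
- **Subgroups.**  The high-vs-low HR recomputed within clinical strata;
  strata with fewer than two events are flagged and reported with missing
  estimates rather than fabricated ones.

## Synthetic cohorts

The generator emulates a log-intensity microarray cohort.  Gene g is
i.i.d. Normal(mu_g, sd_g) across samples with mu_g ~ U(5, 10) and sd_g ~
U(0.4, 1.5); genes participating in a planted pair share mu = 7, sd = 1 so
their ordering indicator is near-Bernoulli(1/2) and genuinely informative.
Survival follows a proportional-hazards model with exponential baseline
(mean 60 months at linear predictor 0) and linear predictor
sum_k beta_k I_k(s) over the planted pairs.  Censoring is administrative:
uniform on [0, tau] with tau solved by bisection so the expected censored
fraction matches the target (default 0.40, a typical follow-up loss for
retrospective cancer cohorts).  All randomness flows from a single seed
through one named generator, so cohorts are bit-reproducible.

The probe expansion adds probe-specific Gaussian noise whose SD grows with
probe index (0.05 + 0.4·j), giving a known IQR ordering for collapse
tests.  Batch distortion applies x → f(scale·x + shift) per sample for a
named strictly increasing f (identity, exponential, cube, arsinh).

What the generator does *not* emulate: heavy-tailed probe noise, spatial
array artifacts, probe cross-hybridization, correlated gene modules, or
the empirical intensity distributions of any real cohort.  Passing tests
therefore demonstrate the statistical machinery under a clean
proportional-hazards data-generating process, not microarray physics; the
batch-invariance results, however, are distribution-free (they hold for
any strictly monotone distortion by construction).

## Default problem sizes

Simulation-based checks use cohorts of n = 300 samples — the size of the
training cohorts this method targets — with 30–50 genes and, for recovery
experiments, 5 planted pairs at beta = 0.8 among 50 genes (1,225 candidate
pairs), 20 seeded replicates.  Null calibration uses 500 null genes with
B = 200 permutations at alpha = 0.05, and 20 random-pair control
replicates.  End-to-end pipeline demonstrations (screen → fit → cutoff)
plant pairs at beta = 1.5: the median-split screen roughly halves the
effective pair signal, so the per-gene effect must be strong enough for
the screening stage itself to detect.  These sizes give stable Monte-Carlo estimates while keeping a
full run of the suite and the acceptance script to a few minutes.

## Numerical choices and edge cases

- Ties: pair indicators score 0 on exact expression ties; samples at the
  median go to the high group; score = cutoff classifies high; cutoff
  distance ties resolve to the lower threshold; IQR ties to the smaller
  probe id.  Every tie-break is a fixed convention so reruns are
  byte-identical.
- Coordinate descent tolerance 1e-7 (1e-10 when checking the unpenalized
  limit); at a near-zero penalty the fitted coefficients agree with an
  independent Newton–Raphson maximizer of the Breslow partial likelihood
  to 1e-4 on small instances (tested).
- The random-pair control's unpenalized Cox fit can be singular when two
  sampled indicators are collinear or separate the events; it then retries
  with a small ridge (0.1), logged.
- The permutation p-value is never 0 by construction (≥ 1/(B+1)), so
  alpha = 0 selects nothing.
- Degenerate inputs error loudly: empty groups, zero events, all-constant
  design matrices, horizons before the first event, signatures with
  duplicate pairs or missing genes.

## Known limitations

- The log-rank screen tests each gene marginally at its median split;
  prognostic genes whose effect is not captured by a median dichotomy can
  be missed.
- Lasso selection among highly correlated pair indicators (pairs sharing
  a gene) may return a correlated proxy rather than the planted pair; the
  recovery criterion therefore asks for 4 of 5 pairs across replicates,
  not exact support recovery.
- The 1SE rule with 10 folds is noticeably conservative at weak signal;
  on small weak cohorts it can select nothing, which is reported as an
  error rather than silently relaxing the penalty.
- The published reference signature ships as a fixture for scoring and
  validation; refitting on new data is not expected to reproduce its
  exact coefficients (penalty-path and fold randomness).
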