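"""pairsig: rank-based gene-pair prognostic signatures for survival cohorts.

The package builds and evaluates prognostic signatures from within-sample
gene-expression orderings: binary pair indicators I(expr_A > expr_B) feed an
L1-penalized Cox model, the selected pairs form a risk score, and a
time-dependent ROC fixes the high/low-risk cutoff.  Because the features
depend only on orderings, a fitted signature transfers across cohorts with
different normalizations or batch structure without adjustment.
"""

from importlib import resources

from .evaluation import (
    ConcordanceResult,
    GroupComparison,
    KMCurve,
    TdROC,
    classify,
    compare_cindex,
    group_hr,
    harrell_cindex,
    km_estimate,
    optimal_cutoff,
    subgroup_analysis,
    td_roc_nne,
)
from .io import (
    CohortBundle,
    load_cohort,
    read_series_matrix,
    read_signature,
    read_survival,
    write_signature,
)
from .model import (
    FitDiagnostics,
    SignatureModel,
    fit_penalized_cox,
    pseudo_signature,
    risk_score,
    sensitivity_leave_one_pair_out,
)
from .pairs import (
    build_pair_matrix,
    enumerate_pairs,
    pair_indicator,
    prune_degenerate_pairs,
)
from .preprocess import collapse_probes, filter_genes
from .screening import logrank_test, permutation_pvalue, screen_prognostic_genes
from .synthetic import (
    SyntheticCohort,
    SyntheticConfig,
    apply_batch_transform,
    generate_cohort,
    generate_probe_matrix,
)

__version__ = "0.1.0"


def load_reference_signature() -> SignatureModel:
    """The published seven-pair gastric-cancer signature shipped with the package.

    Twelve genes form seven ordered pairs with Cox coefficients; the risk
    cutoff is -0.154 at a 5-year (60-month) ROC horizon.  Shipped as a
    read-only fixture for scoring and validation; refitting on new data is
    not expected to reproduce these exact coefficients (penalty-path and
    fold randomness).
    """
    from .io import read_signature

    data_dir = resources.files("pairsig").joinpath("data")
    with resources.as_file(data_dir) as path:
        return read_signature(path / "gc_pair_signature.tsv")
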