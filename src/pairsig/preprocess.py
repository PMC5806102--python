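"""Probe-to-gene collapsing and expression/variance pre-filters.

When a gene symbol is measured by several probes, the probe with the
largest inter-quartile range of expression across samples represents the
gene (high dynamic range probes track the transcript best).  Before
screening, the least-expressed and least-variable genes are removed to cut
the multiple-testing burden: genes in the lowest 20% by mean intensity,
then — among the survivors — genes in the lowest 20% by standard deviation.
"""

from __future__ import annotations

import logging
from math import floor
from typing import Union

import numpy as np
import pandas as pd
from scipy.stats import iqr

logger = logging.getLogger(__name__)


def collapse_probes(
    probes: pd.DataFrame,
    annotation: Union[pd.DataFrame, pd.Series, dict],
    multi_gene_policy: str = "drop",
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to one row per gene symbol.

    ``annotation`` maps probe_id -> gene_symbol (a DataFrame with those two
    columns, a Series indexed by probe, or a dict).  For genes with several
    probes the probe with maximal IQR is kept; IQR ties break toward the
    lexicographically smallest probe id.  Unannotated probes are dropped
    with a logged count.  A probe annotated to multiple distinct genes is
    discarded under the default policy ("drop", logged) to avoid counting
    one probe in several genes' pair space; policy "error" raises instead.
    """
    if isinstance(annotation, pd.DataFrame):
        ann = annotation[["probe_id", "gene_symbol"]].astype(str)
    elif isinstance(annotation, pd.Series):
        ann = annotation.rename_axis("probe_id").rename("gene_symbol").reset_index().astype(str)
    else:
        ann = pd.DataFrame(
            {"probe_id": list(annotation.keys()), "gene_symbol": list(annotation.values())}
        ).astype(str)

    multi = ann.groupby("probe_id")["gene_symbol"].nunique()
    ambiguous = multi.index[multi > 1].tolist()
    if ambiguous:
        if multi_gene_policy == "error":
            raise ValueError(f"probe(s) mapped to multiple genes: {ambiguous[:10]}")
        logger.info("dropped %d probes mapped to multiple genes", len(ambiguous))
        ann = ann[~ann["probe_id"].isin(ambiguous)]
    ann = ann.drop_duplicates()

    probe_to_gene = ann.set_index("probe_id")["gene_symbol"]
    annotated = probes.index.intersection(probe_to_gene.index)
    n_unannotated = probes.shape[0] - len(annotated)
    if n_unannotated:
        logger.info("dropped %d unannotated probes", n_unannotated)
    if len(annotated) == 0:
        raise ValueError("no annotated probes remain")

    sub = probes.loc[annotated]
    probe_iqr = pd.Series(iqr(sub.to_numpy(), axis=1), index=sub.index)
    table = pd.DataFrame(
        {"gene": probe_to_gene.loc[sub.index].to_numpy(), "iqr": probe_iqr}
    ).rename_axis("probe_id")
    # max IQR per gene; ties toward the lexicographically smallest probe id
    table = table.sort_values(["gene", "iqr", "probe_id"], ascending=[True, False, True])
    chosen = table.groupby("gene", sort=True).head(1)
    collapsed = sub.loc[chosen.index]
    collapsed.index = pd.Index(chosen["gene"].to_numpy(), name="gene")
    return collapsed.sort_index()


def filter_genes(
    expr: pd.DataFrame,
    low_expression_fraction: float = 0.20,
    low_variability_fraction: float = 0.20,
) -> pd.DataFrame:
    """Remove the least-expressed, then the least-variable genes.

    With G genes, the floor(f1*G) genes with the smallest mean intensity are
    dropped; among the G' survivors the floor(f2*G') genes with the smallest
    standard deviation are dropped.  Gene order of the survivors is
    preserved.  Genes containing missing values are removed up front (rank
    comparisons need complete vectors).  Mean/SD ties break by input order
    (among tied genes, earlier rows are dropped first — a stable sort).
    """
    for f in (low_expression_fraction, low_variability_fraction):
        if not (0.0 <= f < 1.0):
            raise ValueError("filter fractions must lie in [0, 1)")
    n_missing = int(expr.isna().any(axis=1).sum())
    if n_missing:
        logger.info("dropped %d genes with missing values before filtering", n_missing)
        expr = expr.dropna(axis=0)
    if expr.shape[0] == 0:
        raise ValueError("no complete genes to filter")

    def drop_lowest(df: pd.DataFrame, stat: pd.Series, fraction: float) -> pd.DataFrame:
        k = floor(fraction * df.shape[0])
        if k == 0:
            return df
        order = stat.sort_values(kind="mergesort")  # stable: ties keep input order
        dropped = set(order.index[:k])
        return df.loc[[g for g in df.index if g not in dropped]]

    out = drop_lowest(expr, expr.mean(axis=1), low_expression_fraction)
    out = drop_lowest(out, out.std(axis=1, ddof=1), low_variability_fraction)
    if out.shape[0] == 0:
        raise ValueError("all genes removed by filtering")
    return out
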