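"""Binary gene-pair indicator features.

A pair (A, B) scores 1 in a sample when A's expression strictly exceeds B's,
0 otherwise (ties score 0).  Because only the within-sample ordering enters,
the features are exactly invariant to any strictly monotone per-sample
transform of the expression values — the property that lets a fitted
signature travel across differently normalized cohorts.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PAIR_SEP = "|"


def pair_id(gene_a: str, gene_b: str) -> str:
    return f"{gene_a}{PAIR_SEP}{gene_b}"


def parse_pair_id(pid: str) -> tuple[str, str]:
    a, b = pid.split(PAIR_SEP)
    return a, b


def enumerate_pairs(genes: Sequence[str]) -> list[tuple[str, str]]:
    """All G*(G-1)/2 unordered pairs, slot order fixed by input order.

    The earlier gene of the input list takes slot 1 so the catalog is
    deterministic; the model's coefficient signs absorb the orientation.
    """
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in input")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    return list(combinations(genes, 2))


def pair_indicator(x_a: float, x_b: float) -> int:
    """1 iff x_a > x_b strictly; ties and reversals give 0."""
    return int(x_a > x_b)


def build_pair_matrix(expr: pd.DataFrame, pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Pairs x samples {0,1} matrix of within-sample order indicators."""
    index = set(expr.index)
    missing = sorted({g for p in pairs for g in p if g not in index})
    if missing:
        raise KeyError(f"pair genes absent from expression matrix: {missing[:10]}")
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values; drop them upstream")
    a_idx = [a for a, _ in pairs]
    b_idx = [b for _, b in pairs]
    A = expr.loc[a_idx].to_numpy()
    B = expr.loc[b_idx].to_numpy()
    values = (A > B).astype(np.uint8)
    return pd.DataFrame(
        values, index=pd.Index([pair_id(a, b) for a, b in pairs], name="pair"),
        columns=expr.columns,
    )


def prune_degenerate_pairs(m: pd.DataFrame, min_fraction: float = 0.0) -> pd.DataFrame:
    """Drop pairs whose indicator frequency is outside (min_fraction, 1-min_fraction).

    Bounds are inclusive, so the default 0.0 removes exactly the constant
    pairs (frequency 0 or 1), which carry no ordering information.
    """
    if not (0.0 <= min_fraction <= 0.5):
        raise ValueError("min_fraction must lie in [0, 0.5]")
    freq = m.mean(axis=1)
    keep = (freq > min_fraction) & (freq < 1.0 - min_fraction)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("pruned %d degenerate pairs (min_fraction=%g)", n_dropped, min_fraction)
    return m.loc[keep]
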