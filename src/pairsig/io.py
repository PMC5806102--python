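"""Readers and writers for the tabular formats the pipeline touches.

Covers plain TSV expression matrices, the GEO series-matrix text dialect
(``!``-prefixed metadata lines with the data table between the
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers),
survival tables, and the signature file format (TSV of gene pairs and
coefficients plus a JSON sidecar holding the cutoff and ROC horizon).
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import SignatureModel

logger = logging.getLogger(__name__)

#: sidecar filename suffix for signature metadata
_SIDECAR_SUFFIX = ".json"


@dataclass
class CohortBundle:
    """Expression + survival (+ optional clinical covariates) on one sample set.

    Sample identifiers are intersected and ordered identically on load;
    samples present on only one side are dropped with a logged count.
    """

    expression: pd.DataFrame
    survival: pd.DataFrame
    clinical: Optional[pd.DataFrame] = None


def read_series_matrix(path) -> pd.DataFrame:
    """Read an expression matrix from plain TSV or GEO series-matrix text.

    Lines starting with ``!`` are metadata and ignored; if table-begin/end
    markers are present only the delimited block is parsed.  Non-numeric
    cells become missing values (logged).  Duplicate row or sample ids and
    empty tables are errors.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if any(line.startswith("!") for line in lines):
        data_lines = []
        in_table = None  # None = no markers seen yet
        for line in lines:
            low = line.strip().lower()
            if low.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if low.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if line.startswith("!") or not line.strip():
                continue
            if in_table is None or in_table:
                data_lines.append(line)
        if not data_lines:
            raise ValueError(f"{path}: no data table found")
        body = "\n".join(data_lines)
    else:
        body = text
    header = body.splitlines()[0].split("\t")
    sample_ids = [h.strip('"') for h in header[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    df = pd.read_csv(_io.StringIO(body), sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression table")
    # GEO wraps identifiers in quotes; pandas strips them for cells but row
    # ids may retain them when the file mixes quoting styles.
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    n_bad = int(numeric.isna().sum().sum() - df.isna().sum().sum())
    if n_bad:
        logger.warning("%s: %d non-numeric cells set to missing", path, n_bad)
    return numeric


# a plain TSV matrix is the same dialect minus the metadata lines
read_expression = read_series_matrix


def read_survival(path, event_map: Optional[dict] = None) -> pd.DataFrame:
    """Read a survival TSV with columns sample_id, time, event.

    Extra columns are preserved as clinical covariates.  ``event_map``
    translates coded event labels (e.g. {"dead": 1, "alive": 0}); matching is
    case-insensitive.  Non-positive times and unknown event labels are errors
    that name the offending row.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    df["time"] = pd.to_numeric(df["time"])
    bad = df.index[df["time"] <= 0]
    if len(bad):
        raise ValueError(f"{path}: non-positive time for sample(s) {bad.tolist()[:5]}")
    if event_map is not None:
        mapping = {str(k).lower(): int(v) for k, v in event_map.items()}
        coded = df["event"].astype(str).str.lower().map(mapping)
        bad = df.index[coded.isna()]
        if len(bad):
            raise ValueError(f"{path}: unknown event label for sample(s) {bad.tolist()[:5]}")
        df["event"] = coded.astype(int)
    else:
        df["event"] = pd.to_numeric(df["event"]).astype(int)
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])]
        raise ValueError(f"{path}: event must be 0/1; offending sample(s) {bad.tolist()[:5]}")
    return df


def load_cohort(
    expression_path, survival_path, event_map: Optional[dict] = None
) -> CohortBundle:
    """Load expression + survival, intersect sample ids, normalize ordering."""
    expr = read_series_matrix(expression_path)
    surv = read_survival(survival_path, event_map=event_map)
    shared = [s for s in expr.columns if s in set(surv.index)]
    if not shared:
        raise ValueError("expression and survival share no sample ids")
    n_dropped = (expr.shape[1] - len(shared)) + (surv.shape[0] - len(shared))
    if n_dropped:
        logger.info("dropped %d samples present on only one side", n_dropped)
    expr = expr.loc[:, shared]
    surv = surv.loc[shared]
    clinical = surv.drop(columns=["time", "event"])
    if clinical.shape[1] == 0:
        clinical = None
    return CohortBundle(expression=expr, survival=surv[["time", "event"]], clinical=clinical)


def write_signature(model: SignatureModel, path) -> None:
    """Write a signature as TSV (gene_a, gene_b, coefficient) + JSON sidecar.

    Coefficients are serialized with 17 significant digits so that the
    TSV -> model -> TSV round trip is bit-stable.
    """
    path = Path(path)
    if len(model.entries) == 0:
        raise ValueError("refusing to write an empty signature")
    seen = set()
    for a, b, _ in model.entries:
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"duplicate pair {a}|{b} in signature")
        seen.add(key)
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tcoefficient\n")
        for a, b, coef in model.entries:
            fh.write(f"{a}\t{b}\t{coef:.17g}\n")
    sidecar = {
        "cutoff": model.cutoff,
        "horizon": model.horizon,
        "n_pairs": len(model.entries),
    }
    with open(path.with_suffix(path.suffix + _SIDECAR_SUFFIX), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_signature(path) -> SignatureModel:
    """Read a signature TSV (+ sidecar JSON, if present) back into a model."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_a": str, "gene_b": str}, float_precision="round_trip"
    )
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty signature")
    entries = [
        (str(r.gene_a), str(r.gene_b), float(r.coefficient)) for r in df.itertuples()
    ]
    seen = set()
    for a, b, _ in entries:
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"{path}: duplicate pair {a}|{b}")
        seen.add(key)
    cutoff = None
    horizon = None
    sidecar_path = path.with_suffix(path.suffix + _SIDECAR_SUFFIX)
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        cutoff = meta.get("cutoff")
        horizon = meta.get("horizon")
    return SignatureModel(entries=entries, cutoff=cutoff, horizon=horizon)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t")


def write_survival(surv: pd.DataFrame, path) -> None:
    surv.rename_axis("sample_id").to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    """Read a probe annotation TSV with columns probe_id, gene_symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"probe_id", "gene_symbol"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
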