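"""Reading, writing and preprocessing of expression and clinical tables.

Covers the microarray preprocessing used upstream of pattern
classification: collapsing multiple probes per gene to the probe with
the largest mean intensity, additive median-scale normalization on the
log2 scale, and the sign convention that converts qPCR delta-Ct values
into expression-oriented numbers (larger = more expressed).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


def read_expression_table(path, *, rows_are_genes: bool = True, sep: str | None = None) -> ExpressionMatrix:
    """Read a delimited gene-by-sample table into an :class:`ExpressionMatrix`.

    The file must have one header row of sample ids and a first id
    column.  Duplicate gene rows are rejected here; collapsing probe
    rows to genes is an explicit separate step (:func:`collapse_probes`).
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"duplicate sample ids in header: {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index.name = None
    df.columns.name = None
    if not rows_are_genes:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        na = df.isna()
        r = na.any(axis=1).idxmax()
        c = na.loc[r].idxmax()
        raise ValidationError(f"missing/non-numeric cell at row {r!r}, column {c!r} in {path}")
    return ExpressionMatrix(df)


def write_expression_table(matrix: ExpressionMatrix, path, *, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.data.to_csv(path, sep=sep, index_label="gene_id")


def read_probe_map(path, *, sep: str = "\t") -> pd.Series:
    """Two-column probe-to-gene map; returns probe_id -> gene_symbol."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("probe map needs two columns: probe_id, gene_symbol")
    probe, gene = df.columns[:2]
    if df[probe].duplicated().any():
        raise ValidationError("a probe maps to more than one gene symbol")
    return pd.Series(df[gene].to_numpy(), index=df[probe].to_numpy())


def collapse_probes(matrix: ExpressionMatrix, probe_map: pd.Series) -> ExpressionMatrix:
    """Collapse a probe-level matrix to genes.

    For each gene symbol, the retained row is the probe with the largest
    mean intensity across all samples; ties break on the
    lexicographically smallest probe id.
    """
    probes = matrix.data.index
    unmapped = [p for p in probes if p not in probe_map.index]
    if unmapped:
        raise ValidationError(f"probes without gene mapping: {unmapped[:20]}")
    means = matrix.data.mean(axis=1)
    # sort probes so the first row per gene is (max mean, then smallest probe id)
    order = pd.DataFrame({
        "gene": probe_map.loc[probes].to_numpy(),
        "mean": means.to_numpy(),
        "probe": probes.to_numpy(),
    })
    order = order.sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
    keep = order.drop_duplicates("gene", keep="first")
    collapsed = matrix.data.loc[keep["probe"]]
    collapsed.index = keep["gene"].to_numpy()
    return ExpressionMatrix(collapsed.sort_index())


def median_scale_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Median-scale normalization on the log2 scale.

    Each sample column is shifted additively so its median equals the
    global median of per-sample medians.  Within-sample rank order is
    unchanged; the operation is idempotent.
    """
    if matrix.data.empty:
        raise ValidationError("cannot normalize an empty matrix")
    med = matrix.data.median(axis=0)
    target = float(np.median(med.to_numpy()))
    return ExpressionMatrix(matrix.data - med + target)


def qpcr_to_expression(dct_table: pd.DataFrame) -> ExpressionMatrix:
    """Orient a delta-Ct table as expression: a greater delta-Ct means a
    lower expression level, so expression is taken as -delta-Ct."""
    df = dct_table.astype(float) if not isinstance(dct_table, ExpressionMatrix) else dct_table.data
    return ExpressionMatrix(-df)


def read_clinical_table(path, *, sep: str = "\t", event_map: dict | None = None) -> ClinicalTable:
    """Read a clinical TSV with columns id, time, event (plus optional
    covariates).  Rows with missing time or event are dropped and the
    count logged; a declared ``event_map`` recodes string events to 0/1."""
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    for req in ("id", "time", "event"):
        if req not in cols:
            raise ValidationError(f"clinical table missing required column {req!r}")
    df = df.rename(columns={cols["id"]: "id", cols["time"]: "time", cols["event"]: "event"})
    if event_map:
        df["event"] = df["event"].map(lambda v: event_map.get(v, v))
    n0 = len(df)
    df = df.dropna(subset=["time", "event"])
    if len(df) < n0:
        logger.info("dropped %d clinical rows lacking time or event", n0 - len(df))
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    df = df.set_index("id")
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path, *, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, sep=sep, index_label="id")
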