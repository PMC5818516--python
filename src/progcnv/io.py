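"""Readers and writers for the pipeline's tab-separated dialects.

All tables are TSV with a header row; lines starting with '#' are
comments.  CNV calls come either in long form (gene, sample, call,
cohort) or as a wide genes x samples matrix with a cohort sidecar —
the shape is auto-detected from the header.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .cnv import CALL_VALUES, CnvCallMatrix
from .concordance import ExpressionMatrix

logger = logging.getLogger(__name__)

_READ_KW = dict(sep="\t", comment="#", dtype=str)


def read_literature(path) -> pd.DataFrame:
    """Literature records: gene_symbol, pubmed_id, description."""
    df = pd.read_csv(path, **_READ_KW)
    required = {"gene_symbol", "pubmed_id", "description"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"literature table missing columns {sorted(missing)}")
    return df


def write_prognosis_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_cnv(path, cohorts_path=None) -> CnvCallMatrix:
    """Read CNV calls, auto-detecting long vs wide layout.

    Long layout has columns gene, sample, call[, cohort]; wide layout
    has a leading ``gene`` column and one column per sample, with
    cohort labels supplied via ``cohorts_path`` (TSV: sample, cohort).
    Without cohort information every sample lands in cohort "ALL".
    """
    df = pd.read_csv(path, **_READ_KW)
    cols = set(df.columns)
    if {"gene", "sample", "call"} <= cols:
        calls = df.pivot(index="gene", columns="sample", values="call")
        if calls.isna().any().any():
            raise ValueError("long CNV table is not complete over gene x sample")
        if "cohort" in cols:
            cohorts = df.drop_duplicates("sample").set_index("sample")["cohort"]
        else:
            cohorts = pd.Series("ALL", index=calls.columns)
    elif "gene" in cols:
        calls = df.set_index("gene")
        cohorts = None
    else:
        raise ValueError(
            "unrecognized CNV layout: need columns (gene, sample, call) or a "
            "wide matrix with a 'gene' column"
        )
    if cohorts is None:
        if cohorts_path is not None:
            sidecar = pd.read_csv(cohorts_path, **_READ_KW)
            cohorts = sidecar.set_index("sample")["cohort"]
        else:
            cohorts = pd.Series("ALL", index=calls.columns)
    bad = set(pd.unique(calls.to_numpy().ravel())) - set(CALL_VALUES)
    if bad:
        raise ValueError(f"unknown CNV call values: {sorted(bad)}")
    return CnvCallMatrix(calls=calls, cohorts=cohorts)


def write_cnv(matrix: CnvCallMatrix, path) -> None:
    """Write CNV calls in long form (gene, sample, call, cohort)."""
    long = (
        matrix.calls.stack()
        .rename("call")
        .rename_axis(["gene", "sample"])
        .reset_index()
    )
    long["cohort"] = matrix.cohorts.loc[long["sample"]].to_numpy()
    long.to_csv(path, sep="\t", index=False)


def read_expression(path, reference_path=None) -> ExpressionMatrix:
    """Wide genes x samples expression matrix, float-valued.

    ``reference_path`` is a one-column TSV (header ``sample``) listing
    the reference samples for Z-scoring.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "gene"
    reference: list[str] = []
    if reference_path is not None:
        ref = pd.read_csv(reference_path, **_READ_KW)
        reference = list(ref["sample"])
    return ExpressionMatrix(values=df.astype(float), reference_samples=reference)


def write_expression(expr: ExpressionMatrix, path, reference_path=None) -> None:
    expr.values.to_csv(path, sep="\t", float_format="%.10g")
    if reference_path is not None:
        pd.DataFrame({"sample": expr.reference_samples}).to_csv(
            reference_path, sep="\t", index=False
        )


def read_clinical(path) -> pd.DataFrame:
    """Clinical table: sample, os_months (float), os_event (0/1)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "os_months", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns {sorted(missing)}")
    df["sample"] = df["sample"].astype(str)
    df["os_months"] = df["os_months"].astype(float)
    df["os_event"] = df["os_event"].astype(int)
    return df


def read_edge_list(path) -> pd.DataFrame:
    """Interaction edges: gene_a, gene_b[, weight]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"gene_a", "gene_b"} - set(df.columns)
    if missing:
        raise ValueError(f"edge list missing columns {sorted(missing)}")
    return df


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
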