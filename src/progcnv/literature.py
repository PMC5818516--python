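"""Keyword screening of literature annotation records.

Records are short free-text statements linking a gene to a finding,
each carrying a PubMed identifier (GeneRIF-style).  A record is
prognosis-related when its description contains at least one term from
each of two keyword groups — {prognosis, prognostic} and
{cancer, tumour, tumor, carcinoma} — matched case-insensitively on
whole words.  Derivative forms such as "prognostically" are excluded
by the word-boundary rule but surfaced to the log so a curator can
review them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

PROGNOSIS_TERMS = ("prognosis", "prognostic")
CANCER_TERMS = ("cancer", "tumour", "tumor", "carcinoma")

_PROGNOSIS_RE = re.compile(
    r"\b(?:" + "|".join(PROGNOSIS_TERMS) + r")\b", re.IGNORECASE
)
_CANCER_RE = re.compile(r"\b(?:" + "|".join(CANCER_TERMS) + r")\b", re.IGNORECASE)

# Substring hits that fail the whole-word rule, e.g. "prognostically",
# "tumourigenesis"; reported, never counted.
_LOOSE_RE = re.compile(
    "|".join(f"{t}[a-z]+" for t in PROGNOSIS_TERMS + CANCER_TERMS), re.IGNORECASE
)


@dataclass(frozen=True)
class GeneAnnotationRecord:
    """One literature statement about a gene."""

    gene_symbol: str
    pubmed_id: str
    description: str

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if not self.pubmed_id:
            raise ValueError("pubmed_id must be non-empty")


def matches_prognosis_pattern(description: str) -> bool:
    """True iff the text holds a prognosis term AND a cancer term.

    Matching is case-insensitive and on word boundaries; an empty or
    missing description is False.
    """
    if not description or not isinstance(description, str):
        return False
    return bool(_PROGNOSIS_RE.search(description)) and bool(
        _CANCER_RE.search(description)
    )


def near_miss_terms(description: str) -> list[str]:
    """Substring-only keyword hits (e.g. 'prognostically') for logging."""
    if not description or not isinstance(description, str):
        return []
    return sorted({m.group(0).lower() for m in _LOOSE_RE.finditer(description)})


def build_prognosis_table(
    records: Iterable[GeneAnnotationRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Tabulate per-gene distinct-study counts over matching records.

    Parameters
    ----------
    records
        Either an iterable of :class:`GeneAnnotationRecord` or a
        DataFrame with columns ``gene_symbol``, ``pubmed_id``,
        ``description``.

    Returns
    -------
    DataFrame indexed by gene symbol with columns ``study_count``
    (number of distinct PubMed IDs among matching records) and
    ``pubmed_ids`` (comma-joined, sorted).  Only genes with at least
    one matching record appear.  Rows missing a gene symbol or PubMed
    ID are skipped with a warning; duplicate (gene, pubmed) pairs
    collapse.
    """
    if isinstance(records, pd.DataFrame):
        df = records.loc[:, ["gene_symbol", "pubmed_id", "description"]].copy()
    else:
        df = pd.DataFrame(
            [(r.gene_symbol, r.pubmed_id, r.description) for r in records],
            columns=["gene_symbol", "pubmed_id", "description"],
        )

    if df.empty:
        return pd.DataFrame(columns=["study_count", "pubmed_ids"]).rename_axis(
            "gene_symbol"
        )

    df["gene_symbol"] = df["gene_symbol"].astype("string").str.strip()
    df["pubmed_id"] = df["pubmed_id"].astype("string").str.strip()
    bad = df["gene_symbol"].isna() | (df["gene_symbol"] == "") | df[
        "pubmed_id"
    ].isna() | (df["pubmed_id"] == "")
    if bad.any():
        logger.warning("skipped %d unparseable literature rows", int(bad.sum()))
        df = df.loc[~bad]

    near_misses = 0
    keep = []
    for desc in df["description"]:
        ok = matches_prognosis_pattern(desc if isinstance(desc, str) else "")
        keep.append(ok)
        if not ok and near_miss_terms(desc if isinstance(desc, str) else ""):
            near_misses += 1
    if near_misses:
        logger.info(
            "%d non-matching records contain keyword-derived substrings "
            "(whole-word rule excluded them)",
            near_misses,
        )

    matched = df.loc[keep]
    if matched.empty:
        return pd.DataFrame(columns=["study_count", "pubmed_ids"]).rename_axis(
            "gene_symbol"
        )

    grouped = matched.groupby("gene_symbol")["pubmed_id"].agg(
        lambda s: sorted(set(s))
    )
    table = pd.DataFrame(
        {
            "study_count": grouped.map(len),
            "pubmed_ids": grouped.map(",".join),
        }
    ).rename_axis("gene_symbol")
    return table.sort_index()
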