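"""Per-gene copy-number profiling and the gain/loss ratio classification.

Discrete per-gene, per-sample copy-number calls (GAIN / LOSS / NEUTRAL)
are tallied across the pooled cohort.  A gene is classed CNG
(copy-number gained) when gained samples outnumber lost samples by more
than the ratio cut-off, CNL symmetrically, otherwise BALANCED.  Frequent
CNG genes — those with strictly more gained samples than the sample
cut-off — continue into the expression-concordance stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .thresholds import PipelineThresholds

logger = logging.getLogger(__name__)

GAIN = "GAIN"
LOSS = "LOSS"
NEUTRAL = "NEUTRAL"
CALL_VALUES = (GAIN, LOSS, NEUTRAL)

CNG = "CNG"
CNL = "CNL"
BALANCED = "BALANCED"


@dataclass
class CnvCallMatrix:
    """Genes x samples matrix of discrete copy-number calls.

    ``calls`` holds one of GAIN/LOSS/NEUTRAL per cell; ``cohorts`` maps
    every sample (column) to a cohort label.
    """

    calls: pd.DataFrame
    cohorts: pd.Series

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls.to_numpy())) - set(CALL_VALUES)
        if bad:
            raise ValueError(f"unknown CNV call values: {sorted(bad)}")
        missing = [s for s in self.calls.columns if s not in self.cohorts.index]
        if missing:
            raise ValueError(
                f"{len(missing)} samples lack a cohort label, e.g. {missing[:3]}"
            )
        self.cohorts = self.cohorts.loc[list(self.calls.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.calls.index

    @property
    def samples(self) -> pd.Index:
        return self.calls.columns

    def cohort_samples(self, cohort: str) -> list[str]:
        if cohort not in set(self.cohorts):
            known = sorted(set(self.cohorts))
            raise KeyError(f"unknown cohort {cohort!r}; known cohorts: {known}")
        return list(self.cohorts.index[self.cohorts == cohort])


@dataclass(frozen=True)
class GeneCnvProfile:
    gene: str
    n_gain: int
    n_loss: int
    gain_loss_ratio: float = field(default=math.nan)
    cnv_class: str = BALANCED


def classify_counts(
    n_gain: int, n_loss: int, ratio_cutoff: float = 2.0
) -> str:
    """Classify a gene from its gain/loss sample counts.

    CNG iff n_gain/n_loss > ratio_cutoff, CNL symmetrically.  A zero
    denominator with a positive numerator counts as an infinite ratio
    (passes); 0/0 is BALANCED.  For ratio_cutoff >= 1 the classes are
    mutually exclusive.
    """
    if n_gain < 0 or n_loss < 0:
        raise ValueError("counts must be nonnegative")
    if n_gain > 0 and (n_loss == 0 or n_gain / n_loss > ratio_cutoff):
        return CNG
    if n_loss > 0 and (n_gain == 0 or n_loss / n_gain > ratio_cutoff):
        return CNL
    return BALANCED


def profile_genes(
    matrix: CnvCallMatrix,
    genes: Iterable[str] | None = None,
    thresholds: PipelineThresholds | None = None,
) -> pd.DataFrame:
    """Tally gain/loss samples per gene and classify by the ratio rule.

    Parameters
    ----------
    matrix
        The call matrix; cohorts are pooled for counting.
    genes
        Restrict to these genes (e.g. the curated prognosis set).
        Genes absent from the matrix are reported and ignored.
    thresholds
        Supplies ``ratio_cutoff`` and ``min_cng_samples``; defaults used
        when omitted.

    Returns
    -------
    DataFrame indexed by gene with columns ``n_gain``, ``n_loss``,
    ``gain_loss_ratio`` (inf when n_loss=0 < n_gain, NaN for 0/0),
    ``cnv_class`` and ``passes_frequent_cng``.
    """
    thresholds = thresholds or PipelineThresholds()
    if genes is None:
        selected = matrix.genes
    else:
        genes = list(dict.fromkeys(genes))
        present = matrix.genes.intersection(genes)
        absent = set(genes) - set(present)
        if absent:
            logger.warning(
                "%d requested genes absent from CNV matrix, e.g. %s",
                len(absent),
                sorted(absent)[:5],
            )
        selected = matrix.genes[matrix.genes.isin(present)]
        if len(selected) == 0:
            logger.warning("no requested genes present in the CNV matrix")

    sub = matrix.calls.loc[selected]
    values = sub.to_numpy()
    n_gain = (values == GAIN).sum(axis=1)
    n_loss = (values == LOSS).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            n_loss > 0,
            n_gain / np.maximum(n_loss, 1),
            np.where(n_gain > 0, np.inf, np.nan),
        )
    classes = [
        classify_counts(int(g), int(l), thresholds.ratio_cutoff)
        for g, l in zip(n_gain, n_loss)
    ]
    profiles = pd.DataFrame(
        {
            "n_gain": n_gain.astype(int),
            "n_loss": n_loss.astype(int),
            "gain_loss_ratio": ratio,
            "cnv_class": classes,
        },
        index=pd.Index(selected, name="gene"),
    )
    profiles["passes_frequent_cng"] = (profiles["cnv_class"] == CNG) & (
        profiles["n_gain"] > thresholds.min_cng_samples
    )
    return profiles


def frequent_cng_filter(
    profiles: pd.DataFrame, thresholds: PipelineThresholds | None = None
) -> set[str]:
    """Genes classed CNG with strictly more gained samples than the cut-off."""
    thresholds = thresholds or PipelineThresholds()
    mask = (profiles["cnv_class"] == CNG) & (
        profiles["n_gain"] > thresholds.min_cng_samples
    )
    return set(profiles.index[mask])


def class_counts(profiles: pd.DataFrame) -> Mapping[str, int]:
    """Number of genes in each CNV class."""
    counts = profiles["cnv_class"].value_counts()
    return {cls: int(counts.get(cls, 0)) for cls in (CNG, CNL, BALANCED)}
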