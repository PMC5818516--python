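"""Expression Z-scores and CNV/expression concordance counting.

Per-sample over-expression is judged by the Z-score of a gene's
expression relative to a designated reference sample population:

    Z = (x - mu) / sigma

where x is the expression in the scored sample, mu the mean and sigma
the standard deviation of expression over the reference samples.  A
sample is over-expressed when Z exceeds the cut-off (default 2 SDs),
under-expressed when Z falls below its negation.  For each gene the
pipeline counts the matched samples that carry both a copy-number gain
and over-expression (and, symmetrically, loss with under-expression);
genes whose gain/over-expression count strictly exceeds the
concordant-sample cut-off become key genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cnv import GAIN, LOSS, CnvCallMatrix
from .thresholds import PipelineThresholds

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples continuous expression with a reference subset.

    ``reference_samples`` designates the samples whose mean/SD define
    the Z-score baseline (typically diploid or normal samples).  When
    empty, all samples serve as their own reference.  With
    ``reference_by_cohort`` set, mu and sigma are computed separately
    within each cohort's reference samples and applied to that cohort's
    tumour samples.
    """

    values: pd.DataFrame
    reference_samples: list[str] = field(default_factory=list)
    reference_by_cohort: Mapping[str, str] | None = None  # sample -> cohort

    def __post_init__(self) -> None:
        missing = [s for s in self.reference_samples if s not in self.values.columns]
        if missing:
            raise ValueError(
                f"{len(missing)} reference samples absent from the expression "
                f"matrix, e.g. {missing[:3]}"
            )
        if not self.reference_samples:
            logger.warning(
                "no reference samples designated; using all %d samples as "
                "their own reference",
                self.values.shape[1],
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def tumour_samples(self) -> list[str]:
        ref = set(self.reference_samples)
        return [s for s in self.values.columns if s not in ref]


def _reference_stats(
    expr: ExpressionMatrix, columns: list[str]
) -> tuple[pd.Series, pd.Series]:
    ref = expr.values.loc[:, columns]
    return ref.mean(axis=1), ref.std(axis=1, ddof=1)


def z_scores(expr: ExpressionMatrix) -> pd.DataFrame:
    """Z-score every cell against the reference mean and SD.

    Genes with zero or non-finite reference SD are excluded with a
    warning — a Z-score is undefined for them.  Missing expression
    values propagate to missing Z values.
    """
    ref_cols = expr.reference_samples or list(expr.values.columns)
    if expr.reference_by_cohort is None:
        mu, sigma = _reference_stats(expr, ref_cols)
        z = expr.values.sub(mu, axis=0).div(sigma, axis=0)
    else:
        cohort_of = pd.Series(expr.reference_by_cohort)
        z = pd.DataFrame(
            np.nan, index=expr.values.index, columns=expr.values.columns
        )
        sigma = pd.Series(np.nan, index=expr.values.index)
        for cohort in sorted(set(cohort_of.loc[cohort_of.index.intersection(ref_cols)])):
            cohort_refs = [s for s in ref_cols if cohort_of.get(s) == cohort]
            cohort_cols = [
                s for s in expr.values.columns if cohort_of.get(s) == cohort
            ]
            mu_c, sigma_c = _reference_stats(expr, cohort_refs)
            z.loc[:, cohort_cols] = (
                expr.values.loc[:, cohort_cols].sub(mu_c, axis=0).div(sigma_c, axis=0)
            )
            sigma = sigma.combine(sigma_c, np.fmin)
    degenerate = ~(sigma > 0)
    if degenerate.any():
        logger.warning(
            "excluding %d genes with zero/undefined reference SD, e.g. %s",
            int(degenerate.sum()),
            list(sigma.index[degenerate][:5]),
        )
        z = z.loc[~degenerate]
    return z


def call_overexpressed(
    z: pd.DataFrame, thresholds: PipelineThresholds | None = None
) -> pd.DataFrame:
    """Boolean matrix: Z strictly above the cut-off (missing Z -> False)."""
    thresholds = thresholds or PipelineThresholds()
    return z.gt(thresholds.z_cutoff).fillna(False)


def call_underexpressed(
    z: pd.DataFrame, thresholds: PipelineThresholds | None = None
) -> pd.DataFrame:
    """Boolean matrix: Z strictly below the negated cut-off."""
    thresholds = thresholds or PipelineThresholds()
    return z.lt(-thresholds.z_cutoff).fillna(False)


def count_concordance(
    cnv: CnvCallMatrix,
    over: pd.DataFrame,
    under: pd.DataFrame | None = None,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Count matched samples concordant for gain+over / loss+under.

    Only samples present in both the CNV matrix and the expression call
    matrices are counted; the overlap size is logged.  Raises if the
    two sample universes are disjoint.

    Returns a DataFrame indexed by gene with columns ``n_gain``,
    ``n_gain_over``, ``n_loss``, ``n_loss_under`` (restricted to the
    shared samples).
    """
    shared = [s for s in cnv.samples if s in set(over.columns)]
    if not shared:
        raise ValueError(
            "no shared samples between CNV calls "
            f"({len(cnv.samples)} samples, e.g. {list(cnv.samples[:3])}) and "
            f"expression calls ({over.shape[1]} samples, e.g. "
            f"{list(over.columns[:3])})"
        )
    logger.info(
        "concordance over %d shared samples (%d CNV, %d expression)",
        len(shared),
        len(cnv.samples),
        over.shape[1],
    )

    if genes is None:
        gene_index = cnv.genes.intersection(over.index)
        gene_index = cnv.genes[cnv.genes.isin(gene_index)]
    else:
        wanted = list(dict.fromkeys(genes))
        gene_index = pd.Index(
            [g for g in wanted if g in cnv.genes and g in over.index], name="gene"
        )
        dropped = set(wanted) - set(gene_index)
        if dropped:
            logger.warning(
                "%d genes absent from CNV or expression matrix, e.g. %s",
                len(dropped),
                sorted(dropped)[:5],
            )

    calls = cnv.calls.loc[gene_index, shared].to_numpy()
    over_m = over.loc[gene_index, shared].to_numpy(dtype=bool)
    gain = calls == GAIN
    loss = calls == LOSS
    out = pd.DataFrame(
        {
            "n_gain": gain.sum(axis=1).astype(int),
            "n_gain_over": (gain & over_m).sum(axis=1).astype(int),
            "n_loss": loss.sum(axis=1).astype(int),
        },
        index=pd.Index(gene_index, name="gene"),
    )
    if under is not None:
        under_m = under.loc[gene_index, shared].to_numpy(dtype=bool)
        out["n_loss_under"] = (loss & under_m).sum(axis=1).astype(int)
    else:
        out["n_loss_under"] = 0
    return out


def select_key_genes(
    records: pd.DataFrame,
    thresholds: PipelineThresholds | None = None,
    mode: str = "count",
) -> set[str]:
    """Select genes passing the concordant-sample cut-off.

    mode="count" (default) retains genes with
    ``n_gain_over > min_concordant_samples``.  mode="ratio" instead
    applies the cut-off to the ratio ``n_gain_over / n_loss_under``
    (with a zero denominator and positive numerator treated as
    infinite).
    """
    thresholds = thresholds or PipelineThresholds()
    cutoff = thresholds.min_concordant_samples
    if mode == "count":
        mask = records["n_gain_over"] > cutoff
    elif mode == "ratio":
        num = records["n_gain_over"].to_numpy(dtype=float)
        den = records["n_loss_under"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den > 0, num / np.maximum(den, 1.0),
                             np.where(num > 0, np.inf, 0.0))
        mask = pd.Series(ratio > cutoff, index=records.index)
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return set(records.index[mask])
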