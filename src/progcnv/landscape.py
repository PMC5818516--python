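"""OncoPrint-style per-cohort alteration summaries.

A sample is "altered" with respect to a gene list when it carries a
GAIN or LOSS call in at least one listed gene.  Per-gene amplification
(gain) and deletion (loss) frequencies are fractions of cohort samples;
the two-level distinction some portals draw (gain vs amplification,
shallow vs deep deletion) is collapsed to the binary calls this
pipeline models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .cnv import GAIN, LOSS, CnvCallMatrix

logger = logging.getLogger(__name__)


@dataclass
class CohortAlterationSummary:
    cohort: str
    n_samples: int
    n_altered_samples: int
    gene_gain_freq: pd.Series  # fraction of cohort samples with GAIN, per gene
    gene_loss_freq: pd.Series

    @property
    def altered_fraction(self) -> float:
        return self.n_altered_samples / self.n_samples if self.n_samples else 0.0


def summarize_cohort(
    cnv: CnvCallMatrix, genes: Iterable[str], cohort: str
) -> CohortAlterationSummary:
    """Alteration summary of one cohort over a gene list.

    Raises KeyError (listing known cohorts) for an unknown cohort;
    listed genes absent from the matrix are ignored with a warning.
    """
    samples = cnv.cohort_samples(cohort)  # raises with known cohorts listed
    wanted = list(dict.fromkeys(genes))
    present = [g for g in wanted if g in cnv.genes]
    if len(present) < len(wanted):
        logger.warning(
            "cohort %s: %d listed genes absent from CNV matrix",
            cohort,
            len(wanted) - len(present),
        )
    sub = cnv.calls.loc[present, samples]
    gain = sub.eq(GAIN)
    loss = sub.eq(LOSS)
    altered = (gain | loss).any(axis=0)
    return CohortAlterationSummary(
        cohort=cohort,
        n_samples=len(samples),
        n_altered_samples=int(altered.sum()),
        gene_gain_freq=gain.sum(axis=1) / len(samples),
        gene_loss_freq=loss.sum(axis=1) / len(samples),
    )


def summarize_all(
    cnv: CnvCallMatrix, genes: Iterable[str]
) -> dict[str, CohortAlterationSummary]:
    genes = list(genes)
    return {
        cohort: summarize_cohort(cnv, genes, cohort)
        for cohort in sorted(set(cnv.cohorts))
    }


def top_amplified(summary: CohortAlterationSummary, k: int = 20) -> list[str]:
    """Top-k genes by gain frequency, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    freq = summary.gene_gain_freq
    if k > len(freq):
        logger.warning(
            "cohort %s: k=%d exceeds gene list size %d; returning all",
            summary.cohort,
            k,
            len(freq),
        )
        k = len(freq)
    ranked = sorted(freq.items(), key=lambda item: (-item[1], item[0]))
    return [gene for gene, _ in ranked[:k]]


def cross_cohort_common(ranked_lists: Sequence[Iterable[str]]) -> set[str]:
    """Genes present in every per-cohort top-k list (>= 2 cohorts)."""
    if len(ranked_lists) < 2:
        raise ValueError("need ranked lists from at least 2 cohorts")
    common = set(ranked_lists[0])
    for lst in ranked_lists[1:]:
        common &= set(lst)
    return common


def landscape_tables(
    summaries: dict[str, CohortAlterationSummary],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long per-(cohort, gene) frequency table + per-cohort summary table."""
    freq_rows = []
    cohort_rows = []
    for cohort, s in sorted(summaries.items()):
        for gene in s.gene_gain_freq.index:
            freq_rows.append(
                (cohort, gene, s.gene_gain_freq[gene], s.gene_loss_freq[gene])
            )
        cohort_rows.append((cohort, s.n_samples, s.n_altered_samples,
                            s.altered_fraction))
    freq = pd.DataFrame(
        freq_rows, columns=["cohort", "gene", "gain_freq", "loss_freq"]
    )
    cohorts = pd.DataFrame(
        cohort_rows,
        columns=["cohort", "n_samples", "n_altered_samples", "altered_fraction"],
    )
    return freq, cohorts
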