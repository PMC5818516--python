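"""Synthetic cancer-cohort generator with planted driver genes.

Emits a complete, internally consistent input bundle — literature
records, discrete CNV calls with cohort labels, an expression matrix
with designated reference samples, a clinical table, gene sets and an
interaction network — whose signal is known by construction:

* each planted driver gene receives GAIN calls in an exact fraction of
  tumour samples, and its expression in those samples is shifted
  upward by a chosen number of reference standard deviations
  (gene dosage effect);
* background genes gain/lose independently at low per-cell rates;
* samples carrying at least one planted-gene gain draw their survival
  times from an exponential model with an elevated hazard, with
  administrative censoring at a fixed horizon;
* one designated gene set contains a known number of planted genes,
  the rest are random decoys;
* the network links planted seed genes through a pool of linker genes.

The accompanying :class:`SyntheticTruth` records the planted genes,
their realized gain-sample sets and concordant-sample counts, all
recomputable from the emitted matrices by direct counting.  A given
config and seed fully determine every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import CnvCallMatrix, GAIN, LOSS, NEUTRAL
from .concordance import ExpressionMatrix
from . import io as pio
from .enrichment import write_gmt

_MATCHING_TEMPLATES = (
    "High {gene} expression predicts poor prognosis in {tissue} cancer",
    "{gene} is an independent prognostic factor in {tissue} carcinoma",
    "Overexpression of {gene} correlates with adverse prognosis in "
    "{tissue} tumour samples",
    "{gene} expression is a prognostic biomarker in patients with "
    "{tissue} tumor",
)
_NONMATCHING_TEMPLATES = (
    "{gene} regulates mitotic spindle assembly in dividing cells",
    "{gene} participates in ribosome biogenesis and rRNA processing",
    "Loss of {gene} alters membrane trafficking in epithelial cells",
    "{gene} is prognostically uninformative in population screening",
)
_TISSUES = ("breast", "lung", "colorectal", "gastric", "ovarian", "hepatic")


class SyntheticConfigError(ValueError):
    """Raised when a generator configuration field is invalid."""


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a pan-cancer-style cohort: 500 genes by 600
    tumour samples over 3 cohorts, 12 planted drivers gained in 10% of
    samples with a 3-SD expression dosage shift, 2% background
    gain/loss rates, and a threefold hazard for altered samples.
    """

    n_genes: int = 500
    n_samples: int = 600
    n_cohorts: int = 3
    n_reference_samples: int = 100
    planted_genes: list[str] = field(default_factory=list)
    planted_gain_fraction: float = 0.1
    dosage_shift: float = 3.0
    background_gain_rate: float = 0.02
    background_loss_rate: float = 0.02
    hazard_ratio_altered: float = 3.0
    n_gene_sets: int = 10
    planted_set_overlap: int = 8
    seed: int = 0
    # secondary knobs (not part of the planted-signal contract)
    prognosis_fraction: float = 0.6
    baseline_median_months: float = 40.0
    censor_horizon_months: float = 120.0
    gene_set_size: int = 30

    def __post_init__(self) -> None:
        if not self.planted_genes:
            self.planted_genes = [f"DRV{i + 1:02d}" for i in range(12)]
        checks = {
            "n_genes": self.n_genes >= len(self.planted_genes) and self.n_genes > 0,
            "n_samples": self.n_samples > 0,
            "n_cohorts": 1 <= self.n_cohorts <= self.n_samples,
            "n_reference_samples": self.n_reference_samples >= 3,
            "planted_gain_fraction": 0 <= self.planted_gain_fraction <= 1,
            "background_gain_rate": 0 <= self.background_gain_rate <= 1,
            "background_loss_rate": 0 <= self.background_loss_rate <= 1
            and self.background_gain_rate + self.background_loss_rate <= 1,
            "dosage_shift": np.isfinite(self.dosage_shift),
            "hazard_ratio_altered": self.hazard_ratio_altered > 0,
            "n_gene_sets": self.n_gene_sets >= 1,
            "planted_set_overlap": 0
            <= self.planted_set_overlap
            <= len(self.planted_genes),
            "seed": isinstance(self.seed, (int, np.integer)) and self.seed >= 0,
            "prognosis_fraction": 0 <= self.prognosis_fraction <= 1,
            "baseline_median_months": self.baseline_median_months > 0,
            "censor_horizon_months": self.censor_horizon_months > 0,
            "gene_set_size": self.gene_set_size >= 1,
        }
        for fname, ok in checks.items():
            if not ok:
                raise SyntheticConfigError(
                    f"invalid configuration field {fname!r}: "
                    f"{getattr(self, fname)!r}"
                )
        if len(set(self.planted_genes)) != len(self.planted_genes):
            raise SyntheticConfigError("invalid configuration field "
                                       "'planted_genes': duplicates present")


@dataclass
class SyntheticTruth:
    """Planted signal, recomputable from the emitted matrices."""

    planted_genes: list[str]
    gain_samples: dict[str, list[str]]
    concordant_counts: dict[str, int]
    altered_samples: list[str]
    prognosis_genes: list[str]
    enriched_set: str
    seed: int


@dataclass
class SyntheticBundle:
    literature: pd.DataFrame
    cnv: CnvCallMatrix
    expression: ExpressionMatrix
    clinical: pd.DataFrame
    gene_sets: dict[str, set[str]]
    gene_set_descriptions: dict[str, str]
    network_edges: pd.DataFrame
    truth: SyntheticTruth


def _gene_universe(config: SyntheticConfig) -> list[str]:
    background = [
        f"G{i + 1:04d}" for i in range(config.n_genes - len(config.planted_genes))
    ]
    return list(config.planted_genes) + background


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the full input bundle for one seeded cohort."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config)
    n_genes, n_samples = len(genes), config.n_samples
    planted_idx = {g: i for i, g in enumerate(config.planted_genes)}

    tumour_samples = [f"T{i + 1:04d}" for i in range(n_samples)]
    reference_samples = [f"N{i + 1:04d}" for i in range(config.n_reference_samples)]
    cohorts = pd.Series(
        [f"COHORT_{i % config.n_cohorts + 1}" for i in range(n_samples)],
        index=pd.Index(tumour_samples, name="sample"),
        name="cohort",
    )

    # --- CNV calls: background rates everywhere, exact planted gains ---
    u = rng.random((n_genes, n_samples))
    gain = u < config.background_gain_rate
    loss = (~gain) & (
        u < config.background_gain_rate + config.background_loss_rate
    )
    n_planted_gain = round(config.planted_gain_fraction * n_samples)
    for g, row in planted_idx.items():
        chosen = rng.choice(n_samples, size=n_planted_gain, replace=False)
        gain[row, :] = False
        loss[row, :] = False
        gain[row, chosen] = True
        rest = np.setdiff1d(np.arange(n_samples), chosen)
        loss_draw = rng.random(rest.size) < config.background_loss_rate
        loss[row, rest[loss_draw]] = True
    calls = np.where(gain, GAIN, np.where(loss, LOSS, NEUTRAL))
    cnv = CnvCallMatrix(
        calls=pd.DataFrame(calls, index=pd.Index(genes, name="gene"),
                           columns=tumour_samples),
        cohorts=cohorts,
    )

    # --- expression: gene-specific normal background + dosage shift ---
    mu = rng.uniform(4.0, 12.0, size=n_genes)
    sd = rng.uniform(0.5, 2.0, size=n_genes)
    ref = rng.normal(
        mu[:, None], sd[:, None], size=(n_genes, config.n_reference_samples)
    )
    tum = rng.normal(mu[:, None], sd[:, None], size=(n_genes, n_samples))
    ref_mean = ref.mean(axis=1)
    ref_sd = ref.std(axis=1, ddof=1)
    for g, row in planted_idx.items():
        gained = gain[row]
        tum[row, gained] += config.dosage_shift * ref_sd[row]
    values = pd.DataFrame(
        np.hstack([tum, ref]),
        index=pd.Index(genes, name="gene"),
        columns=tumour_samples + reference_samples,
    )
    expression = ExpressionMatrix(values=values,
                                  reference_samples=reference_samples)

    # --- literature: keyword-positive records for the prognosis subset ---
    n_prognosis = max(len(config.planted_genes),
                      round(config.prognosis_fraction * n_genes))
    background_pool = [g for g in genes if g not in planted_idx]
    extra = rng.choice(
        len(background_pool),
        size=min(n_prognosis - len(config.planted_genes), len(background_pool)),
        replace=False,
    )
    prognosis_genes = list(config.planted_genes) + [
        background_pool[i] for i in sorted(extra)
    ]
    prognosis_set = set(prognosis_genes)
    rows = []
    pmid = 10_000_000
    for gene in genes:
        if gene in prognosis_set:
            n_records = 1 + int(rng.integers(0, 3))
            for _ in range(n_records):
                pmid += 1
                template = _MATCHING_TEMPLATES[
                    int(rng.integers(0, len(_MATCHING_TEMPLATES)))
                ]
                tissue = _TISSUES[int(rng.integers(0, len(_TISSUES)))]
                rows.append((gene, str(pmid),
                             template.format(gene=gene, tissue=tissue)))
        else:
            pmid += 1
            template = _NONMATCHING_TEMPLATES[
                int(rng.integers(0, len(_NONMATCHING_TEMPLATES)))
            ]
            rows.append((gene, str(pmid), template.format(gene=gene)))
    literature = pd.DataFrame(
        rows, columns=["gene_symbol", "pubmed_id", "description"]
    )

    # --- clinical: exponential survival with altered-group hazard ratio ---
    planted_rows = [planted_idx[g] for g in config.planted_genes]
    altered_mask = gain[planted_rows, :].any(axis=0)
    base_rate = np.log(2.0) / config.baseline_median_months
    rate = np.where(altered_mask,
                    base_rate * config.hazard_ratio_altered, base_rate)
    t = rng.exponential(1.0 / rate)
    t = np.maximum(t, 1e-3)
    event = t <= config.censor_horizon_months
    clinical = pd.DataFrame(
        {
            "sample": tumour_samples,
            "os_months": np.minimum(t, config.censor_horizon_months),
            "os_event": event.astype(int),
        }
    )

    # --- gene sets: one planted-enriched set plus random decoys ---
    gene_sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    planted_members = list(config.planted_genes[: config.planted_set_overlap])
    n_fill = max(0, min(config.gene_set_size, n_genes) - len(planted_members))
    fill = rng.choice(
        len(background_pool),
        size=min(n_fill, len(background_pool)),
        replace=False,
    )
    enriched_name = "PLANTED_DRIVER_SET"
    gene_sets[enriched_name] = set(planted_members) | {
        background_pool[i] for i in fill
    }
    descriptions[enriched_name] = "set seeded with planted driver genes"
    for j in range(config.n_gene_sets - 1):
        members = rng.choice(n_genes, size=min(config.gene_set_size, n_genes),
                             replace=False)
        name = f"RANDOM_SET_{j + 2:02d}"
        gene_sets[name] = {genes[i] for i in members}
        descriptions[name] = "random decoy set"

    # --- interaction network: seed clique-ish core plus linker genes ---
    edges: set[tuple[str, str]] = set()
    planted = config.planted_genes
    for i in range(len(planted)):
        for j in range(i + 1, len(planted)):
            if rng.random() < 0.35:
                edges.add(tuple(sorted((planted[i], planted[j]))))
    n_linkers = min(25, len(background_pool))
    linker_pool = rng.choice(len(background_pool), size=n_linkers, replace=False)
    for i in linker_pool:
        linker = background_pool[i]
        n_links = 1 + int(rng.integers(0, min(5, len(planted))))
        targets = rng.choice(len(planted), size=n_links, replace=False)
        for j in targets:
            edges.add(tuple(sorted((linker, planted[j]))))
    for _ in range(40):  # background noise edges
        a, b = rng.choice(len(background_pool), size=2, replace=False)
        edges.add(tuple(sorted((background_pool[a], background_pool[b]))))
    network_edges = pd.DataFrame(
        sorted(edges), columns=["gene_a", "gene_b"]
    )

    # --- truth: direct counting on the emitted matrices ---
    z = (tum - ref_mean[:, None]) / ref_sd[:, None]
    over = z > 2.0
    sample_arr = np.array(tumour_samples)
    gain_samples = {
        g: sorted(sample_arr[gain[planted_idx[g]]]) for g in planted
    }
    concordant = {
        g: int((gain[planted_idx[g]] & over[planted_idx[g]]).sum())
        for g in planted
    }
    truth = SyntheticTruth(
        planted_genes=list(planted),
        gain_samples=gain_samples,
        concordant_counts=concordant,
        altered_samples=sorted(sample_arr[altered_mask]),
        prognosis_genes=sorted(prognosis_set),
        enriched_set=enriched_name,
        seed=config.seed,
    )
    return SyntheticBundle(
        literature=literature,
        cnv=cnv,
        expression=expression,
        clinical=clinical,
        gene_sets=gene_sets,
        gene_set_descriptions=descriptions,
        network_edges=network_edges,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write every bundle component in the dialects the readers consume."""
    out = pio.ensure_dir(outdir)
    paths = {
        "literature": out / "literature.tsv",
        "cnv": out / "cnv_calls.tsv",
        "expression": out / "expression.tsv",
        "reference_samples": out / "reference_samples.tsv",
        "clinical": out / "clinical.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "network": out / "network_edges.tsv",
        "truth": out / "truth.json",
    }
    bundle.literature.to_csv(paths["literature"], sep="\t", index=False)
    pio.write_cnv(bundle.cnv, paths["cnv"])
    pio.write_expression(bundle.expression, paths["expression"],
                         paths["reference_samples"])
    bundle.clinical.to_csv(paths["clinical"], sep="\t", index=False,
                           float_format="%.10g")
    write_gmt(bundle.gene_sets, paths["gene_sets"],
              bundle.gene_set_descriptions)
    pio.write_edge_list(bundle.network_edges, paths["network"])

    import json

    truth = bundle.truth
    with open(paths["truth"], "w") as handle:
        json.dump(
            {
                "planted_genes": truth.planted_genes,
                "gain_samples": truth.gain_samples,
                "concordant_counts": truth.concordant_counts,
                "altered_samples": truth.altered_samples,
                "prognosis_genes": truth.prognosis_genes,
                "enriched_set": truth.enriched_set,
                "seed": truth.seed,
            },
            handle,
            indent=1,
            sort_keys=True,
        )
    return paths
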