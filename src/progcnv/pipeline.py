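"""End-to-end orchestration of the gene-prioritization funnel.

Stages run in order: literature curation -> CNV profiling ->
expression concordance -> key-gene selection, then the downstream
summaries (enrichment, cohort landscape, survival, network) on the key
gene list.  A run manifest records the config snapshot, the per-stage
gene counts of the funnel, output paths and machine-readable warnings.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as pio
from .cnv import class_counts, frequent_cng_filter, profile_genes, CnvCallMatrix
from .concordance import (
    ExpressionMatrix,
    call_overexpressed,
    call_underexpressed,
    count_concordance,
    select_key_genes,
    z_scores,
)
from .enrichment import GeneSetCollection, enrich, read_gmt
from .landscape import (
    cross_cohort_common,
    landscape_tables,
    summarize_all,
    top_amplified,
)
from .literature import build_prognosis_table
from .network import degree_table, load_network, neighborhood
from .survival import assign_groups, km_fit, km_table, log_rank, ALTERED
from .thresholds import PipelineThresholds

logger = logging.getLogger(__name__)

STAGES = (
    "curation",
    "cnv_profiling",
    "expression_concordance",
    "key_gene_selection",
    "enrichment",
    "cohort_landscape",
    "survival",
    "network_summary",
)


class PipelineError(Exception):
    """Configuration problem detected before any stage ran."""


class StageFailure(Exception):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    prognosis_table: pd.DataFrame
    profiles: pd.DataFrame
    concordance: pd.DataFrame
    key_genes: set[str]
    manifest: dict[str, Any]
    enrichment: pd.DataFrame | None = None
    landscape: dict[str, Any] = field(default_factory=dict)
    survival: Any | None = None
    survival_groups: pd.DataFrame | None = None
    network: dict[str, Any] = field(default_factory=dict)


def _funnel(
    prognosis_table, profiles, frequent, key_genes
) -> dict[str, int]:
    counts = class_counts(profiles)
    return {
        "curated": int(len(prognosis_table)),
        "cnv_overlapping": int(len(profiles)),
        "cng": counts["CNG"],
        "cnl": counts["CNL"],
        "balanced": counts["BALANCED"],
        "frequent_cng": int(len(frequent)),
        "key_genes": int(len(key_genes)),
    }


def run_stages(
    literature: pd.DataFrame,
    cnv: CnvCallMatrix,
    expression: ExpressionMatrix,
    clinical: pd.DataFrame | None = None,
    gene_sets: dict[str, set[str]] | None = None,
    network_edges: pd.DataFrame | None = None,
    thresholds: PipelineThresholds | None = None,
    key_gene_mode: str = "count",
    top_k: int = 20,
    max_linkers: int = 20,
) -> PipelineResult:
    """Run the funnel and downstream summaries on in-memory inputs.

    Downstream stages that lack their input (no clinical table, no gene
    sets, empty key-gene list) are skipped with a machine-readable
    warning in the manifest rather than failing the run.
    """
    thresholds = thresholds or PipelineThresholds()
    warnings: list[dict[str, str]] = []

    def warn(stage: str, message: str) -> None:
        warnings.append({"stage": stage, "message": message})
        logger.warning("[%s] %s", stage, message)

    def run(stage: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageFailure(stage, exc) from exc

    prognosis_table = run("curation", lambda: build_prognosis_table(literature))
    curated = list(prognosis_table.index)

    profiles = run(
        "cnv_profiling", lambda: profile_genes(cnv, curated, thresholds)
    )
    frequent = frequent_cng_filter(profiles, thresholds)

    def _concordance():
        z = z_scores(expression)
        over = call_overexpressed(z, thresholds)
        under = call_underexpressed(z, thresholds)
        return count_concordance(cnv, over, under, sorted(frequent))

    records = run("expression_concordance", _concordance)
    key_genes = run(
        "key_gene_selection",
        lambda: select_key_genes(records, thresholds, mode=key_gene_mode),
    )
    if not key_genes:
        warn("key_gene_selection",
             "no gene passed the concordance cut-off; downstream stages "
             "run on an empty list or are skipped")

    result = PipelineResult(
        prognosis_table=prognosis_table,
        profiles=profiles,
        concordance=records,
        key_genes=key_genes,
        manifest={},
    )

    if gene_sets is not None and key_genes:
        universe = set(cnv.genes)
        collection = GeneSetCollection.from_mapping(gene_sets, universe)
        result.enrichment = run(
            "enrichment", lambda: enrich(key_genes, collection)
        )
    elif gene_sets is not None:
        warn("enrichment", "skipped: empty key-gene list")

    if key_genes:
        def _landscape():
            summaries = summarize_all(cnv, sorted(key_genes))
            tops = {c: top_amplified(s, top_k) for c, s in summaries.items()}
            common = (
                cross_cohort_common(list(tops.values()))
                if len(tops) >= 2
                else set(next(iter(tops.values()), []))
            )
            freq, cohorts_df = landscape_tables(summaries)
            return {
                "summaries": summaries,
                "frequencies": freq,
                "cohorts": cohorts_df,
                "top_amplified": tops,
                "common_genes": common,
            }

        result.landscape = run("cohort_landscape", _landscape)
    else:
        warn("cohort_landscape", "skipped: empty key-gene list")

    if clinical is not None and key_genes:
        def _survival():
            groups = assign_groups(cnv, sorted(key_genes), clinical)
            if groups["group"].nunique() < 2:
                warn("survival",
                     "only one survival group present; log-rank skipped")
                return groups, None
            return groups, log_rank(groups)

        result.survival_groups, result.survival = run("survival", _survival)
    elif clinical is not None:
        warn("survival", "skipped: empty key-gene list")

    if network_edges is not None and key_genes:
        def _network():
            graph = load_network(network_edges)
            seeds = sorted(
                result.landscape.get("common_genes") or key_genes
            )
            seeds_present = [s for s in seeds if s in graph]
            if not seeds_present:
                warn("network_summary",
                     "skipped: no key gene present in the network")
                return {}
            sub, linkers = neighborhood(graph, seeds, max_linkers)
            return {
                "subnetwork": sub,
                "linkers": linkers,
                "degrees": degree_table(sub),
                "seeds": seeds_present,
            }

        result.network = run("network_summary", _network)
    elif network_edges is not None:
        warn("network_summary", "skipped: empty key-gene list")

    result.manifest = {
        "thresholds": {
            "ratio_cutoff": thresholds.ratio_cutoff,
            "min_cng_samples": thresholds.min_cng_samples,
            "z_cutoff": thresholds.z_cutoff,
            "min_concordant_samples": thresholds.min_concordant_samples,
        },
        "key_gene_mode": key_gene_mode,
        "funnel": _funnel(prognosis_table, profiles, frequent, key_genes),
        "warnings": warnings,
    }
    return result


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return config
    path = Path(config)
    if not path.exists():
        raise PipelineError(f"config file not found: {path}")
    with open(path) as handle:
        loaded = yaml.safe_load(handle)
    if not isinstance(loaded, dict):
        raise PipelineError("config must be a YAML mapping")
    return loaded


def run_pipeline(config: str | Path | dict, outdir: str | Path | None = None):
    """Run the pipeline from a YAML config; write all outputs + manifest.

    The config holds ``inputs`` (paths: literature, cnv, expression,
    reference_samples, and optionally cohorts, clinical, gene_sets,
    network), ``thresholds``, and optional ``options``
    (key_gene_mode, top_k, max_linkers) and ``outdir``.

    Raises :class:`PipelineError` for configuration problems and
    :class:`StageFailure` when a stage fails; on stage failure the
    output directory keeps partial outputs next to a FAILED marker
    naming the stage.
    """
    cfg = _load_config(config)
    inputs = cfg.get("inputs")
    if not isinstance(inputs, dict):
        raise PipelineError("config missing 'inputs' mapping")
    for key in ("literature", "cnv", "expression"):
        if key not in inputs:
            raise PipelineError(f"config inputs missing required path {key!r}")
        if not Path(inputs[key]).exists():
            raise PipelineError(f"input file not found: {inputs[key]}")
    outdir = Path(outdir or cfg.get("outdir") or "progcnv_run")
    pio.ensure_dir(outdir)

    try:
        thresholds = PipelineThresholds(**(cfg.get("thresholds") or {}))
    except (TypeError, ValueError) as exc:
        raise PipelineError(f"bad thresholds: {exc}") from exc
    options = cfg.get("options") or {}

    literature = pio.read_literature(inputs["literature"])
    cnv = pio.read_cnv(inputs["cnv"], inputs.get("cohorts"))
    expression = pio.read_expression(
        inputs["expression"], inputs.get("reference_samples")
    )
    clinical = (
        pio.read_clinical(inputs["clinical"]) if inputs.get("clinical") else None
    )
    gene_sets = read_gmt(inputs["gene_sets"]) if inputs.get("gene_sets") else None
    network_edges = (
        pio.read_edge_list(inputs["network"]) if inputs.get("network") else None
    )

    try:
        result = run_stages(
            literature,
            cnv,
            expression,
            clinical,
            gene_sets,
            network_edges,
            thresholds,
            key_gene_mode=options.get("key_gene_mode", "count"),
            top_k=int(options.get("top_k", 20)),
            max_linkers=int(options.get("max_linkers", 20)),
        )
    except StageFailure as exc:
        (outdir / "FAILED").write_text(f"{exc.stage}\n")
        raise

    _write_outputs(result, outdir, cfg)
    return result


def _write_outputs(result: PipelineResult, outdir: Path, cfg: dict) -> None:
    result.prognosis_table.to_csv(outdir / "prognosis_genes.tsv", sep="\t")
    result.profiles.to_csv(outdir / "cnv_profiles.tsv", sep="\t",
                           float_format="%.10g")
    conc = result.concordance.copy()
    conc["passes_key_gene"] = conc.index.isin(result.key_genes)
    conc.to_csv(outdir / "concordance.tsv", sep="\t")
    (outdir / "key_genes.txt").write_text(
        "".join(f"{g}\n" for g in sorted(result.key_genes))
    )
    if result.enrichment is not None:
        result.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t",
                                 index=False, float_format="%.6g")
    if result.landscape:
        result.landscape["frequencies"].to_csv(
            outdir / "landscape_frequencies.tsv", sep="\t", index=False,
            float_format="%.10g")
        result.landscape["cohorts"].to_csv(
            outdir / "landscape_cohorts.tsv", sep="\t", index=False,
            float_format="%.10g")
        top_rows = [
            (cohort, rank + 1, gene)
            for cohort, genes in sorted(result.landscape["top_amplified"].items())
            for rank, gene in enumerate(genes)
        ]
        pd.DataFrame(top_rows, columns=["cohort", "rank", "gene"]).to_csv(
            outdir / "top_amplified.tsv", sep="\t", index=False)
        (outdir / "common_genes.txt").write_text(
            "".join(f"{g}\n" for g in sorted(result.landscape["common_genes"]))
        )
    if result.survival_groups is not None:
        result.survival_groups.to_csv(outdir / "survival_groups.tsv",
                                      sep="\t", index=False,
                                      float_format="%.10g")
    if result.survival is not None:
        sg = result.survival_groups
        for label in ("ALTERED", "UNALTERED"):
            grp = sg[sg["group"] == label]
            curve = km_fit(grp["os_months"], grp["os_event"])
            km_table(curve).to_csv(outdir / f"km_{label.lower()}.tsv",
                                   sep="\t", index=False,
                                   float_format="%.10g")
        lr = result.survival
        pd.DataFrame([{
            "statistic": lr.statistic,
            "p_value": lr.p_value,
            "n_altered": lr.n_altered,
            "n_unaltered": lr.n_unaltered,
            "events_altered": lr.events_altered,
            "events_unaltered": lr.events_unaltered,
            "median_altered": lr.median_altered,
            "median_unaltered": lr.median_unaltered,
        }]).to_csv(outdir / "logrank.tsv", sep="\t", index=False,
                   float_format="%.10g")
    if result.network:
        sub = result.network["subnetwork"]
        pd.DataFrame(sorted(sub.edges()), columns=["gene_a", "gene_b"]).to_csv(
            outdir / "subnetwork_edges.tsv", sep="\t", index=False)
        result.network["degrees"].to_csv(outdir / "degree_table.tsv",
                                         sep="\t", index=False)

    manifest = dict(result.manifest)
    manifest["config"] = {k: v for k, v in cfg.items()}
    manifest["outputs"] = sorted(p.name for p in outdir.iterdir()
                                 if p.name != "manifest.json")
    manifest["timestamp"] = datetime.datetime.now(
        datetime.timezone.utc
    ).isoformat()
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
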