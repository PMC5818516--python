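# progcnv

Integrative prioritization of prognosis-related cancer genes from somatic
copy-number and tumour expression data.

## The problem

Thousands of genes have been linked to cancer prognosis in individual
expression studies, but most of those associations never identify which
genes are *driven* — i.e. where a somatic copy-number gain (CNG) plausibly
causes the over-expression that the prognostic study observed.  `progcnv`
implements a selection funnel that narrows a literature-derived candidate
list to genes with concordant copy-number gain and over-expression in the
same tumour samples:

1. **Literature curation** — screen short gene-annotation records
   (GeneRIF-style, one PubMed ID each) for the boolean keyword pattern
   *(prognosis OR prognostic) AND (cancer OR tumour OR tumor OR carcinoma)*,
   matched case-insensitively on whole words.
2. **CNV profiling** — tally per-gene GAIN/LOSS sample counts over the
   pooled cohort and classify each gene by the ratio rule: CNG when
   `n_gain / n_loss > 2` (symmetrically CNL), else BALANCED.  Frequent-CNG
   genes need strictly more than 30 gained samples.
3. **Expression concordance** — Z-score each tumour sample against a
   reference sample population, `Z = (x − μ) / σ`, call over-expression at
   `Z > 2`, and count per gene the matched samples that are simultaneously
   gained and over-expressed.  Genes with more than 20 such samples are the
   **key genes**.
4. **Downstream summaries** — hypergeometric gene-set enrichment with
   Benjamini–Hochberg correction, OncoPrint-style per-cohort alteration
   frequencies and top-amplified rankings, Kaplan–Meier / log-rank survival
   comparison of altered vs unaltered samples, and seed-neighborhood
   extraction (linker genes) from a supplied interaction network.

A fully seeded synthetic cohort generator emits all six input types
(literature TSV, CNV calls, expression matrix with reference samples,
clinical table, GMT gene sets, network edge list) with planted driver
genes, so the whole funnel is testable without any external downloads.

## Worked example

Generate a synthetic cohort (500 genes × 600 tumour samples, 12 planted
driver genes gained in 10% of samples with a 3-SD expression dosage shift)
and run the full pipeline:

```bash
progcnv synth --seed 1 --out demo_bundle
progcnv run --config run.yaml --out demo_run
```

with `run.yaml` pointing at the bundle files:

```yaml
inputs:
  literature: demo_bundle/literature.tsv
  cnv: demo_bundle/cnv_calls.tsv
  expression: demo_bundle/expression.tsv
  reference_samples: demo_bundle/reference_samples.tsv
  clinical: demo_bundle/clinical.tsv
  gene_sets: demo_bundle/gene_sets.gmt
  network: demo_bundle/network_edges.tsv
```

The run prints the selection funnel:

```
curated=300 -> cnv_overlapping=300 -> cng=27 -> cnl=17 -> balanced=256 -> frequent_cng=12 -> key_genes=12
```

Of 500 genes, 300 carried prognosis keywords in their literature records;
27 were classed CNG and 12 of those passed both the frequent-CNG and
concordance cut-offs — exactly the 12 planted drivers (`demo_run/key_genes.txt`).
`demo_run/logrank.tsv` shows the survival contrast between samples with and
without an alteration in a key gene:

```
statistic       p_value          n_altered  n_unaltered  median_altered  median_unaltered
79.38226419     5.118352596e-19  468        132          14.2875503      39.87919764
```

— altered samples die at roughly the planted threefold hazard (median 14.3
vs 39.9 months).  `demo_run/enrichment.tsv` ranks the planted gene set first
(overlap 8/12, adjusted p = 2.7e-07); `demo_run/manifest.json` records the
funnel counts, thresholds and machine-readable warnings of the run.

Every step is also available as a library call (`progcnv.run_stages`,
`profile_genes`, `z_scores`, `count_concordance`, `enrich`, `log_rank`, …)
and as focused CLI subcommands (`curate`, `profile`, `concordance`,
`survive`, `stages`).

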