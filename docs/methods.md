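# Methods

## The selection funnel

`progcnv` models gene prioritization as a strict funnel over a candidate
list. Let G be the genes with at least one literature record matching the
prognosis/cancer keyword pattern. For each g ∈ G present in the CNV call
matrix, the pooled-cohort gain and loss sample counts (n_gain, n_loss) are
tallied and the gene classified

* CNG if n_gain / n_loss > r (with n_loss = 0, n_gain > 0 treated as an
  infinite ratio, hence CNG),
* CNL symmetrically,
* BALANCED otherwise (including 0/0).

For any ratio cut-off r ≥ 1 the classes are mutually exclusive and
swapping all GAIN↔LOSS calls swaps CNG↔CNL exactly; both properties are
enforced by tests. Frequent-CNG genes additionally satisfy
n_gain > m (strict).

Over-expression of gene g in sample s is called from the Z-score

    Z(g, s) = (x(g, s) − μ(g)) / σ(g)

where μ and σ are the mean and standard deviation (ddof = 1) of g's
expression over the designated reference samples. Genes with σ ≤ 0 or an
undefined σ are excluded with a warning, since their Z-score is undefined.
Z-scores are affine-invariant: rescaling a gene's expression by a > 0 and
shifting by b changes nothing downstream.

A frequent-CNG gene becomes a **key gene** when the number of matched
samples that are simultaneously gained and over-expressed exceeds c
(strict). Only samples present in both the CNV and expression matrices
are counted, and the overlap size is logged.

### Defaults and why

| parameter | default | meaning |
|---|---|---|
| ratio_cutoff | 2 | gained samples must outnumber lost at least twofold |
| min_cng_samples | 30 | minimum evidence that a gain is recurrent |
| z_cutoff | 2 | over-expression = 2 reference SDs above the reference mean |
| min_concordant_samples | 20 | minimum matched gain+over-expression samples |

All four comparisons are strict (`>`), mirroring the "more than" phrasing
of the thresholds; a gene sitting exactly on a cut-off is dropped. The
concordance cut-off is applied to the *count* of gain+over-expression
samples; an alternative mode applies it to the ratio
n_gain_over / n_loss_under instead (flag `key_gene_mode: ratio`), kept
because the two readings of the threshold are both defensible — the count
reading is the default since the count is what the preceding step
computes.

Funnel monotonicity holds by construction: each stage's gene set is a
subset of the previous stage's, and raising any threshold can only shrink
every downstream set. This is asserted over randomized configurations in
the test suite.

## Downstream summaries

**Enrichment.** Over-representation of a gene set with K members in a
universe of N genes against a query of n genes overlapping it in k is the
upper-tail hypergeometric probability P(X ≥ k), identical to a one-sided
Fisher exact test on the 2×2 table (asserted to 1e−9). Adjustment is
Benjamini–Hochberg across all tested sets; the universe defaults to the
genes of the CNV matrix, since the annotation universe of external
web tools is not knowable in general and the choice materially affects
p-values.

**Cohort landscape.** A sample is altered w.r.t. a gene list when it has
GAIN or LOSS in ≥ 1 listed gene. Per-gene gain ("amplification") and loss
("deletion") frequencies are exact tallies divided by cohort size.
Top-k amplified rankings break ties lexicographically by symbol so output
is deterministic; the cross-cohort intersection of top-k sets is monotone
non-decreasing in k.

**Survival.** Kaplan–Meier product-limit estimation over distinct death
times; censored times reduce risk sets only, and deaths at a time are
processed before censorings at the same time (standard convention). The
median is the smallest time with S ≤ 0.5 and is reported as undefined
when S never crosses it. The two-group log-rank statistic accumulates
(O − E)²/V over death times with the hypergeometric variance of the
group-1 death count; p-values come from χ²(1). The implementation is
written here and cross-checked against lifelines to 1e−8 on randomized
censored fixtures; its type-I error at hazard ratio 1 is verified to sit
at the nominal 5% level within Monte-Carlo error (1000 replicates of
n = 100).

**Network.** A supplied undirected edge list is cleaned (self-loops
removed, duplicates collapsed); edge weights are carried through to output
but never used for ranking. Around a seed list the module extracts linker
genes — non-seed nodes ranked by the number of distinct seeds they touch,
ties lexicographic — and induces the subnetwork on seeds plus the top 20
linkers (configurable), then tabulates within-subnetwork degrees.

## The synthetic cohort generator

The generator emulates the statistical structure the funnel assumes,
not the genomics that produces it:

* **CNV calls.** Background cells gain/lose independently at per-cell
  rates (default 0.02/0.02). Each planted driver gene is gained in
  exactly `round(fraction × n_samples)` samples (default 10% of 600) and
  receives no background gains, so realized counts are exact.
* **Expression.** Each gene draws a mean ~ U(4, 12) and SD ~ U(0.5, 2)
  once; reference and tumour samples are i.i.d. normal around them. Gained
  samples of planted genes are shifted upward by `dosage_shift` × the
  *empirical* reference SD (default 3 SDs), directly emulating a dosage
  effect on the Z-score scale. With the shift at 0 the expected
  gain+over-expression count per planted gene is analytic,
  n_gain × Φ̄(2) ≈ 0.0228 × n_gain, which the calibration test checks
  within 3 binomial SDs at 5000 samples.
* **Literature.** Genes in the prognosis-positive subset (all planted
  genes plus a random 60% of the universe by default) receive 1–3 records
  whose descriptions contain both keyword groups; all other genes receive
  one non-matching record, some containing derivative forms
  ("prognostically") that exercise the whole-word rule.
* **Clinical.** Survival times are exponential with baseline median 40
  months; samples carrying ≥ 1 planted-gene gain have their hazard
  multiplied by `hazard_ratio_altered` (default 3). Censoring is
  administrative at 120 months — enough to exercise Kaplan–Meier with
  censoring without modeling dropout.
* **Gene sets.** One designated set holds 8 of the 12 planted genes plus
  random fillers; the remaining sets are random decoys of the same size,
  giving the enrichment stage one known positive.
* **Network.** Planted genes form a loosely connected core (pairwise edge
  probability 0.35); 25 background linker genes attach to 1–5 planted
  genes each, plus random background noise edges.

A config and seed fully determine every output; byte-identical re-emission
is tested. The accompanying truth object (planted genes, realized gain
sample sets, concordant counts at Z > 2, altered samples) is computed by
direct counting on the emitted matrices, never by a second code path
through the pipeline.

**What passing tests do not show.** The generator omits segment-level CNV
structure, probe/assay noise, batch effects, cohort-specific expression
baselines, non-exponential survival and informative censoring. Exact
driver recovery on this cohort demonstrates that the funnel implements
its stated rules correctly and separates a 3-SD dosage signal from a 2%
background — not that those cut-offs are optimal on any real tumour
cohort.

## Numerical and design choices

* Reference statistics use the sample SD (ddof = 1); the reference set is
  the designated (e.g. diploid/normal) samples, falling back to all
  samples with a warning when none are designated. Per-cohort reference
  scoring is available via `reference_by_cohort`.
* Ratios with a zero denominator and positive numerator are treated as
  +∞ (they pass any cut-off); 0/0 is BALANCED / not selected.
* Missing expression values yield missing Z-scores and count as
  not-over-expressed.
* All rankings (top-amplified, linkers, degree tables) break ties
  lexicographically by gene symbol.
* The pipeline runner skips downstream stages whose inputs are absent or
  whose key-gene list is empty, recording a machine-readable warning in
  the manifest instead of failing; a genuine stage error aborts the run
  with the stage named and a FAILED marker in the output directory.
* Problem sizes in the test suite (60×150 for unit fixtures, 500×600 for
  the end-to-end recovery check, 5000 samples for the null calibration,
  1000 replicates for the type-I error simulation) were chosen as the
  smallest sizes at which the respective statistical checks have
  negligible Monte-Carlo ambiguity.

## Limitations

Discrete GAIN/LOSS calls are taken as given — deriving them from
segmented log-ratios (GISTIC-style) is out of scope, as are probe-to-gene
mapping, eQTL modeling, Cox regression, GO-graph-aware enrichment and any
network-inference algorithm (the network module consumes a supplied edge
list). Headline gene counts from any particular literature/CNV snapshot
depend on database versions and manual curation and are not reproducible
from code alone; the package's claims are therefore the property-based
ones its tests compute.
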