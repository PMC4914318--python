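# Methods

`mirmeta` implements the statistical core of a cross-study miRNA
deregulation analysis of the kind used to characterize papillary thyroid
carcinoma (PTC): a discovery signature from a small tumor/normal cohort, a
sequencing-based validation cohort processed from isoform-level
quantification files, a vote-counting literature meta-analysis on
harmonized identifiers, a concordance intersection with in-vitro oncogene
models, and sample clustering with cluster–label enrichment. This note
describes each model/procedure, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was open.

## Identifier harmonization

miRNA names are unstable across registry releases: arm suffixes
(`-5p/-3p`) replaced the star convention (`miR-X*`), and letter suffixes
appear when paralogs are discovered (`miR-451` → `miR-451a`). Signatures
printed in different eras can only be compared on the stable mature
accession (MIMAT identifier). `mirmeta.registry` builds a case-insensitive,
species-prefix-agnostic alias index over every current and historical name
of a reference release and resolves query names strictly through it.

Key decisions:

* **No arm guessing.** An arm-less legacy name resolves only if the
  registry records it as an alias of a specific mature. A name recorded as
  an alias of two accessions is returned *ambiguous* with all candidates —
  never silently picked. Unknown and ambiguous entries are excluded from
  harmonized signatures but always listed in a resolution report.
* **Alias list order.** In the aliases table the last listed name is the
  current one (the `aliases.txt` convention); everything earlier is a
  previous name.
* **Intra-study conflicts.** If one study reports the same accession in
  both directions (possible after merging legacy names), the entry is
  excluded and flagged; duplicates with a consistent direction merge,
  keeping the largest-magnitude fold change.
* **Grouping.** Related-miRNA structure is reported three ways: shared
  family label (sequence similarity), genomic cluster (precursors on the
  same chromosome and strand with inter-precursor gaps ≤ a window,
  transitive closure via a running-max-end sweep), and shared hairpin
  precursor (`-5p/-3p` pairs). The cluster window defaults to 10 kb, a
  common polycistron convention; only groups of ≥ 2 members are reported.

The precursor table is GFF3-like in the miRBase dialect: hairpin lines
(`miRNA_primary_transcript`, `ID=MI…`, optional `family=`) plus mature
lines (`miRNA`, `ID=MIMAT…`, `Derives_from=MI…`) that carry the
mature-to-hairpin links; coordinates are 1-based inclusive.

## Discovery-stage differential expression

The discovery comparison is tumor vs normal on a log2 expression matrix.

* **Detection filter** — a miRNA must be flagged detected in at least
  `min_samples` samples (default use: 15 of 24), mirroring platform
  detection calls.
* **Fold change** — `log2FC = mean(tumor) − mean(normal)` on the log2
  scale, i.e. a ratio of geometric means; the signed linear FC is
  `sign(log2FC)·2^|log2FC|`, `+1` at zero.
* **Test** — two-sided Wilcoxon rank-sum. For tie-free groups of at most
  `exact_max_n` (default 8) observations each, the exact permutation null
  is used; otherwise a normal approximation with tie-corrected variance
  and 0.5 continuity correction. All-identical pooled data give p = 1.
  Ties always use the approximation because the exact null under midranks
  is not defined by the rank pattern alone. A Welch t-test is available
  via `method="welch"` as a parametric alternative; the package does not
  implement empirical-Bayes moderated statistics.
* **Multiplicity** — Benjamini–Hochberg step-up over all tested miRNAs.
* **Call** — significant iff `|linear FC| ≥ fc_cut` (inclusive) and
  `FDR < fdr_cut` (strict), defaults 1.5 and 0.05. Output is sorted by
  |log2FC| descending with accession as the deterministic tie-break.
  The FC threshold is applied on the linear scale, the standard reading
  of "FC ≥ 1.5".

## Sequencing validation (TCGA-style)

Level-3-like isoform files (sample, mature accession, read count, several
records per pair) are summed per mature accession after translating
source-release accessions through a release map; records that do not map
are excluded and reported rather than carried under stale identifiers.
RPM normalization uses the aggregated mature counts of each file as the
denominator (the per-million universe is the file's own miRNA-mapped
reads; original library totals are not recoverable from Level-3-like
input). Zeros are replaced by the minimum non-null value before log2; the
minimum is **global** over the matrix by default, with a per-miRNA option
(`per_mirna=True`) since either reading of "the minimum non-null value" is
defensible — the choice is recorded in the function signature rather than
hidden.

Validation statistics: two-group Wilcoxon with BH adjustment computed
over the validated subset only (m = subset size, the correct correction
for an a-priori signature); Kruskal–Wallis (tie-corrected H, chi-square
with k−1 df) for multi-stratum comparisons; and pairwise Wilcoxon tests
of every stratum against a reference plus all non-reference pairs,
reported **unadjusted** — the global Kruskal–Wallis p gates their
interpretation, matching the per-pair-star reporting style of clinical
stratification figures.

## Vote-counting meta-analysis

Per-study signatures are harmonized, a study published as several
datasets is collapsed to one column (union over datasets; datasets that
disagree in direction make the cell a *conflict*), and the study–miRNA
matrix holds +1/−1/0/conflict cells. The frequency score of a miRNA per
direction is simply the number of studies reporting it in that direction;
conflicted studies count toward neither. The reporting filter keeps
miRNAs reported by ≥ k studies (default 2). Union collapsing maximizes
sensitivity while surfacing conflicts instead of hiding them; fold
changes are never pooled — this is deliberately vote counting, not
effect-size meta-analysis, because heterogeneous platforms and cutoffs
across the literature do not support a common effect scale.

## Concordant intersection

Datasets entering the intersection declare an explicit orientation:
whether their "up" corresponds to the tumor-like (oncogene-active) state.
This matters because an inhibition model's comparison (e.g. solvent vs
inhibitor) points opposite to a naive treated-vs-control reading. A miRNA
is concordant iff it passes every dataset's own thresholds (each dataset
keeps its published FC cut, with or without an FDR cut) and has the same
tumor-oriented direction in all of them. The operation is order-invariant
and idempotent on self-intersection; both properties are tested.

## Clustering and enrichment

Samples are clustered on their signature profiles with Pearson
correlation distance (d = 1 − r ∈ [0, 2]) and average (UPGMA) linkage.
The implementation delegates to scipy's linkage; tests hold it to a naive
O(n³) agglomeration oracle with lexicographic tie-breaking, which agrees
identically on tie-free data. The number of clusters k is a parameter (no
automatic selection). Cluster ids are numbered by first sample occurrence
so output is invariant to column order up to relabeling. Each
(cluster, label) pair is tested by a one-sided Fisher exact test
(hypergeometric upper tail, enrichment only) of cluster membership against
all other samples, unadjusted by default (per-cluster reporting); a BH
option exists. Dendrograms export as ultrametric newick.

## Synthetic data and what it does (not) show

The generator (`mirmeta.simulate`) emits every format the pipeline reads,
with planted truth, and a self-audit verifies truth/file consistency
after generation. Defaults encode the study conditions: 500 candidate
miRNAs; discovery 19 tumor vs 5 normal with 18 planted DE miRNAs at
|log2FC| = 2 on σ = 0.5 log2-normal noise; validation 100 tumor vs 12
normal (a speed-scaled stand-in for a 499/59 cohort) over 200 miRNAs with
10 planted −2 log2 shifts and 1 M multinomial reads per sample split over
1–5 isoform records; a 15-study corpus (one study emitted as three
datasets) with a 10-miRNA consensus and 20% per-study dropout. Registry
renames cover arm-less, star and letter-less legacy forms at a 0.5 rename
fraction. The planted most-frequent down-regulated miRNA is reported by
every study and carries the smallest planted accession, encoding "most
frequent" as planted structure rather than sampling accident. Planted DE
rows draw baselines above the detection floor, as truly expressed miRNAs
do.

Not emulated: batch effects, paired-sample correlation, platform-specific
intensity distributions, realistic miRNA biogenesis or sequence content.
Passing the planted-recovery tests therefore demonstrates the
correctness and calibration of the statistical machinery under the
declared noise model, not performance on real cohort data.

Determinism: each generator draws from `numpy.random.default_rng` seeded
from `spec.seed` plus a fixed per-stage offset; identical spec + seed
yield byte-identical files.

## Numerical choices and limitations

* Exact Wilcoxon enumeration is capped at groups of 8 (C(16,8) = 12 870
  splits) — above that the normal approximation is indistinguishable at
  the reported precision and enumeration cost grows combinatorially.
* Degenerate inputs are defined, not errors: all-tied test data give
  p = 1; an all-zero Fisher table gives p = 1; an all-zero RPM matrix,
  zero-total samples, empty groups and zero-variance samples raise named
  errors.
* BH adjusted values are returned in input order and capped at 1.
* `cut_clusters` requires the requested k to be attainable; exact ties in
  merge heights that make a k-cut ambiguous raise rather than guess.
* The harmonizer accepts pre-filtered study tables; per-study inclusion
  cutoffs applied by the original publications are treated as upstream of
  this package.
* Sensitivity/FDR guarantees in the acceptance tests are averages over 20
  generator seeds at the default conditions; single seeds fluctuate.
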