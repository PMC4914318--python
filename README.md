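# mirmeta

Cross-study analysis of miRNA deregulation in tumors — built around the
workflow used to characterize papillary thyroid carcinoma (PTC), where a
handful of upregulated miRNAs (miR-146b-5p, miR-221-3p, miR-222-3p) are
broadly agreed upon while downregulated miRNAs (miR-451a, miR-199a-3p,
miR-214-3p, …) are reported inconsistently, largely because studies print
names from different miRBase eras.

The package is for computational biologists who need to:

* **harmonize** miRNA names from any nomenclature era to univocal mature
  accessions (MIMAT identifiers) through a registry alias index — legacy
  arm-less names, star-strand names (`miR-X*`) and letter-less names
  (`miR-451` → `miR-451a`) resolve only through recorded aliases, never by
  guessing;
* **derive a differential-expression signature** from a log2 expression
  matrix: detection filter, geometric-mean fold change, two-sided Wilcoxon
  rank-sum test (exact by enumeration for small tie-free groups),
  Benjamini–Hochberg FDR, and the call `|FC| ≥ 1.5 AND FDR < 0.05`;
* **validate in a sequencing cohort** from Level-3-style isoform files:
  per-accession read summation, release-map reannotation, reads-per-million
  normalization, zero-replacement log2, Wilcoxon + BH over the signature,
  Kruskal–Wallis and pairwise Wilcoxon tests across clinical strata;
* **meta-analyze the literature** by vote counting: a study–miRNA matrix of
  +1/−1/0/conflict cells over harmonized accessions (multi-dataset studies
  collapsed to one column), per-direction frequency scores, and a
  ≥ 2-study reporting filter;
* **intersect signatures concordantly** across datasets with explicit
  tumor-axis orientations (an oncogene-inhibition model's "up" points away
  from the tumor-like state);
* **cluster samples** on a signature with Pearson-distance UPGMA and test
  each cluster for clinical-label enrichment with a one-sided Fisher exact
  test.

A synthetic-data generator (`mirmeta.simulate`) produces every input
format with planted ground truth, so the whole pipeline is testable
without downloading anything.

## Worked example

```python
import mirmeta as mm
from mirmeta.simulate import SimulationSpec, simulate_all
from mirmeta.meta import (StudySignature, build_matrix,
                          filter_min_studies, frequency_score)
from mirmeta.registry import harmonize_signature

sim = simulate_all(SimulationSpec(seed=7))   # 19 vs 5 discovery cohort,
                                             # 15-study corpus, registry…

# discovery signature: Wilcoxon + BH, |FC| >= 1.5, FDR < 0.05
de = mm.differential_expression(sim.expression)
sig = mm.call_signature(de, fc_cut=1.5, fdr_cut=0.05, registry=sim.registry)
print(sig)
print(sig.table.head(3).round(4))

# literature meta-analysis on harmonized accessions
studies = [
    StudySignature(sid, {ds: harmonize_signature(e, sim.registry)[0]
                         for ds, e in d.items()})
    for sid, d in sim.study_tables.items()
]
matrix = filter_min_studies(build_matrix(studies), 2)
print(frequency_score(matrix)["down"].head(3))
```

prints

```text
<Signature: 17 miRNAs (13 up, 4 down)>
                         name direction  linear_fc  log2fc       p     fdr
accession
MIMAT9000102     hsa-miR-9078        up     5.4670  2.4507  0.0008  0.0246
MIMAT9000427  hsa-miR-9335-5p        up     5.0922  2.3483  0.0008  0.0246
MIMAT9000463  hsa-miR-9360-3p        up     5.0588  2.3388  0.0008  0.0246
              score
MIMAT9000013     15
MIMAT9000159     13
MIMAT9000471     13
```

The signature recovered 17 of the 18 planted deregulated miRNAs with no
false discovery (the strongest hit has a 5.5-fold geometric-mean change,
adjusted p = 0.025), and the top-scoring downregulated miRNA in the
meta-analysis matrix — reported down by all 15 synthetic studies — is
exactly the planted most-frequent one, recovered across nomenclature eras
by alias resolution.

The generator is also available from the shell:

```bash
mirmeta simulate out/ --seed 7            # writes registry tables,
                                          # expression/isoform/study TSVs
```

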