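# hccsubtypes

Tumor cells in hepatocellular carcinoma (HCC) are not one population: across
patients they repeatedly organize into three transcriptional subtypes — a
**metabolism** subtype (marked by *ARG1*, *ALDOB*), a **proliferation**
subtype (*TOP2A*, *STMN1*, *MKI67*) and an **EMT/stemness** subtype
(*S100A6*, *S100A11*, plus cancer-stem-cell markers such as *EPCAM* and
*CD24*). Samples tend to keep a stable proliferative fraction while the rest
of their tumor cells are dominated by either the metabolism or the EMT
program, and samples from the same patient share that dominance.

`hccsubtypes` implements this analysis as a tested, reusable Python package
for computational biologists working with single-cell (and pseudo-spatial or
bulk) liver-cancer transcriptomes:

- **Synthetic cohorts** (`hccsubtypes.simulate`): a negative-binomial
  cell-by-gene count simulator with known per-cell subtypes, patient-shared
  dominance, library-size variation, mitochondrial fractions, low-quality
  cells, bulk cell-line panels and 1–10-cell pseudo-spots — ground truth for
  every downstream recovery test.
- **Preprocessing** (`hccsubtypes.preprocess`): QC (drop cells with <500
  detected features or >15% mitochondrial counts; drop samples left with
  <20 tumor cells), CP10K + log1p normalization, top-2000 highly variable
  genes, exact PCA (20 PCs), and Leiden clustering on a shared-nearest-
  neighbor graph (`SNNLeiden`, a scikit-learn style clusterer).
- **Subtype discovery** (`hccsubtypes.subtypes`): per-subcluster mean
  profiles, the top-50 genes by between-cluster SD, Spearman similarity,
  average-linkage merging at k = 3 on distance 1 − ρ, and marker-based
  naming of the merged groups.
- **NMF consensus** (`hccsubtypes.nmf`): downsample 50 cells/sample,
  factorize with multiplicative-update NMF (k = 3, Frobenius loss, monotone
  loss trajectory), assign cells to argmax factors, and measure the
  best-matching **concordance rate** against the subtype labels over 10
  resampling repeats.
- **Signature scoring** (`hccsubtypes.scoring`): a single-sample rank
  enrichment score (weighted-ECDF running sum, α = 0.25), mean z-score
  signatures (including the 8-marker CSC score), argmax subtype assignment,
  and Metab-HCC / EMT-HCC / Mixed-HCC classification of bulk cohorts.
- **Regulon activity** (`hccsubtypes.regulons`): 20-cell pseudo-cell
  averaging, recovery-curve AUC of regulon genes in the top 5% of each
  ranking, and the regulon specificity score RSS = 1 − √JSD(P, Q).
- **Composition heterogeneity** (`hccsubtypes.composition`): per-sample
  subtype fractions, Euclidean distances on the composition simplex split
  within vs between patients with a Wilcoxon rank-sum test (exact
  enumeration for ≤20 distances), cohort grouping, and mutation-rate tables.

The computational stages are exposed as scikit-learn style estimators
(`SNNLeiden`, `MultiplicativeNMF`, `SSGSEAScorer`, `MeanZScorer`,
`RegulonAUCScorer`, `PseudocellAggregator`, `TranscriptomeSimilarityMerger`)
so they compose with sklearn pipelines; the module-level functions are thin
wrappers over them.

## Worked example

The one-shot demo simulates a 10-patient × 2-sample × 300-cell cohort and
runs every stage:

```bash
hccsubtypes run-all --seed 1 --out demo/
```

prints

```json
{
 "cells": 5553,
 "concordance_median": 1.0,
 "within_median": 0.05203726071518807,
 "between_median": 0.21309486878700565,
 "emt_hcc_proportion": 0.7
}
```

Reading these numbers: of the 6000 simulated cells, 5553 survive QC. The
NMF consensus labels agree perfectly with the similarity-based subtypes
(median concordance 1.0 across 10 resampling repeats — the synthetic
programs are far better separated than real tumors, where concordance near
0.87–0.88 is typical). The median Euclidean distance between the subtype
compositions of two samples from the *same* patient (0.052) is four times
smaller than between samples of *different* patients (0.213), reproducing
patient-shared subtype dominance; 70% of samples fall in the EMT-dominated
cohort group for this seed. `demo/` holds the per-stage artifacts
(`cell_subtypes.tsv`, `markers.gmt`, `concordance_report.json`,
`regulon_rss.tsv`, `composition.tsv`, `distance_summary.json`, …) plus a
`manifest.json`; reruns with the same seed reproduce them bit-identically.

Each stage is also available on its own (`hccsubtypes simulate | preprocess |
subtype | nmf-validate | score | regulons | composition`) or as library
calls — see the module docstrings.

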