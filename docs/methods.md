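# Methods

This note documents the models, statistics, parameter choices and numerical
conventions behind `hccsubtypes`, and what the synthetic-data tests do and do
not demonstrate.

## Synthetic cohort model

The simulator emulates the statistical structure the analysis assumes rather
than any particular dataset. Counts follow a gamma–Poisson (negative
binomial) model: gene `g` has a baseline log-activity `a_g ~ N(0, 1)`, and a
cell of subtype `s` elevates its program's marker genes by `program_log_fc`
natural-log units. Per-cell expected counts are the softmax of these
activities times a log-normal library size (mean 5 000 counts,
σ = 0.3); dispersion is a single NB size parameter `nb_dispersion` (default
2, the overdispersed regime typical of UMI data; large values approach
Poisson). Ten designated mitochondrial genes (`MT-SIM…`) receive a Beta-
distributed fraction of each cell's library (mean 5%), so QC covariates are
meaningful.

Cohort structure: each patient is assigned a dominant terminal subtype
(metab or emt, equiprobable). Each sample draws its proliferative fraction
from Beta(μκ, (1−μ)κ) with μ = `prol_fraction_mean` = 0.2 and κ = 60 — a
stable-but-minor Prol compartment; the remaining probability mass is split
`dominance_strength` : 1 − `dominance_strength` (default 0.85 : 0.15)
between the patient's dominant subtype and the other one. All samples of a
patient share the dominant side, which is precisely the property the
composition-heterogeneity analysis tests. A `lowq_cell_fraction` (5%) of
cells is generated on the failing side of the QC thresholds, half by
truncating the library to 80–400 counts (few detected genes), half by
inflating the mitochondrial fraction to 20–40%.

Defaults were set once for desk-scale realism: no per-sample tumor-cell
counts are published for the motivating cohorts, so `cells_per_sample` = 300
and `n_genes` = 1000 (three 30-gene programs, 10 mitochondrial genes, filler
genes) were chosen for minute-scale runtimes while keeping all marker
symbols the scoring operations expect (*ARG1*, *ALDOB*; *TOP2A*, *STMN1*,
*MKI67*; *S100A6*, *S100A11* and the eight CSC markers).

All randomness flows through named substreams of one global seed
(`[seed, crc32(stage_name)]`), so adding a generator stage never perturbs
earlier draws and identical configs give bit-identical cohorts.

What the simulator does **not** model: batch effects beyond library size
(batch integration is out of scope), doublets, ambient RNA, non-tumor
compartments (all cells are `tumor`-class by default), spatial coordinates,
or realistic gene–gene correlation beyond the three programs. Passing
recovery tests therefore shows the pipeline's statistics are implemented
correctly and can recover planted structure at realistic noise levels — not
that real tumors separate this cleanly. On real cohorts the NMF concordance
sits near 0.87–0.88; on the synthetic reference cohort it is essentially 1.

## Preprocessing

QC removes cells with fewer than 500 detected features **or** a
mitochondrial fraction above 15% (both strict on the removal side: a cell
with exactly 500 features and exactly 15% survives), then excludes whole
samples left with fewer than 20 tumor cells. Filtering is idempotent.

Normalization is counts-per-10k followed by `ln(1 + x)`. Highly variable
genes are ranked by plain variance of log-normalized expression (no
mean-variance trend correction; the criterion is documented so alternates
can be swapped in). PCA uses exact SVD on the HVG submatrix after per-gene
centering and unit scaling with z-scores clipped at ±10 to bound outlier
leverage. Subclustering builds a shared-nearest-neighbor graph (k = 20
Euclidean neighbors including the cell itself, Jaccard edge weights, edges
below 1/15 pruned — conventional SNN defaults) and optimizes modularity with
a seeded Leiden run at resolution 1.0. The number of subclusters is
data-dependent and not a target; the merge step below absorbs it.

## Subtype discovery

Subcluster mean profiles (unweighted arithmetic means; cluster sizes are not
used as weights) are reduced to the 50 genes with the highest
between-cluster population SD (ddof = 0; ties broken by input gene order).
Spearman correlation (average ranks on ties; constant vectors recorded as 0
with a warning) gives the similarity matrix; average-linkage agglomeration
on 1 − ρ cut at k = 3 merges subclusters into three groups. Average linkage
was chosen as the standard choice for correlation-based profile clustering
and is stable at small k. Groups are named deterministically by marker
evidence — highest mean expression of {ARG1, ALDOB} → metab,
{TOP2A, STMN1, MKI67} → prol, {S100A6, S100A11} → emt — replacing manual
annotation; a collision (one group winning two names) raises rather than
guessing. Subtype markers are ranked by avg logFC (subtype mean minus
rest-of-cells mean in log space) with threshold 1.0 and the top 50 kept.

## NMF consensus validation

Each repeat draws 50 cells per sample without replacement (seeded with
`seed + repeat`), restricts the log-normalized matrix to the union of the
per-subtype top-50 markers and the HVGs (the exact published feature space
is unstated; this union is configurable), and factorizes with k = 3
multiplicative updates minimizing squared Frobenius error. Frobenius was
chosen over KL divergence for numerical robustness on log-space data and is
recorded as a deliberate deviation from the common "brunet" default of R NMF
packages. The loss is recorded every sweep and asserted non-increasing with
slack `1e-10·previous + 1e-12·‖X‖²` (the absolute term covers round-off once
the loss reaches the float64 noise floor). An all-zero input returns zero
factors with loss 0. Cells take their argmax factor (ties to the lowest
index, logged; all-zero rows become `unassigned` and leave the denominator).

**Concordance** between the factor labels and the subtype labels is the
best-matching cell-level agreement: an injective matching of the smaller
class set into the larger one is found by exhaustive permutation search
(both sides capped at 6 classes), and the rate is matched agreements over
cells. The term is not formally defined in the motivating work; maximal
one-to-one matching is the defensible reading and is cross-checked against
Hungarian assignment in the tests. Concordance is computed on the
downsampled cells of each repeat (not propagated to all cells); the report
carries per-repeat rates with median, min and max.

## Signature scoring

The single-sample enrichment score ranks a cell's genes by expression
(descending, ties by input gene order) and sums, over all positions, the
difference between the weighted in-set ECDF (weight = rank-from-bottom^α,
α = 0.25, the conventional exponent) and the uniform out-set ECDF. With
normalization on, the score is divided by the spread between the maximal and
minimal score achievable for that set size and gene count (computed
analytically from the two extreme arrangements — no permutation nulls).
This one rank-based engine scores subtype signatures, hallmark-style GMT
sets and spot mixtures alike; being rank-based it is invariant to monotone
transforms of expression. The CSC stemness score is the mean z-score of
EPCAM, CD24, KRT19, SOX9, PROM1, CD44, THY1 and CD47, with SD-zero genes
contributing 0. Entity subtype assignment is argmax score; exact ties are
`unassigned`. Bulk cohorts are clustered (average linkage, correlation
distance) on the combined metab + EMT top-50 marker space, cut at three
groups, and named by mean signature z-scores with the leftover group called
Mixed-HCC.

## Regulon activity

Regulons are supplied as gene sets (GMT); no network inference is performed.
Same-subtype cells are averaged in random disjoint chunks of exactly 20
(seeded permutation; incomplete trailing chunks dropped), so each cell
contributes to exactly one pseudo-cell — chosen over resampling with
replacement to keep contributions balanced. Activity is the area under the
step recovery curve of regulon genes along the top 5% of each pseudo-cell's
expression ranking, normalized by the ideal curve's area so AUC ∈ [0, 1];
5% is the established recovery-curve window. Specificity per subtype is
RSS = 1 − √JSD(P, Q) with base-2 logarithms (JSD ∈ [0, 1]), where P is the
regulon's activity column normalized to a distribution over pseudo-cells
and Q is uniform over the subtype's pseudo-cells; all-zero activity columns
score 0 with a warning.

## Composition heterogeneity

Sample composition is the fraction of each subtype among its tumor cells —
a point on the 2-simplex; distances are plain Euclidean on these 3-vectors
(no log-ratio transform, keeping magnitudes comparable with published
values). Cohort grouping is average-linkage Euclidean clustering cut at 2,
with the higher-mean-EMT group named EMT-HCC. The within- vs between-patient
comparison uses a two-sided Wilcoxon rank-sum test: exact by enumerating all
C(n, n₁) group assignments of the average ranks when the pooled count is
≤ 20 (ties handled naturally), otherwise the normal approximation with
continuity and tie correction. Mutation-rate tables report
100 × mutant/total rounded half-up to one decimal (matching conventional
reporting precision), with raw counts retained.

## Problem sizes and determinism

The test suite exercises operations on ≤100-gene fixtures against
independent brute-force oracles, and runs the full pipeline on a
4 × 2 × 150-cell cohort (seconds) plus a reference recovery experiment of
10 patients × 2 samples × 300 cells at `program_log_fc` = 2
(about half a minute), on which it requires per-cell subtype ARI ≥ 0.9,
median NMF concordance ≥ 0.85, ≥ 95% agreement between cohort grouping and
simulated dominance, and within-patient < between-patient median distance
with rank-sum p < 0.05. `scripts/acceptance.py` recomputes these quantities
at the same sizes. Every stage is deterministic given the global seed;
rerunning a pipeline config reproduces all artifacts bit-identically.

## Known limitations

- No batch correction or integration; multi-dataset cohorts need external
  harmonization first.
- The Leiden resolution is a free parameter; the subcluster count is not
  meaningful on its own and only the merged 3-group structure is tested.
- ssGSEA-style ranking scores and GSVA's kernel-ECDF variant differ in
  scale; only the rank-based engine is provided.
- The exact rank-sum enumeration is O(C(n, n₁)) and deliberately capped at
  pooled n = 20.
- Spot generation sums counts without spatial coordinates or segmentation
  noise; it tests mixture scoring, not deconvolution.
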