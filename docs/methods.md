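# Methods

This note documents the statistical procedures implemented in `cafscape`,
the conventions chosen where a method's common description leaves details
open, and what the synthetic test bed does and does not establish.

## Spatial k-distance and proximity analysis

For a query cell c in slice s and a reference cell type R, the spatial
k-distance is the arithmetic mean of the Euclidean distances from c to its
k nearest R-cells in s, excluding c itself (default k = 10).  Self-exclusion
is required because a reference cell's distance to itself is zero and would
make the statistic degenerate for the reference population.  Consequences:

* a slice needs ≥ k reference cells to be analyzed at all (otherwise it is
  skipped with a warning and flagged);
* a reference cell needs k *other* reference cells, so in a slice with
  exactly k reference cells the reference cells themselves get a missing
  value while other cells are still scored.

Distances are computed exactly from dense per-slice distance matrices; no
approximate nearest-neighbor search is used anywhere.  All outputs are
invariant under translation and rotation of slice coordinates, and rankings
and partitions are invariant under uniform rescaling.  Coordinates are used
in each slice's native units; no cross-slice harmonization is attempted,
which is why all downstream aggregation is rank- or proportion-based.

**Proximity ranking.**  Per slice, non-reference cell types are ordered by
the mean k-distance of their member cells (ascending; ties broken
alphabetically; types absent from a slice are simply missing from its
list).  The per-slice lists feed robust rank aggregation.

**Proximal/distal partition.**  Eligible cells are non-reference cells with
a defined k-distance.  Per slice, the `max(1, floor(fraction · n_eligible))`
eligible cells with the smallest k-distance form the proximal region
(default fraction 0.10, i.e. the nearest decile); everything else is
distal.  Ties at the cutoff are broken by (k-distance, cell id) so the
partition is deterministic.  Reference-type cells are excluded from
eligibility and from region proportions: they would trivially dominate the
proximal decile and mask every other signal.

**Enrichment test.**  Per slice with both regions, the per-type share of
eligible cells is computed within each region (shares sum to 1 per region).
For each type observed in ≥ 2 such slices, the paired per-slice differences
d_s = share_proximal(s) − share_distal(s) are tested with a two-sided paired
t-test (t = d̄ / (sd/√m), df = m − 1).  When the differences are constant
(sd = 0) with nonzero mean, the row is flagged `degenerate` with p = 0
rather than dividing by zero.  Because shares are compositional, a strong
enrichment of one type necessarily depresses the others; interpretation
should focus on the types with planted or hypothesized structure.

## Robust rank aggregation

Positions are normalized as r = position/|universe| ∈ (0, 1], and items
missing from a partial list are imputed at r = 1 (ranked last) — the
conservative convention for partial lists.  Under the null that each list
is an independent random permutation, r(k) behaves like the k-th order
statistic of n iid Uniform(0,1) draws, so

    β_k,n = P(U(k) ≤ r(k)) = I_{r(k)}(k, n − k + 1)

is evaluated with the regularized incomplete beta function (numerically
stable versus explicit binomial sums; the two agree to 1e-10 for n ≤ 25).
The score ρ = min_k β_k,n is corrected by the number of minima considered:
p = min(1, ρ·n).  Since each β_k is marginally Uniform(0,1) under the null,
ρ ≤ P(min_k β_k ≤ ρ) ≤ n·ρ; the corrected p is therefore valid but
conservative, which the null-calibration tests confirm empirically
(observed type-I error ≈ 1–2% at α = 5%).  Ties are broken by item name
everywhere so consensus rankings are total and deterministic.

Ligand–receptor aggregation ranks pairs within each slice by descending
occurrence count (ties by pair name) and aggregates the resulting lists
over the union universe.  Full lists are assumed; no score-threshold
truncation is applied.

## Regulon specificity

A regulon's activity vector over cells is normalized to a probability
distribution P^R; a cell type is the normalized indicator P^C.  With base-2
logarithms, JSD(P^R, P^C) = H((P^R+P^C)/2) − (H(P^R)+H(P^C))/2 lies in
[0, 1] and RSS = 1 − √JSD lies in [0, 1], reaching 1 exactly when activity
is uniform on the type's cells and 0 for disjoint supports.  Shannon
entropy is used with the standard minus sign and the 0·log 0 ≡ 0
convention.  The log base is a documented choice: it cancels in none of
these quantities, and base 2 gives the clean [0, 1] range.  All-zero
activity vectors are reported as missing rather than scored.  P^C is
computed over all annotated cells of the analyzed population, not
per-sample.

## Signature scoring

**ssGSEA.**  Per sample, genes are ranked by expression descending (the top
gene has rank value N; expression ties broken by gene name so the score is
a pure rank statistic, invariant to monotone transforms).  Walking down the
ranking, the in-set cumulative weight uses rank^α normalized by the set's
total weight (α = 0.25) and the out-set cumulative weight takes uniform
steps 1/(N − |S|); the score is the sum of the deviations (P_in − P_out)
over all positions.  The sum statistic with α = 0.25 and no cohort-wide
rescaling is the common single-sample default; it is recorded here so tests
can be exact.

**AUCell-style AUC.**  Per cell, genes are ranked descending with ties
broken by a seeded random shuffle; the recovery curve counts set genes
among the top T = ⌈top_fraction·N⌉ ranks (top_fraction = 0.05 by default);
the score is the step-curve area divided by the maximal area (all set genes
at the very top), giving [0, 1].

**Simple scores.**  Cytolytic activity is the geometric mean of GZMA and
PRF1; matrices containing zeros are handled with a +0.01 offset inside the
log (not subtracted afterwards — documented, and exact when all values are
positive and the offset set to 0).  TLS/IFN-γ/expanded-immune scores are
arithmetic means over their sets.  The T-cell-inflamed score subtracts each
sample's mean housekeeping expression from every signature gene and takes
the weighted sum; the housekeeping list and weights must be supplied by the
user.  Gene-symbol matching is case-insensitive; unmatched symbols are
reported in errors rather than silently dropped.

**Median split.**  Samples strictly above the median score are "high";
ties at the median go to "low" (an arbitrary but fixed rule — only
determinism matters for downstream contingency tests).  An all-equal score
vector is rejected as a degenerate split.

## Transcriptional homogeneity

Marker-gene expression is discretized per gene into 10 equal-width bins
over the analyzed population's [min, max] (equal-frequency binning is
available behind a flag); constant genes map to bin 0 and maxima are
clamped into the last bin.  Pairwise NMI between two cells treats the genes
as samples of the joint bin distribution; NMI = I/√(H·H) with base-2 logs
(the base cancels), and a constant profile (zero entropy) yields NMI = 0 by
convention.  Per tumor sample, min(100, available) cells are subsampled
without replacement 100 times and the median pairwise NMI recorded per
replicate; samples below the subsample size contribute all their cells
rather than being dropped, and samples with < 2 cells are skipped.
Replicates use spawned seed substreams, so results are reproducible and
per-sample streams independent.

Because the bins are defined over the pooled analyzed population, the NMI
is a *relative* homogeneity measure: a population occupying a narrow part
of the pooled expression range scores high, and with G genes and 10 bins
the empirical MI of unrelated profiles has an upward small-sample bias of
order (bins−1)²/(2G ln 2) — comparisons should therefore use a fixed gene
panel, as the subsampling design does.  Note also that NMI measures
statistical dependence, not similarity: two deterministic transformations
of the same profile are maximally dependent.

## Cancer preference

For subtype i and cancer j, the 2×2 table (a = i∩j, b = i∖j, c = j∖i,
d = rest) gives the sample cross-product odds ratio (a·d)/(b·c) — not the
conditional MLE — with the Haldane–Anscombe +0.5 added to all four cells
iff any cell is zero.  The two-sided Fisher exact p sums hypergeometric
probabilities not exceeding the observed table's and is computed from the
uncorrected integer table.

## Quality control and marker finding

QC removes cells that *strictly* exceed 40,000 total UMIs, detect strictly
fewer than 500 or strictly more than 5,000 genes, or have a mitochondrial
fraction (symbols prefixed "MT-", case-insensitive) strictly above 20%;
cells exactly at a boundary are retained.  The report lists each removed
cell with the first failed criterion in the order (umi, min_genes,
max_genes, mito).  Filtering is idempotent.

Markers are found one-vs-rest per group with the two-sided Wilcoxon
rank-sum test: exact null when the smaller side has ≤ 50 cells and the
pooled values are tie-free, normal approximation with tie correction
otherwise.  log2FC is the difference of mean log-expression (group minus
rest) — the simplest deterministic convention, recorded because marker
frameworks differ here.  Benjamini–Hochberg adjustment is applied across
genes within each group; significance requires |log2FC| > 1 and adjusted
p < 0.05 by default.

## Synthetic data: what it emulates, and what it does not

The spatial generator reproduces the *structure the analyses assume*:
cell-type patches (anchor types placed by a Thomas-style cluster process —
Poisson cluster centers, Gaussian scatter, mean 4 centers per slice, sd 60
on a 1000×1000 field), directed attraction (a subject cell is placed at a
Gaussian offset from a random target cell with probability `strength`,
else uniformly), repulsion (rejection sampling with acceptance
(1 − e^(−d/range))^strength in the distance d to the nearest target cell),
and neutral/uniform placement.  A type is an anchor iff it is not the
subject of any rule.  Expression is negative binomial (Gamma–Poisson with
shape θ = 2, so var = μ + μ²/θ) at baseline mean 1 count per gene, with
each type's 5 (configurable) marker genes scaled 4-fold (2 log2 units) in
that type.  Defaults of 10 slices × 500 cells × 200 genes keep a full
planted-recovery analysis under a minute on one core.

Deliberately not emulated: tissue histology and anisotropic structures,
per-slice depth/scale differences, gene–gene correlation beyond the planted
type effects, doublets and ambient RNA, and spot-level deconvolution noise
from the coordinate-transfer step (mapped cells are simulated directly at
single-cell resolution).  Passing recovery tests therefore demonstrates the
*statistics* behave correctly on data with known structure — not that any
biological conclusion transfers to a particular real atlas.

The regulon generator assigns targets round-robin and draws Beta(mean·c,
(1−mean)·c) activities (c = 10) with mean `specificity` in target cells and
(1 − specificity)·0.2 elsewhere; the degenerate means 0 and 1 are emitted
exactly so that full specificity is a clean fixture.  The ranked-list
generator promotes a planted item of strength s into the first
max(1, ⌈(1−s)·U⌉) slots uniformly (strongest items placed first so their
windows are least constrained); the bulk generator uses Gaussian log-scale
expression (baseline N(5, 1.5²) per gene, unit noise) with the planted
effect added to signature genes in a randomly chosen half of samples.

## Numerical choices and degenerate inputs

* Beta scores via the regularized incomplete beta; JSD clipped at
  [0, 1] against rounding before the square root.
* Paired t-test: sd indistinguishable from 0 at float precision (relative
  1e-12) is treated as constant differences.
* Tie-breaks: gene name (ssGSEA), seeded shuffle (AUCell), item name (RRA),
  (k-distance, cell id) (partition), alphabetical (rankings) — every
  ranked output is deterministic.
* Problem sizes in the acceptance script (10-slice/400-cell collections,
  200-simulation null batteries, 100-seed consensus recovery, 100-sample
  cohorts) were chosen so the whole battery completes in well under a
  minute while keeping Monte-Carlo standard errors a few percent at most.

## Known limitations

* `find_markers` loops genes × groups through scipy; it is meant for
  hundreds-to-thousands of genes, not genome-wide matrices.
* Expression matrices are dense in memory; Matrix Market input is read
  sparse but densified.  At the intended scale (10⁴–10⁵ cells × curated
  gene panels) this is not a constraint.
* The paired enrichment t-test assumes slices are exchangeable replicates;
  slices from different platforms or tissues should be stratified by the
  caller.
* The enrichment test inherits the compositionality of proportions; it
  tests shares, not absolute densities.
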