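# cafscape

Statistical toolkit for spatially mapped single-cell tumor atlases, built
around the questions that arise when studying cancer-associated fibroblasts
(CAFs) and their neighborhood in the tumor microenvironment:

* **Who sits next to whom?**  Per-cell *spatial k-distance* — the mean
  Euclidean distance from a cell to its k nearest cells of a reference type
  within one tissue slice — with per-slice cell-type proximity rankings, a
  proximal/distal partition (nearest decile by default) and paired t-tests
  on region composition across slices.
* **What is consistent across slices?**  *Robust rank aggregation* (RRA) of
  per-slice ranked lists.  For an item with sorted normalized ranks
  r(1) ≤ … ≤ r(n) over n lists, the beta score
  β_k,n = P(U(k) ≤ r(k)) for the k-th order statistic of n iid Uniform(0,1)
  variables, ρ = min_k β_k,n, and the Bonferroni-corrected p = min(1, ρ·n).
* **Which regulons define a cell type?**  The *regulon specificity score*
  RSS(R,C) = 1 − √JSD(P^R, P^C), where P^R is the regulon's activity
  distribution over cells and P^C the normalized cell-type indicator,
  with base-2 Jensen–Shannon divergence so RSS ∈ [0, 1].
* **How homogeneous is a population?**  Pairwise *normalized mutual
  information* NMI(X,Y) = I(X;Y)/√(H(X)·H(Y)) between 10-bin discretized
  marker-gene profiles, medians over repeated 100-cell subsamples.
* **Does a subtype prefer a cancer type?**  2×2 cross-product odds ratios
  with Fisher's exact test.
* **Signature scoring.**  Single-sample GSEA (rank-weighted running sum),
  AUCell-style recovery-curve AUC, geometric-mean scores (cytolytic
  activity), mean-expression scores (TLS, IFN-γ, expanded immune), the
  T-cell-inflamed weighted sum with housekeeping normalization, and
  median-based high/low splits.

A synthetic-data module generates multi-slice spatial maps with
configurable attraction/repulsion between cell types, negative-binomial
expression with planted marker genes, regulon activity with planted targets,
ranked-list families with planted consensus items and bulk cohorts with a
planted group effect — so every statistic can be validated against ground
truth.

## Worked example

Simulate an 8-slice collection in which endothelial cells are attracted to
mCAFs and epithelial cells are repelled, then recover that structure:

```python
from cafscape import (SimulationConfig, SpatialRule, simulate_collection,
                      proximity_enrichment, proximity_ranked_lists, rra)

cfg = SimulationConfig(
    n_slices=8, cells_per_slice=300,
    cell_types={"mCAF": 0.3, "endothelial": 0.25, "epithelial": 0.25, "Tcell": 0.2},
    spatial_rules=[
        SpatialRule("endothelial", "mCAF", "attract", strength=0.8, range=40.0),
        SpatialRule("epithelial", "mCAF", "repel", strength=2.0, range=120.0),
    ],
    seed=3,
)
cells, counts, truth = simulate_collection(cfg)

consensus = rra(proximity_ranked_lists(cells, "mCAF", k=10))
print(consensus.table.to_string(index=False))

enrichment = proximity_enrichment(cells, "mCAF", k=10, fraction=0.10)
print(enrichment[["cell_type", "mean_diff", "t", "p", "direction"]].to_string(index=False))
```

Output:

```
       item      rho  p_corrected  consensus_rank
endothelial 0.000152     0.001219               1
      Tcell 0.039018     0.312148               2
 epithelial 1.000000     1.000000               3
  cell_type  mean_diff          t            p         direction
      Tcell  -0.197428  -5.373222 1.037908e-03   distal-enriched
endothelial   0.595715  17.800020 4.358122e-07 proximal-enriched
 epithelial  -0.398287 -34.146790 4.788928e-09   distal-enriched
```

The attracted endothelial cells rank closest to mCAFs in every slice
(consensus rank 1, ρ = 1.5×10⁻⁴) and make up a 60-percentage-point larger
share of the mCAF-proximal decile than of the distal region (paired t-test
across 8 slices, p = 4.4×10⁻⁷); the repelled epithelial cells are
distal-enriched.  Note that region proportions are compositional — a strong
proximal enrichment of one type necessarily depresses the shares of the
others, which is why the neutral T cells drift distal.

A command-line interface mirrors the main operations
(`cafscape kdist|proximity|rra|score|homogeneity|preference`).

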