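"""Per-sample and per-cell gene-set scores.

The suite covers the scoring conventions used around tumor-immune gene
signatures:

* :func:`ssgsea_score` — single-sample GSEA: a rank-weighted running sum
  over each sample's gene ranking (sum-of-deviations statistic, exponent
  alpha = 0.25 by default).  Drives the iCAF score (top marker genes of
  inflammatory CAFs, scored per bulk sample, then median-split).
* :func:`aucell_score` — per-cell recovery-curve AUC over the top fraction
  of each cell's ranking (AUCell-style), in [0, 1].
* :func:`geometric_mean_score` — e.g. cytolytic activity (CYT), the
  geometric mean of GZMA and PRF1.
* :func:`mean_score` — mean-expression signatures (TLS, IFN-γ 6-gene,
  expanded immune 18-gene).
* :func:`weighted_sum_score` — the T-cell-inflamed weighted sum after
  housekeeping normalization.
* :func:`median_split` — high/low grouping at the median score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, SchemaError

__all__ = [
    "GroupSplit",
    "ssgsea_score",
    "aucell_score",
    "geometric_mean_score",
    "mean_score",
    "weighted_sum_score",
    "median_split",
]


def _match_or_fail(expr: ExpressionMatrix, genes: Sequence[str], minimum: int) -> list[str]:
    matched, unmatched = expr.match_genes(genes)
    matched = [g for g in matched if g in set(expr.genes)]
    if len(matched) < minimum:
        raise SchemaError(
            f"only {len(matched)} of {len(genes)} set genes found in the matrix "
            f"(need >= {minimum}); missing: {unmatched[:10]}"
        )
    return matched


def ssgsea_score(
    expr: ExpressionMatrix, gene_set: Sequence[str], alpha: float = 0.25
) -> pd.Series:
    """Single-sample GSEA score per sample (sum-of-deviations statistic).

    Per sample, genes are ranked by expression descending (the highest
    expressed gene carries rank value N).  Walking down the ranking, the
    in-set cumulative weight at each position uses |rank|^alpha normalized
    by the set's total weight; the out-set cumulative weight takes uniform
    steps 1/(N − |S|).  The score is the sum over positions of
    (P_in − P_out).  Ties in expression are broken by gene name, so the
    score depends only on ranks (invariant to monotone transforms).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    members = set(_match_or_fail(expr, gene_set, minimum=2))
    genes = np.array(expr.genes)
    n = len(genes)
    if len(members) >= n:
        raise SchemaError("gene set covers the whole matrix; out-set is empty")
    vals = expr.values
    scores = {}
    name_order = np.argsort(genes, kind="mergesort")  # ties -> gene-name order
    for sample in expr.cells:
        x = vals[sample].to_numpy()[name_order]
        order = name_order[np.argsort(-x, kind="mergesort")]
        in_set = np.isin(genes[order], list(members))
        rank_values = np.arange(n, 0, -1, dtype=float)  # N for the top gene
        w = np.where(in_set, rank_values**alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~in_set) / (n - len(members))
        scores[sample] = float((p_in - p_out).sum())
    return pd.Series(scores, name="ssgsea")


def aucell_score(
    expr: ExpressionMatrix,
    gene_set: Sequence[str],
    top_fraction: float = 0.05,
    seed: int = 0,
) -> pd.Series:
    """Recovery-curve AUC per cell, in [0, 1].

    Genes are ranked descending by expression with ties broken by a seeded
    random shuffle; the recovery curve counts set genes among the top
    T = ceil(top_fraction × N) ranks, and the score is its area divided by
    the maximal area (every set gene at the very top).
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    members = set(_match_or_fail(expr, gene_set, minimum=1))
    genes = np.array(expr.genes)
    n = len(genes)
    t_top = math.ceil(top_fraction * n)
    if t_top < 1:
        raise ValueError("top_fraction yields an empty top window")
    rng = np.random.default_rng(seed)
    in_set_by_gene = np.isin(genes, list(members))
    n_set = int(in_set_by_gene.sum())
    max_area = sum(min(t, n_set) for t in range(1, t_top + 1))
    scores = {}
    for cell in expr.cells:
        x = expr.values[cell].to_numpy()
        shuffle = rng.permutation(n)  # random tie-break, one draw per cell
        order = shuffle[np.argsort(-x[shuffle], kind="mergesort")]
        hits = in_set_by_gene[order[:t_top]]
        area = int(np.cumsum(hits).sum())
        scores[cell] = area / max_area
    return pd.Series(scores, name="aucell")


def geometric_mean_score(
    expr: ExpressionMatrix, gene_set: Sequence[str], eps: float = 0.01
) -> pd.Series:
    """Geometric mean of set-gene expression per sample.

    Zeros are handled by adding ``eps`` before the log (and not subtracting
    it afterwards); with all-positive input and ``eps=0`` this is the
    classical geometric mean.
    """
    members = _match_or_fail(expr, gene_set, minimum=1)
    sub = expr.values.loc[members]
    if eps == 0 and (sub.to_numpy() <= 0).any():
        raise ValueError("eps=0 requires strictly positive expression")
    return pd.Series(
        np.exp(np.log(sub + eps).mean(axis=0)), index=expr.cells, name="geomean"
    )


def mean_score(expr: ExpressionMatrix, gene_set: Sequence[str]) -> pd.Series:
    """Arithmetic mean of set-gene expression per sample."""
    members = _match_or_fail(expr, gene_set, minimum=1)
    return pd.Series(expr.values.loc[members].mean(axis=0), name="mean")


def weighted_sum_score(
    expr: ExpressionMatrix,
    gene_set: Sequence[str],
    weights: Sequence[float],
    housekeeping: Sequence[str],
) -> pd.Series:
    """Weighted sum of signature genes after housekeeping normalization.

    Per sample, each signature gene's expression has the sample's mean
    housekeeping expression subtracted; the score is Σ_g w_g · normalized_g.
    Adding a constant to every gene (signature and housekeeping alike)
    leaves the score unchanged.
    """
    if len(weights) != len(gene_set):
        raise SchemaError(
            f"{len(weights)} weights supplied for {len(gene_set)} signature genes"
        )
    members = _match_or_fail(expr, gene_set, minimum=len(gene_set))
    hk = _match_or_fail(expr, housekeeping, minimum=1)
    hk_mean = expr.values.loc[hk].mean(axis=0)
    normalized = expr.values.loc[members].sub(hk_mean, axis=1)
    w = np.asarray(weights, dtype=float)
    return pd.Series(normalized.mul(w, axis=0).sum(axis=0), name="weighted_sum")


@dataclass
class GroupSplit:
    """High/low grouping of samples at the median score."""

    groups: pd.Series  # per sample: "high" or "low"
    threshold: float


def median_split(scores: pd.Series) -> GroupSplit:
    """Split samples at the median: score > median → high, else low.

    Scores equal to the median go to "low" (documented tie rule).  Invariant
    under strictly monotone transforms of the scores.
    """
    if len(scores) < 2:
        raise ValueError("median_split needs at least 2 samples")
    if scores.nunique() == 1:
        raise ValueError("degenerate split: all scores identical")
    threshold = float(scores.median())
    groups = pd.Series(
        np.where(scores > threshold, "high", "low"), index=scores.index, name="group"
    )
    return GroupSplit(groups=groups, threshold=threshold)
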