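"""Transcriptional homogeneity (discretized-profile NMI) and cancer
preference odds ratios.

Homogeneity of a cell population is measured by discretizing marker-gene
expression into bins (10 by default, equal width per gene), then computing
the normalized mutual information between the bin profiles of cell pairs:

    NMI(X, Y) = I(X; Y) / sqrt(H(X) · H(Y))

over the genes shared by the pair, with the convention NMI = 0 when either
profile is constant.  Per tumor sample, a fixed number of cells (100) is
subsampled repeatedly (100 times) and the median pairwise NMI recorded per
replicate; homogeneous populations score near 1, mixtures of expression
programs lower.

Cancer preference of a cell subtype is the cross-product odds ratio of the
2×2 table (subtype i in cancer j / i elsewhere / non-i in j / non-i
elsewhere), tested with Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, SchemaError

__all__ = [
    "DiscretizedProfile",
    "HomogeneityResult",
    "discretize",
    "pairwise_nmi",
    "nmi_matrix",
    "homogeneity",
    "preference_or",
]


@dataclass
class DiscretizedProfile:
    """Per-cell bin-index vectors over a shared marker gene order."""

    bins: pd.DataFrame  # cells as rows, genes as columns, integer bin indices
    n_bins: int


def discretize(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    n_bins: int = 10,
    method: str = "width",
) -> DiscretizedProfile:
    """Discretize each marker gene into ``n_bins`` bins across the cells.

    ``method='width'`` (default) uses equal-width bins over each gene's
    [min, max]; ``method='frequency'`` uses equal-frequency (quantile) bins.
    Constant genes are assigned bin 0 for every cell; the maximum value is
    clamped into the last bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    missing = [g for g in genes if g not in set(expr.genes)]
    if missing:
        raise SchemaError(f"marker gene(s) missing from the matrix: {missing[:10]}")
    mat = expr.values.loc[list(genes)].to_numpy()  # genes × cells
    out = np.zeros_like(mat, dtype=np.int64)
    for gi in range(mat.shape[0]):
        x = mat[gi]
        lo, hi = x.min(), x.max()
        if hi == lo:
            continue  # constant gene -> bin 0
        if method == "width":
            width = (hi - lo) / n_bins
            out[gi] = np.minimum((x - lo) // width, n_bins - 1).astype(np.int64)
        elif method == "frequency":
            edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
            out[gi] = np.searchsorted(edges, x, side="right")
        else:
            raise ValueError(f"unknown binning method {method!r}")
    bins = pd.DataFrame(out.T, index=expr.cells, columns=list(genes))
    return DiscretizedProfile(bins=bins, n_bins=n_bins)


def _entropy_from_counts(counts: np.ndarray, total: int) -> float:
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def pairwise_nmi(x: Sequence[int], y: Sequence[int]) -> float:
    """NMI between two discretized cell profiles, in [0, 1].

    The joint distribution over bin pairs is estimated across genes; MI and
    entropies use base-2 logs with 0·log0 ≡ 0.  If either profile is
    constant (zero entropy) the NMI is defined as 0.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal gene length")
    g = len(x)
    if g < 1:
        raise ValueError("profiles must be non-empty")
    joint = pd.crosstab(x, y).to_numpy()
    hx = _entropy_from_counts(joint.sum(axis=1), g)
    hy = _entropy_from_counts(joint.sum(axis=0), g)
    if hx == 0.0 or hy == 0.0:
        return 0.0
    hxy = _entropy_from_counts(joint.ravel(), g)
    mi = hx + hy - hxy
    return float(mi / np.sqrt(hx * hy))


def nmi_matrix(profiles: np.ndarray, n_bins: int) -> np.ndarray:
    """All-pairs NMI for a (cells × genes) bin-index matrix (vectorized)."""
    profiles = np.asarray(profiles, dtype=np.int64)
    n, g = profiles.shape
    n_states = n_bins * n_bins
    # marginal entropies per cell
    h = np.empty(n)
    for i in range(n):
        h[i] = _entropy_from_counts(np.bincount(profiles[i], minlength=n_bins), g)
    out = np.eye(n)
    for i in range(n):
        codes = profiles[i][None, :] * n_bins + profiles[i + 1 :]
        if codes.size == 0:
            continue
        offsets = np.arange(codes.shape[0])[:, None] * n_states
        flat = np.bincount((codes + offsets).ravel(), minlength=codes.shape[0] * n_states)
        joint = flat.reshape(codes.shape[0], n_states)
        p = joint / g
        with np.errstate(divide="ignore", invalid="ignore"):
            hxy = -np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0).sum(axis=1)
        mi = h[i] + h[i + 1 :] - hxy
        denom = np.sqrt(h[i] * h[i + 1 :])
        nmi = np.where(denom > 0, mi / np.maximum(denom, 1e-300), 0.0)
        out[i, i + 1 :] = nmi
        out[i + 1 :, i] = nmi
    if np.any(h == 0):
        out[h == 0, :] = 0.0
        out[:, h == 0] = 0.0
    return np.clip(out, 0.0, 1.0)


@dataclass
class HomogeneityResult:
    """Median pairwise NMI per (sample, replicate) from repeated subsampling."""

    table: pd.DataFrame  # sample, replicate, n_cells_used, median_nmi
    n_cells: int
    n_reps: int
    seed: int
    skipped_samples: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return (
            self.table.groupby("sample")["median_nmi"]
            .agg(["median", "mean", "std"])
            .reset_index()
        )


def homogeneity(
    expr: ExpressionMatrix,
    cells_by_sample: Mapping[str, str] | pd.Series,
    markers: Sequence[str],
    n_cells: int = 100,
    n_reps: int = 100,
    seed: int = 0,
    n_bins: int = 10,
) -> HomogeneityResult:
    """Transcriptional homogeneity per sample via subsampled pairwise NMI.

    Per sample and replicate, ``min(n_cells, available)`` cells are drawn
    without replacement and the median of all pairwise NMIs recorded.
    Samples smaller than the subsample size contribute all their cells;
    samples with fewer than 2 cells are skipped with a warning.  Replicates
    use seeded substreams so results are reproducible.
    """
    labels = pd.Series(cells_by_sample, dtype=str).reindex(expr.cells)
    if labels.isna().any():
        missing = labels.index[labels.isna()][0]
        raise SchemaError(f"no sample label for cell {missing!r}")
    prof = discretize(expr, markers, n_bins=n_bins)
    bins = prof.bins.to_numpy()
    cell_index = {c: i for i, c in enumerate(expr.cells)}
    samples = sorted(labels.unique())
    streams = np.random.SeedSequence(seed).spawn(len(samples))
    rows = []
    skipped = []
    for sample, stream in zip(samples, streams):
        members = [cell_index[c] for c in labels.index[labels == sample]]
        if len(members) < 2:
            warnings.warn(f"sample {sample!r} has < 2 cells; skipped")
            skipped.append(sample)
            continue
        rng = np.random.default_rng(stream)
        size = min(n_cells, len(members))
        for rep in range(n_reps):
            chosen = rng.choice(members, size=size, replace=False)
            mat = nmi_matrix(bins[chosen], n_bins)
            iu = np.triu_indices(size, k=1)
            rows.append(
                {
                    "sample": sample,
                    "replicate": rep,
                    "n_cells_used": size,
                    "median_nmi": float(np.median(mat[iu])),
                }
            )
    return HomogeneityResult(
        table=pd.DataFrame(rows),
        n_cells=n_cells,
        n_reps=n_reps,
        seed=seed,
        skipped_samples=skipped,
    )


def preference_or(annotations: pd.DataFrame) -> pd.DataFrame:
    """Cancer-preference odds ratios per (subtype, cancer type) pair.

    ``annotations`` needs columns ``subtype`` and ``cancer_type`` (one row
    per cell).  For each pair (i, j) a 2×2 table (a = i in j, b = i
    elsewhere, c = non-i in j, d = non-i elsewhere) yields the cross-product
    OR (a·d)/(b·c); the Haldane–Anscombe +0.5 correction is applied to all
    four cells iff any cell is zero.  Two-sided Fisher exact p-values come
    from the uncorrected integer table.
    """
    for col in ("subtype", "cancer_type"):
        if col not in annotations.columns:
            raise SchemaError(f"annotations missing column {col!r}")
    counts = pd.crosstab(annotations["subtype"], annotations["cancer_type"])
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 subtypes and 2 cancer types")
    total = counts.to_numpy().sum()
    rows = []
    for subtype in counts.index:
        row_total = counts.loc[subtype].sum()
        for cancer in counts.columns:
            col_total = counts[cancer].sum()
            a = int(counts.loc[subtype, cancer])
            b = int(row_total - a)
            c = int(col_total - a)
            d = int(total - a - b - c)
            if row_total == 0 or col_total == 0:
                continue
            table = np.array([[a, b], [c, d]], dtype=float)
            if (table == 0).any():
                table = table + 0.5
            odds = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {
                    "subtype": subtype,
                    "cancer_type": cancer,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": odds,
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)
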