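"""Domain containers, file I/O, quality control and marker finding.

The containers here are thin, validated wrappers around pandas objects:

* :class:`CellMap` — spatially mapped single cells (one row per cell with
  slice membership, 2-D coordinates and a cell-type label).
* :class:`ExpressionMatrix` — a gene × cell (or gene × sample) non-negative
  expression matrix tagged with a units flag (``"counts"`` or ``"log"``).
* :class:`GeneSetCollection` — named gene sets, optionally weighted.
* :class:`QCThresholds` / :func:`qc_filter` — standard droplet QC.
* :func:`find_markers` — a one-vs-rest Wilcoxon rank-sum marker finder with
  Benjamini–Hochberg correction, feeding marker genes to downstream scoring.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SchemaError",
    "UnitsError",
    "CellMap",
    "ExpressionMatrix",
    "GeneSetCollection",
    "QCThresholds",
    "MarkerTable",
    "read_cell_map",
    "write_cell_map",
    "read_expression",
    "read_gmt",
    "read_weighted_gene_set",
    "log_normalize",
    "qc_filter",
    "find_markers",
    "top_markers",
]

CELLMAP_COLUMNS = ("cell_id", "slice_id", "x", "y", "cell_type")


class SchemaError(ValueError):
    """An input table violates the documented schema or an invariant."""


class UnitsError(ValueError):
    """An operation received expression data in the wrong units."""


# ---------------------------------------------------------------------------
# CellMap
# ---------------------------------------------------------------------------


@dataclass
class CellMap:
    """Per-cell spatial record: cell id, slice id, x/y coordinates, cell type.

    ``cell_id`` must be unique within each slice and coordinates finite.
    Distance computations elsewhere in the package are always confined to a
    single slice.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CELLMAP_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"cell map missing column(s): {', '.join(missing)}")
        tab = self.table.loc[:, list(CELLMAP_COLUMNS)].copy()
        tab["cell_id"] = tab["cell_id"].astype(str)
        tab["slice_id"] = tab["slice_id"].astype(str)
        tab["cell_type"] = tab["cell_type"].astype(str)
        for col in ("x", "y"):
            vals = pd.to_numeric(tab[col], errors="coerce")
            bad = vals.isna() | ~np.isfinite(vals)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"non-finite or non-numeric coordinate in column {col!r} at row {row}"
                )
            tab[col] = vals.astype(float)
        dup = tab.duplicated(subset=["slice_id", "cell_id"])
        if dup.any():
            cid = tab.loc[dup, "cell_id"].iloc[0]
            raise SchemaError(f"duplicated cell_id {cid!r} within one slice")
        tab = tab.reset_index(drop=True)
        object.__setattr__(self, "table", tab)

    @property
    def slices(self) -> list[str]:
        return list(dict.fromkeys(self.table["slice_id"]))

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())

    @property
    def n_cells(self) -> int:
        return len(self.table)

    def slice_view(self, slice_id: str) -> pd.DataFrame:
        return self.table[self.table["slice_id"] == slice_id]


def read_cell_map(path: str | Path, dialect: str = "csv") -> CellMap:
    """Read a cell map from CSV/TSV with header cell_id,slice_id,x,y,cell_type."""
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'csv' or 'tsv')")
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in CELLMAP_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"cell map file missing column(s): {', '.join(missing)}")
    for col in ("x", "y"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"could not parse coordinate {col!r} at data row {row}: "
                f"{raw[col].iloc[row]!r}"
            )
        raw[col] = vals
    return CellMap(raw)


def write_cell_map(cells: CellMap, path: str | Path, dialect: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    cells.table.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene × cell (or gene × sample) non-negative expression matrix.

    ``units`` is ``"counts"`` for raw UMI counts and ``"log"`` for
    log-normalized data; QC requires counts, marker finding requires log.
    Gene symbols must be unique after upper-casing.
    """

    values: pd.DataFrame  # genes as rows, cells as columns
    units: str = "counts"

    def __post_init__(self) -> None:
        if self.units not in ("counts", "log"):
            raise ValueError(f"units must be 'counts' or 'log', got {self.units!r}")
        vals = self.values.astype(float)
        if (vals.to_numpy() < 0).any():
            raise SchemaError("expression values must be non-negative")
        genes_upper = vals.index.astype(str).str.upper()
        if genes_upper.duplicated().any():
            dup = genes_upper[genes_upper.duplicated()][0]
            raise SchemaError(f"duplicate gene symbol after upper-casing: {dup!r}")
        vals.index = vals.index.astype(str)
        vals.columns = vals.columns.astype(str)
        object.__setattr__(self, "values", vals)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cells(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def total_counts(self) -> pd.Series:
        """Per-cell total (UMI counts when units == 'counts')."""
        return self.values.sum(axis=0)

    def detected_genes(self) -> pd.Series:
        """Per-cell number of genes with nonzero expression."""
        return (self.values > 0).sum(axis=0)

    def mito_fraction(self) -> pd.Series:
        """Per-cell fraction of expression on MT- prefixed genes (case-insensitive)."""
        is_mt = self.values.index.str.upper().str.startswith("MT-")
        tot = self.values.sum(axis=0)
        mito = self.values.loc[is_mt].sum(axis=0) if is_mt.any() else 0.0
        with np.errstate(invalid="ignore"):
            frac = mito / tot
        return pd.Series(np.where(tot > 0, frac, 0.0), index=self.values.columns)

    def match_genes(self, genes: Sequence[str]) -> tuple[list[str], list[str]]:
        """Case-insensitive gene matching; returns (matched row labels, unmatched)."""
        lookup = {g.upper(): g for g in self.values.index}
        matched, unmatched = [], []
        for g in genes:
            hit = lookup.get(str(g).upper())
            (matched if hit is not None else unmatched).append(hit or str(g))
        return matched, unmatched


def read_expression(path: str | Path, format: str = "dense-csv") -> ExpressionMatrix:
    """Read expression data.

    ``dense-csv``: genes as row index, cells as column header.
    ``mtx-triplet``: Matrix Market file with ``genes.tsv`` and ``barcodes.tsv``
    sidecars in the same directory (first sidecar column used as identifier).
    """
    path = Path(path)
    if format == "dense-csv":
        df = pd.read_csv(path, index_col=0)
        return ExpressionMatrix(df, units="counts")
    if format == "mtx-triplet":
        genes_path = path.parent / "genes.tsv"
        barcodes_path = path.parent / "barcodes.tsv"
        for sidecar in (genes_path, barcodes_path):
            if not sidecar.exists():
                raise SchemaError(f"missing sidecar file {sidecar.name} next to {path.name}")
        mat = spio.mmread(path).tocsr()
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
        if mat.shape != (len(genes), len(barcodes)):
            raise SchemaError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"({len(genes)} genes, {len(barcodes)} barcodes)"
            )
        df = pd.DataFrame(mat.toarray(), index=genes, columns=barcodes)
        return ExpressionMatrix(df, units="counts")
    raise ValueError(f"unknown format {format!r}")


def log_normalize(expr: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Depth-normalize counts to ``scale`` per cell and apply log2(1 + x)."""
    if expr.units != "counts":
        raise UnitsError("log_normalize expects raw counts")
    tot = expr.values.sum(axis=0).replace(0, 1.0)
    norm = expr.values.div(tot, axis=1) * scale
    return ExpressionMatrix(np.log2(1.0 + norm), units="log")


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-gene weights.

    ``sets`` maps a set name to a (genes, weights) pair where ``weights`` is
    either None or a list aligned one-to-one with ``genes``.
    """

    sets: dict[str, tuple[list[str], list[float] | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (genes, weights) in self.sets.items():
            if not genes:
                raise SchemaError(f"gene set {name!r} is empty")
            if weights is not None and len(weights) != len(genes):
                raise SchemaError(
                    f"gene set {name!r}: {len(weights)} weights for {len(genes)} genes"
                )

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name][0]

    def weights(self, name: str) -> list[float] | None:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from GMT (tab-separated: name, description, genes...)."""
    sets: dict[str, tuple[list[str], list[float] | None]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
            name, _desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets[name] = (genes, None)
    return GeneSetCollection(sets)


def read_weighted_gene_set(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read one weighted set from a 2-column TSV (gene, weight)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "weight"])
    set_name = name or Path(path).stem
    return GeneSetCollection(
        {set_name: (df["gene"].astype(str).tolist(), df["weight"].astype(float).tolist())}
    )


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCThresholds:
    """Droplet QC thresholds.

    Cells are *removed* when they strictly exceed ``max_umi`` UMIs, detect
    strictly fewer than ``min_genes`` or strictly more than ``max_genes``
    genes, or have a mitochondrial fraction strictly above ``max_mito``.
    Cells exactly at a threshold are retained (strict-inequality exclusion).
    """

    max_umi: int = 40_000
    min_genes: int = 500
    max_genes: int = 5_000
    max_mito: float = 0.20

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0 < self.max_mito <= 1:
            raise ValueError("max_mito must be in (0, 1]")


def qc_filter(
    expr: ExpressionMatrix, thr: QCThresholds = QCThresholds()
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Filter cells by UMI count, detected genes and mitochondrial fraction.

    Returns the filtered matrix and a per-cell report with the first failed
    criterion in the order (umi, min_genes, max_genes, mito).
    """
    if expr.units != "counts":
        raise UnitsError("qc_filter requires raw counts, got log-normalized data")
    umi = expr.total_counts()
    ngenes = expr.detected_genes()
    mito = expr.mito_fraction()
    reasons = pd.Series("", index=expr.values.columns, dtype=object)
    # first failed criterion wins, in the documented order
    for mask, reason in (
        (umi > thr.max_umi, "umi"),
        (ngenes < thr.min_genes, "min_genes"),
        (ngenes > thr.max_genes, "max_genes"),
        (mito > thr.max_mito, "mito"),
    ):
        reasons[(reasons == "") & mask] = reason
    report = pd.DataFrame(
        {
            "cell_id": expr.values.columns,
            "umi": umi.to_numpy(),
            "detected_genes": ngenes.to_numpy(),
            "mito_fraction": mito.to_numpy(),
            "pass": (reasons == "").to_numpy(),
            "reason": reasons.to_numpy(),
        }
    )
    keep = report.loc[report["pass"], "cell_id"]
    filtered = ExpressionMatrix(expr.values.loc[:, keep], units="counts")
    return filtered, report


# ---------------------------------------------------------------------------
# Marker finding
# ---------------------------------------------------------------------------

#: upper bound on per-side group size for the exact rank-sum null
_EXACT_MAX_N = 50


@dataclass
class MarkerTable:
    """One-vs-rest marker statistics, one row per (gene, group)."""

    table: pd.DataFrame  # gene, group, log2fc, statistic, pvalue, padj, significant


def _ranksum_pvalue(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) statistic and p-value.

    Exact null for small tie-free groups, normal approximation with tie
    correction otherwise.
    """
    pooled = np.concatenate([a, b])
    exact = (
        min(len(a), len(b)) <= _EXACT_MAX_N
        and len(np.unique(pooled)) == len(pooled)
    )
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def find_markers(
    expr: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> MarkerTable:
    """One-vs-rest rank-sum markers per gene per group.

    ``log2fc`` is the difference of mean log-expression (group minus rest);
    BH adjustment is applied across genes within each group; a gene is
    flagged significant iff ``|log2fc| > lfc_min`` and ``padj < alpha``.
    """
    if expr.units != "log":
        raise UnitsError("find_markers requires log-normalized expression")
    labels = pd.Series(groups, dtype=str)
    labels = labels.reindex(expr.cells)
    if labels.isna().any():
        missing = labels.index[labels.isna()][0]
        raise SchemaError(f"no group label for cell {missing!r}")
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("find_markers needs at least 2 groups")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"group {small.index[0]!r} has fewer than 2 cells")

    mat = expr.values.to_numpy()
    rows = []
    for group in uniq:
        in_group = (labels == group).to_numpy()
        a_mat, b_mat = mat[:, in_group], mat[:, ~in_group]
        pvals, statistics, lfcs = [], [], []
        for gi in range(mat.shape[0]):
            a, b = a_mat[gi], b_mat[gi]
            lfc = float(a.mean() - b.mean())
            if np.ptp(np.concatenate([a, b])) == 0:
                u, p = float(len(a) * len(b)) / 2.0, 1.0
            else:
                u, p = _ranksum_pvalue(a, b)
            lfcs.append(lfc)
            statistics.append(u)
            pvals.append(p)
        padj = multipletests(pvals, method="fdr_bh")[1]
        for gene, lfc, u, p, q in zip(expr.genes, lfcs, statistics, pvals, padj):
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "log2fc": lfc,
                    "statistic": u,
                    "pvalue": p,
                    "padj": q,
                    "significant": abs(lfc) > lfc_min and q < alpha,
                }
            )
    return MarkerTable(pd.DataFrame(rows))


def top_markers(markers: MarkerTable, group: str, n: int) -> list[str]:
    """The n significant genes of a group with largest log2 fold change."""
    tab = markers.table
    sub = tab[(tab["group"] == group) & tab["significant"]]
    sub = sub.sort_values(["log2fc", "gene"], ascending=[False, True])
    return sub["gene"].head(n).tolist()
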