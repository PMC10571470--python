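"""Robust rank aggregation (RRA) of per-slice ranked lists.

Each slice contributes a (possibly partial) ordering of a shared item
universe — cell types sorted by spatial proximity, or ligand–receptor pairs
sorted by occurrence frequency.  For every item the positions are converted
to normalized ranks r ∈ (0,1] (items missing from a list are imputed at
r = 1, i.e. ranked last).  Under the null that a list is a random
permutation, the k-th smallest normalized rank of an item is the k-th order
statistic of n iid Uniform(0,1) draws; the beta score

    β_{k,n}(r) = P(U_(k) ≤ r) = Σ_{l=k}^{n} C(n,l) r^l (1−r)^{n−l}

measures how surprisingly small that order statistic is.  The item's score
is ρ = min_k β_{k,n}(r_(k)), Bonferroni-corrected by the number of minima
considered (p = min(1, ρ·n)).  Small ρ means the item is consistently
ranked near the top across slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "RankedLists",
    "RRAResult",
    "normalize_ranks",
    "beta_scores",
    "rra",
    "aggregate_lri",
    "read_ranked_lists",
    "write_rra_result",
]


@dataclass
class RankedLists:
    """A family of per-slice orderings over a shared item universe."""

    universe: list[str]
    lists: dict[str, list[str]]  # slice_id -> ordering, best first

    def __post_init__(self) -> None:
        uni = [str(u) for u in self.universe]
        if len(set(uni)) != len(uni):
            raise ValueError("universe contains duplicate items")
        uniset = set(uni)
        clean: dict[str, list[str]] = {}
        for sid, items in self.lists.items():
            items = [str(i) for i in items]
            if not items:
                warnings.warn(f"dropping empty ranked list for slice {sid!r}")
                continue
            if len(set(items)) != len(items):
                raise ValueError(f"list for slice {sid!r} contains duplicates")
            unknown = set(items) - uniset
            if unknown:
                raise ValueError(
                    f"list for slice {sid!r} contains items outside the universe: "
                    f"{sorted(unknown)[:5]}"
                )
            clean[str(sid)] = items
        object.__setattr__(self, "universe", uni)
        object.__setattr__(self, "lists", clean)

    @classmethod
    def from_lists(
        cls,
        lists: Mapping[str, Sequence[str]],
        universe: Sequence[str] | None = None,
    ) -> "RankedLists":
        if universe is None:
            universe = sorted({i for items in lists.values() for i in items})
        return cls(list(universe), {k: list(v) for k, v in lists.items()})


def normalize_ranks(lists: RankedLists) -> pd.DataFrame:
    """Normalized rank matrix (items × lists), missing entries imputed at 1.0.

    r = position / |universe| with 1-based positions, so r ∈ (0, 1].
    """
    if not lists.universe:
        raise ValueError("empty universe")
    if not lists.lists:
        raise ValueError("no ranked lists supplied")
    n_items = len(lists.universe)
    mat = pd.DataFrame(1.0, index=lists.universe, columns=list(lists.lists))
    for sid, items in lists.lists.items():
        for pos, item in enumerate(items, start=1):
            mat.loc[item, sid] = pos / n_items
    return mat


def beta_scores(sorted_r: Sequence[float]) -> np.ndarray:
    """β_{k,n} for a sorted vector of normalized ranks.

    β_{k,n} = P(k-th order statistic of n iid U(0,1) ≤ r_(k)), evaluated via
    the regularized incomplete beta function I_r(k, n−k+1).
    """
    r = np.asarray(sorted_r, dtype=float)
    if r.ndim != 1 or len(r) == 0:
        raise ValueError("expected a non-empty 1-D vector of ranks")
    if np.any(np.diff(r) < 0):
        raise ValueError("ranks must be sorted ascending")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("normalized ranks must lie in (0, 1]")
    n = len(r)
    k = np.arange(1, n + 1)
    return special.betainc(k, n - k + 1.0, r)


@dataclass
class RRAResult:
    """Consensus ranking with rho scores and Bonferroni-corrected p-values."""

    table: pd.DataFrame  # item, rho, p_corrected, consensus_rank (sorted by rho)
    n_lists: int

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)


def rra(lists: RankedLists) -> RRAResult:
    """Aggregate ranked lists into a consensus ranking.

    Per item: rho = min_k β_{k,n}(r_(k)); corrected p = min(1, rho · n).
    Items are sorted ascending by rho, ties broken by item name.
    """
    rmat = normalize_ranks(lists)
    n = rmat.shape[1]
    if len(lists.universe) == 1:
        warnings.warn("single-item universe: consensus ranking is trivial")
    rows = []
    for item in rmat.index:
        r_sorted = np.sort(rmat.loc[item].to_numpy())
        rho = float(beta_scores(r_sorted).min())
        rows.append({"item": item, "rho": rho, "p_corrected": min(1.0, rho * n)})
    tab = pd.DataFrame(rows).sort_values(["rho", "item"], kind="mergesort")
    tab["consensus_rank"] = np.arange(1, len(tab) + 1)
    return RRAResult(tab.reset_index(drop=True), n_lists=n)


def aggregate_lri(
    per_slice_lri: Mapping[str, Mapping[str, int] | Sequence[tuple[str, int]]],
) -> RRAResult:
    """Aggregate per-slice ligand–receptor pair occurrence counts.

    Within each slice, pairs are ranked by descending count (ties broken by
    pair name); the per-slice rankings are then combined with :func:`rra`
    over the union universe.
    """
    if not per_slice_lri:
        raise ValueError("no per-slice interaction counts supplied")
    lists: dict[str, list[str]] = {}
    for sid, counts in per_slice_lri.items():
        items = list(counts.items()) if isinstance(counts, Mapping) else list(counts)
        if any(c < 1 for _, c in items):
            raise ValueError(f"occurrence counts must be >= 1 (slice {sid!r})")
        items.sort(key=lambda pc: (-pc[1], pc[0]))
        lists[str(sid)] = [p for p, _ in items]
    return rra(RankedLists.from_lists(lists))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_ranked_lists(path: str | Path, format: str = "long") -> RankedLists:
    """Read ranked lists from TSV.

    long: columns slice_id, rank, item.  wide: one column per list, rows in
    rank order (empty cells allowed for partial lists).
    """
    if format == "long":
        df = pd.read_csv(path, sep="\t", dtype={"slice_id": str, "item": str})
        for col in ("slice_id", "rank", "item"):
            if col not in df.columns:
                raise ValueError(f"long-format file missing column {col!r}")
        lists = {
            sid: sub.sort_values("rank")["item"].tolist()
            for sid, sub in df.groupby("slice_id")
        }
        return RankedLists.from_lists(lists)
    if format == "wide":
        df = pd.read_csv(path, sep="\t", dtype=str)
        lists = {col: df[col].dropna().tolist() for col in df.columns}
        return RankedLists.from_lists(lists)
    raise ValueError(f"unknown format {format!r}")


def write_rra_result(result: RRAResult, path: str | Path) -> None:
    result.table.to_csv(path, sep="\t", index=False)
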