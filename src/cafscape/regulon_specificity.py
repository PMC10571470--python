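"""Regulon specificity scores (RSS) from regulon-activity matrices.

A regulon's per-cell activity (AUCell-style AUC) is normalized into a
probability distribution P^R over cells; a cell type is represented as the
normalized indicator distribution P^C over the same cells.  Their
Jensen–Shannon divergence (base-2 logs, so JSD ∈ [0,1]) quantifies how far
the regulon's activity is from being concentrated in that type, and

    RSS(R, C) = 1 − sqrt(JSD(P^R, P^C))

is 1 when activity is uniform exactly on the type's cells and 0 when the
supports are disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegulonActivityMatrix",
    "RSSMatrix",
    "entropy",
    "jsd",
    "rss",
    "rss_matrix",
    "read_regulon_activity",
]


@dataclass
class RegulonActivityMatrix:
    """Regulon × cell activity scores with per-cell cell-type annotation."""

    activity: pd.DataFrame  # regulons as rows, cells as columns
    cell_types: pd.Series  # indexed by cell id

    def __post_init__(self) -> None:
        act = self.activity.astype(float)
        if (act.to_numpy() < 0).any():
            raise ValueError("regulon activity must be non-negative")
        types = pd.Series(self.cell_types, dtype=str).reindex(act.columns)
        if types.isna().any():
            missing = types.index[types.isna()][0]
            raise ValueError(f"no cell-type annotation for cell {missing!r}")
        object.__setattr__(self, "activity", act)
        object.__setattr__(self, "cell_types", types)

    @property
    def regulons(self) -> list[str]:
        return list(self.activity.index)

    @property
    def types(self) -> list[str]:
        return sorted(self.cell_types.unique())


def entropy(p: Sequence[float]) -> float:
    """Shannon entropy in bits, with 0·log0 ≡ 0.

    ``p`` must be a probability vector (non-negative, summing to 1).
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("probability vector has a negative entry")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum():g}, expected 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def jsd(p: Sequence[float], q: Sequence[float]) -> float:
    """Jensen–Shannon divergence with base-2 logs: JSD ∈ [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    value = entropy((p + q) / 2.0) - (entropy(p) + entropy(q)) / 2.0
    # clip tiny negative rounding noise so sqrt downstream is safe
    return float(min(1.0, max(0.0, value)))


def rss(activity: Sequence[float], indicator: Sequence[float]) -> float:
    """Regulon specificity score: 1 − sqrt(JSD(P^R, P^C)).

    ``activity`` is the regulon's raw per-cell activity (normalized to sum 1
    internally); ``indicator`` is any non-negative membership vector for the
    cell type (normalized likewise).  Invariant to positive rescaling of
    either argument.
    """
    a = np.asarray(activity, dtype=float)
    m = np.asarray(indicator, dtype=float)
    if a.shape != m.shape:
        raise ValueError("activity and indicator must have equal length")
    if (a < 0).any() or (m < 0).any():
        raise ValueError("activity and indicator must be non-negative")
    if a.sum() == 0:
        raise ValueError("all-zero activity vector: RSS undefined")
    if m.sum() == 0:
        raise ValueError("empty cell-type indicator")
    return float(1.0 - np.sqrt(jsd(a / a.sum(), m / m.sum())))


@dataclass
class RSSMatrix:
    """Per-(regulon, cell type) specificity with top regulons per type."""

    scores: pd.DataFrame  # regulons × cell types, RSS values (NaN if undefined)
    top: pd.DataFrame  # cell_type, regulon, rss, rank — top-n per type
    n_top: int = 5


def rss_matrix(ras: RegulonActivityMatrix, n_top: int = 5) -> RSSMatrix:
    """RSS for every (regulon, cell type) pair; top-n regulons flagged per type.

    Regulons with all-zero activity are reported as missing (NaN) with a
    warning rather than scored; ties in the per-type ranking are broken by
    regulon name.
    """
    types = ras.types
    cells = ras.activity.columns
    indicators = {t: (ras.cell_types == t).to_numpy(dtype=float) for t in types}
    scores = pd.DataFrame(np.nan, index=ras.regulons, columns=types)
    for reg in ras.regulons:
        act = ras.activity.loc[reg].to_numpy()
        if act.sum() == 0:
            warnings.warn(f"regulon {reg!r} has all-zero activity; RSS undefined")
            continue
        for t in types:
            scores.loc[reg, t] = rss(act, indicators[t])
    top_rows = []
    for t in types:
        col = scores[t].dropna()
        ordered = col.to_frame("rss").reset_index(names="regulon")
        ordered = ordered.sort_values(["rss", "regulon"], ascending=[False, True], kind="mergesort")
        for rank, (_, row) in enumerate(ordered.head(n_top).iterrows(), start=1):
            top_rows.append(
                {"cell_type": t, "regulon": row["regulon"], "rss": row["rss"], "rank": rank}
            )
    return RSSMatrix(scores=scores, top=pd.DataFrame(top_rows), n_top=n_top)


def read_regulon_activity(
    activity_path: str | Path, annotation_path: str | Path
) -> RegulonActivityMatrix:
    """Read a regulon × cell activity CSV plus a (cell_id, cell_type) CSV."""
    act = pd.read_csv(activity_path, index_col=0)
    annot = pd.read_csv(annotation_path)
    for col in ("cell_id", "cell_type"):
        if col not in annot.columns:
            raise ValueError(f"annotation file missing column {col!r}")
    types = annot.set_index("cell_id")["cell_type"]
    return RegulonActivityMatrix(act, types)
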