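"""Spatial k-distance neighborhood analysis within tissue slices.

For a reference cell type (e.g. a CAF subtype), the spatial k-distance of a
cell is the mean Euclidean distance to its k nearest reference-type cells in
the same slice (self excluded).  From this statistic the module derives

* per-slice rankings of cell types by mean proximity to the reference,
  which feed robust rank aggregation across slices;
* a proximal/distal partition of each slice (the fraction of eligible cells
  with the smallest k-distance is "proximal", default 10%);
* per-cell-type enrichment between the two regions across slices, tested
  with paired t-tests on per-slice composition proportions.

Distances are exact (dense per-slice distance matrices, no approximate
neighbor search) and computed in each slice's native coordinate units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .core_io import CellMap
from .rank_aggregation import RankedLists

__all__ = [
    "KDistanceResult",
    "ProximityPartition",
    "k_distance",
    "celltype_proximity_ranking",
    "proximity_ranked_lists",
    "proximal_partition",
    "proximity_enrichment",
]

DEFAULT_K = 10
DEFAULT_PROXIMAL_FRACTION = 0.10


@dataclass
class KDistanceResult:
    """Per-cell mean distance to the k nearest reference-type cells.

    ``table`` has one row per cell (cell_id, slice_id, cell_type, k_distance);
    k_distance is NaN where undefined (skipped slice, or a reference cell in
    a slice with exactly k reference cells).
    """

    table: pd.DataFrame
    ref_type: str
    k: int
    skipped_slices: list[str] = field(default_factory=list)


def k_distance(cells: CellMap, ref_type: str, k: int = DEFAULT_K) -> KDistanceResult:
    """Spatial k-distance of every cell to the reference type, per slice.

    A slice needs at least k reference cells; reference cells themselves
    need k other reference cells (self is excluded).  Slices with too few
    reference cells are skipped with a warning and flagged in the result.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if ref_type not in set(cells.table["cell_type"]):
        raise ValueError(f"reference type {ref_type!r} not present in the cell map")
    frames = []
    skipped = []
    for sid in cells.slices:
        sl = cells.slice_view(sid)
        is_ref = (sl["cell_type"] == ref_type).to_numpy()
        n_ref = int(is_ref.sum())
        kd = np.full(len(sl), np.nan)
        if n_ref < k:
            warnings.warn(
                f"slice {sid!r} has {n_ref} {ref_type!r} cells (< k={k}); skipped"
            )
            skipped.append(sid)
        else:
            coords = sl[["x", "y"]].to_numpy()
            dmat = cdist(coords, coords[is_ref])
            # exclude self for reference cells
            ref_pos = np.flatnonzero(is_ref)
            dmat[ref_pos, np.arange(n_ref)] = np.inf
            part = np.partition(dmat, k - 1, axis=1)[:, :k]
            kd = part.mean(axis=1)
            if n_ref == k:
                kd[ref_pos] = np.nan  # only k-1 other reference cells available
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": sl["cell_id"].to_numpy(),
                    "slice_id": sid,
                    "cell_type": sl["cell_type"].to_numpy(),
                    "k_distance": kd,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return KDistanceResult(table=table, ref_type=ref_type, k=k, skipped_slices=skipped)


def celltype_proximity_ranking(
    cells: CellMap, ref_type: str, k: int = DEFAULT_K
) -> dict[str, list[str]]:
    """Per-slice cell types ordered from closest to farthest from the reference.

    Types are ordered ascending by the mean k-distance of their member cells;
    the reference type itself is excluded and types absent from a slice are
    omitted (partial lists).  Ties are broken alphabetically.
    """
    kd = k_distance(cells, ref_type, k)
    rankings: dict[str, list[str]] = {}
    for sid in cells.slices:
        if sid in kd.skipped_slices:
            continue
        sub = kd.table[(kd.table["slice_id"] == sid) & (kd.table["cell_type"] != ref_type)]
        sub = sub.dropna(subset=["k_distance"])
        if sub.empty:
            continue
        means = sub.groupby("cell_type")["k_distance"].mean()
        rankings[sid] = means.sort_index().sort_values(kind="mergesort").index.tolist()
    return rankings


def proximity_ranked_lists(
    cells: CellMap, ref_type: str, k: int = DEFAULT_K
) -> RankedLists:
    """Proximity rankings packaged for robust rank aggregation."""
    return RankedLists.from_lists(celltype_proximity_ranking(cells, ref_type, k))


@dataclass
class ProximityPartition:
    """Proximal/distal region assignment of eligible cells, per slice.

    Eligible cells are non-reference cells with a defined k-distance; per
    slice the ``max(1, floor(fraction × n_eligible))`` cells with the
    smallest k-distance are proximal, ties broken by (k_distance, cell_id).
    """

    table: pd.DataFrame  # cell_id, slice_id, cell_type, k_distance, region
    ref_type: str
    fraction: float
    flagged_slices: list[str] = field(default_factory=list)


def proximal_partition(
    kd: KDistanceResult, fraction: float = DEFAULT_PROXIMAL_FRACTION
) -> ProximityPartition:
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    eligible = kd.table.dropna(subset=["k_distance"])
    eligible = eligible[eligible["cell_type"] != kd.ref_type]
    frames = []
    flagged = []
    for sid in kd.table["slice_id"].unique():
        sub = eligible[eligible["slice_id"] == sid]
        if sub.empty:
            if sid not in kd.skipped_slices:
                warnings.warn(f"slice {sid!r} has no eligible cells; flagged")
                flagged.append(sid)
            continue
        n_prox = max(1, math.floor(fraction * len(sub)))
        ordered = sub.sort_values(["k_distance", "cell_id"], kind="mergesort")
        region = np.array(["distal"] * len(ordered), dtype=object)
        region[:n_prox] = "proximal"
        out = ordered.copy()
        out["region"] = region
        frames.append(out)
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=[*kd.table.columns, "region"])
    )
    return ProximityPartition(
        table=table,
        ref_type=kd.ref_type,
        fraction=fraction,
        flagged_slices=kd.skipped_slices + flagged,
    )


def _paired_t(diffs: np.ndarray) -> tuple[float, int, float, bool]:
    """Paired t statistic, df, two-sided p, degenerate flag for sd == 0."""
    m = len(diffs)
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    # sd indistinguishable from zero at float precision counts as constant
    if sd <= 1e-12 * max(1.0, abs(mean)):
        if mean == 0.0:
            return 0.0, m - 1, 1.0, False
        return math.copysign(math.inf, mean), m - 1, 0.0, True
    t = mean / (sd / math.sqrt(m))
    p = 2.0 * float(stats.t.sf(abs(t), df=m - 1))
    return t, m - 1, p, False


def proximity_enrichment(
    cells: CellMap,
    ref_type: str,
    k: int = DEFAULT_K,
    fraction: float = DEFAULT_PROXIMAL_FRACTION,
) -> pd.DataFrame:
    """Per-type enrichment between proximal and distal regions across slices.

    For each slice with both regions, per-type proportions are computed among
    eligible cells within each region (summing to 1 over included types).
    Per-type paired differences proximal − distal across slices are tested
    with a two-sided paired t-test; types observed in fewer than 2 such
    slices are dropped with a warning.  Rows with sd = 0 and nonzero mean
    difference are flagged degenerate (p = 0).

    Returns a table with columns cell_type, n_slices, mean_prox, mean_dist,
    mean_diff, t, df, p, direction, degenerate.
    """
    kd = k_distance(cells, ref_type, k)
    part = proximal_partition(kd, fraction)
    tab = part.table
    slice_frames = []
    for sid, sub in tab.groupby("slice_id"):
        regions = set(sub["region"])
        if regions != {"proximal", "distal"}:
            warnings.warn(f"slice {sid!r} lacks one region; excluded from enrichment")
            continue
        for region, rsub in sub.groupby("region"):
            props = rsub["cell_type"].value_counts(normalize=True)
            slice_frames.append(
                pd.DataFrame(
                    {
                        "slice_id": sid,
                        "region": region,
                        "cell_type": props.index,
                        "prop": props.to_numpy(),
                    }
                )
            )
    if not slice_frames:
        raise ValueError("no slice contributes both proximal and distal regions")
    props = pd.concat(slice_frames, ignore_index=True)
    wide = props.pivot_table(
        index=["slice_id", "cell_type"], columns="region", values="prop", fill_value=0.0
    ).reset_index()
    for col in ("proximal", "distal"):
        if col not in wide.columns:
            wide[col] = 0.0
    # a type contributes a paired observation in each slice where either
    # region contains it; slices where it is absent entirely are not paired
    present = wide[(wide["proximal"] > 0) | (wide["distal"] > 0)]
    rows = []
    for ctype, sub in present.groupby("cell_type"):
        if len(sub) < 2:
            warnings.warn(f"cell type {ctype!r} present in < 2 slices; dropped")
            continue
        diffs = (sub["proximal"] - sub["distal"]).to_numpy()
        t, df, p, degenerate = _paired_t(diffs)
        mean_diff = float(diffs.mean())
        rows.append(
            {
                "cell_type": ctype,
                "n_slices": len(sub),
                "mean_prox": float(sub["proximal"].mean()),
                "mean_dist": float(sub["distal"].mean()),
                "mean_diff": mean_diff,
                "t": t,
                "df": df,
                "p": p,
                "direction": "proximal-enriched" if mean_diff > 0 else "distal-enriched",
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).sort_values("cell_type").reset_index(drop=True)


def significant_enrichment(enrichment: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Reporting helper: rows with p < alpha, signed for heatmap display."""
    out = enrichment[enrichment["p"] < alpha].copy()
    out["signed_effect"] = np.where(out["mean_diff"] > 0, 1, -1) * -np.log10(
        np.maximum(out["p"], np.finfo(float).tiny)
    )
    return out.reset_index(drop=True)
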