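"""Synthetic multi-slice spatial single-cell data with planted structure.

Every analysis stage in the package has a ground-truth test bed generated
here:

* :func:`simulate_collection` — multi-slice spatial cell maps (Thomas-style
  clustered anchor types; attraction/repulsion rules between types) with
  negative-binomial expression and planted per-type marker genes;
* :func:`simulate_regulon_activity` — regulon × cell activity with planted
  cell-type-specific regulons;
* :func:`simulate_ranked_lists` — families of ranked lists with planted
  consensus items;
* :func:`simulate_bulk_cohort` — bulk expression cohorts with a planted
  group effect on a signature.

All generators are pure functions of (config, seed); per-slice randomness
uses spawned substreams so adding slices does not perturb earlier ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_io import CellMap, ExpressionMatrix
from .rank_aggregation import RankedLists
from .regulon_specificity import RegulonActivityMatrix

__all__ = [
    "SpatialRule",
    "SimulationConfig",
    "GroundTruth",
    "simulate_collection",
    "simulate_regulon_activity",
    "simulate_ranked_lists",
    "simulate_bulk_cohort",
]


@dataclass(frozen=True)
class SpatialRule:
    """Placement rule: ``subject`` cells positioned relative to ``target``.

    ``mode`` is attract / repel / neutral; ``strength`` ∈ [0, ∞) controls the
    probability of rule-guided placement (attract) or the steepness of the
    distance-dependent acceptance (repel); ``range`` is in field length
    units (attract: Gaussian offset sd; repel: acceptance length scale).
    """

    subject: str
    target: str
    mode: str  # attract | repel | neutral
    strength: float = 1.0
    range: float = 20.0

    def __post_init__(self) -> None:
        if self.mode not in ("attract", "repel", "neutral"):
            raise ValueError(f"unknown rule mode {self.mode!r}")
        if self.strength < 0:
            raise ValueError("rule strength must be >= 0")
        if self.range <= 0:
            raise ValueError("rule range must be > 0")


@dataclass
class SimulationConfig:
    """Study conditions for the spatial collection generator.

    Defaults emulate a small multi-slice atlas: 10 tissue slices of a
    1000×1000 field with ~500 cells each, four cell types, clustered
    anchors (Thomas process), NB counts with 200 genes and 5 planted
    markers per type at a 4-fold (2 log2) effect.
    """

    n_slices: int = 10
    cell_types: dict[str, float] = field(
        default_factory=lambda: {"mCAF": 0.25, "endothelial": 0.25, "epithelial": 0.25, "Tcell": 0.25}
    )
    field_size: tuple[float, float] = (1000.0, 1000.0)
    spatial_rules: list[SpatialRule] = field(default_factory=list)
    cells_per_slice: int = 500
    cluster_centers: float = 4.0  # Poisson mean of Thomas cluster centers per type
    cluster_sd: float = 60.0
    n_genes: int = 200
    markers_per_type: int = 5
    marker_log2_effect: float = 2.0
    nb_dispersion: float = 2.0  # NB shape theta: var = mu + mu^2/theta
    baseline_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.cell_types.values()) - 1.0) > 1e-6:
            raise ValueError("cell-type abundance weights must sum to 1")
        for name, count in (
            ("n_slices", self.n_slices),
            ("cells_per_slice", self.cells_per_slice),
            ("n_genes", self.n_genes),
            ("markers_per_type", self.markers_per_type),
        ):
            if count <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("nb_dispersion and baseline_mean must be positive")
        types = set(self.cell_types)
        for rule in self.spatial_rules:
            if rule.subject not in types or rule.target not in types:
                raise ValueError(
                    f"spatial rule references absent type: {rule.subject!r} -> {rule.target!r}"
                )
        if self.markers_per_type * len(self.cell_types) > self.n_genes:
            raise ValueError("not enough genes for the requested markers per type")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        rules = [
            r if isinstance(r, SpatialRule) else SpatialRule(**r)
            for r in data.pop("spatial_rules", [])
        ]
        if "field_size" in data:
            data["field_size"] = tuple(data["field_size"])
        return cls(spatial_rules=rules, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class GroundTruth:
    """Planted structure underlying a simulated dataset."""

    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    cluster_centers: dict[str, dict[str, list[list[float]]]] = field(default_factory=dict)
    realized_rules: list[dict] = field(default_factory=list)
    regulon_targets: dict[str, str] = field(default_factory=dict)
    bulk_groups: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _place_uniform(rng: np.random.Generator, n: int, field: tuple[float, float]) -> np.ndarray:
    return rng.uniform((0.0, 0.0), field, size=(n, 2))


def _place_thomas(
    rng: np.random.Generator, n: int, field: tuple[float, float], centers_mean: float, sd: float
) -> tuple[np.ndarray, np.ndarray]:
    n_centers = max(1, rng.poisson(centers_mean))
    centers = _place_uniform(rng, n_centers, field)
    assignment = rng.integers(0, n_centers, size=n)
    pos = centers[assignment] + rng.normal(0.0, sd, size=(n, 2))
    return np.clip(pos, (0.0, 0.0), field), centers


def _place_attract(
    rng: np.random.Generator,
    n: int,
    field: tuple[float, float],
    targets: np.ndarray,
    strength: float,
    offset_sd: float,
) -> np.ndarray:
    pos = _place_uniform(rng, n, field)
    guided = rng.random(n) < min(strength, 1.0)
    n_guided = int(guided.sum())
    if n_guided and len(targets):
        anchor = targets[rng.integers(0, len(targets), size=n_guided)]
        pos[guided] = anchor + rng.normal(0.0, offset_sd, size=(n_guided, 2))
    return np.clip(pos, (0.0, 0.0), field)


def _place_repel(
    rng: np.random.Generator,
    n: int,
    field: tuple[float, float],
    targets: np.ndarray,
    strength: float,
    scale: float,
    max_tries: int = 50,
) -> np.ndarray:
    """Rejection sampling with acceptance (1 − exp(−d/scale))^strength."""
    if strength == 0 or len(targets) == 0:
        return _place_uniform(rng, n, field)
    out = np.empty((n, 2))
    for i in range(n):
        best, best_d = None, -1.0
        for _ in range(max_tries):
            cand = rng.uniform((0.0, 0.0), field)
            d = float(np.sqrt(((targets - cand) ** 2).sum(axis=1)).min())
            if d > best_d:
                best, best_d = cand, d
            accept = (1.0 - math.exp(-d / scale)) ** strength
            if rng.random() < accept:
                best = cand
                break
        out[i] = best
    return out


def simulate_collection(
    cfg: SimulationConfig,
) -> tuple[CellMap, ExpressionMatrix, GroundTruth]:
    """Generate a multi-slice spatial cell map with NB expression.

    Per slice: anchor types (those not subject to any rule) are placed by a
    Thomas-style cluster process; rule subjects follow their rule (attract:
    Gaussian offset from a random target cell with probability ``strength``,
    else uniform; repel: rejection sampling with acceptance increasing in
    distance to the nearest target cell; neutral: uniform).  Counts are
    negative binomial (Gamma–Poisson, shape ``nb_dispersion``) with each
    type's marker genes scaled by 2^marker_log2_effect within that type.
    """
    types = list(cfg.cell_types)
    weights = np.array([cfg.cell_types[t] for t in types])
    rules_by_subject = {r.subject: r for r in cfg.spatial_rules}
    placement_order = [t for t in types if t not in rules_by_subject] + [
        t for t in types if t in rules_by_subject
    ]

    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    truth = GroundTruth()
    gene_cursor = 0
    marker_idx: dict[str, np.ndarray] = {}
    for t in types:
        idx = np.arange(gene_cursor, gene_cursor + cfg.markers_per_type)
        marker_idx[t] = idx
        truth.marker_genes[t] = [genes[i] for i in idx]
        gene_cursor += cfg.markers_per_type

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_slices + 1)
    expr_rng = np.random.default_rng(streams[-1])

    records = []
    for si in range(cfg.n_slices):
        rng = np.random.default_rng(streams[si])
        sid = f"slice{si + 1:02d}"
        counts = rng.multinomial(cfg.cells_per_slice, weights)
        positions: dict[str, np.ndarray] = {}
        truth.cluster_centers[sid] = {}
        for t, n_t in zip(types, counts):
            if t in rules_by_subject or n_t == 0:
                continue
            pos, centers = _place_thomas(
                rng, n_t, cfg.field_size, cfg.cluster_centers, cfg.cluster_sd
            )
            positions[t] = pos
            truth.cluster_centers[sid][t] = centers.tolist()
        for t in placement_order:
            n_t = counts[types.index(t)]
            if t in positions or n_t == 0:
                if n_t == 0:
                    positions[t] = np.empty((0, 2))
                continue
            rule = rules_by_subject[t]
            targets = positions.get(rule.target, np.empty((0, 2)))
            if rule.mode == "attract":
                positions[t] = _place_attract(
                    rng, n_t, cfg.field_size, targets, rule.strength, rule.range
                )
            elif rule.mode == "repel":
                positions[t] = _place_repel(
                    rng, n_t, cfg.field_size, targets, rule.strength, rule.range
                )
            else:
                positions[t] = _place_uniform(rng, n_t, cfg.field_size)
            truth.realized_rules.append(
                {"slice": sid, **asdict(rule), "n_subject": int(n_t), "n_target": len(targets)}
            )
        cell_counter = 0
        for t in types:
            for x, y in positions[t]:
                cell_counter += 1
                records.append(
                    {
                        "cell_id": f"{sid}_c{cell_counter:05d}",
                        "slice_id": sid,
                        "x": float(x),
                        "y": float(y),
                        "cell_type": t,
                    }
                )
    cell_map = CellMap(pd.DataFrame.from_records(records))

    # expression: NB counts with planted marker effects
    n_cells = cell_map.n_cells
    mu = np.full((cfg.n_genes, n_cells), cfg.baseline_mean)
    type_labels = cell_map.table["cell_type"].to_numpy()
    fold = 2.0**cfg.marker_log2_effect
    for t in types:
        in_type = type_labels == t
        if in_type.any():
            mu[np.ix_(marker_idx[t], in_type)] *= fold
    theta = cfg.nb_dispersion
    lam = expr_rng.gamma(shape=theta, scale=mu / theta)
    counts_mat = expr_rng.poisson(lam)
    expr = ExpressionMatrix(
        pd.DataFrame(counts_mat, index=genes, columns=cell_map.table["cell_id"]),
        units="counts",
    )
    return cell_map, expr, truth


def simulate_regulon_activity(
    n_regulons: int,
    cell_types: Sequence[str],
    cells_per_type: int,
    specificity: float,
    seed: int = 0,
    concentration: float = 10.0,
) -> tuple[RegulonActivityMatrix, dict[str, str]]:
    """Regulon × cell activity with planted cell-type-specific regulons.

    Regulon i targets cell type i mod n_types (round-robin).  Activity is
    Beta-distributed with mean ``specificity`` in target-type cells and mean
    ``(1 − specificity) · 0.2`` elsewhere (degenerate means 0/1 are emitted
    exactly).  Returns the matrix and the planted regulon → type mapping.
    """
    if not 0 <= specificity <= 1:
        raise ValueError("specificity must be in [0, 1]")
    types = list(cell_types)
    if n_regulons < len(types):
        raise ValueError("need at least one regulon per cell type")
    rng = np.random.default_rng(seed)
    cells = [f"{t}_c{i:04d}" for t in types for i in range(1, cells_per_type + 1)]
    labels = pd.Series(
        [t for t in types for _ in range(cells_per_type)], index=cells, dtype=str
    )
    regulons = [f"R{i:03d}" for i in range(1, n_regulons + 1)]
    targets = {reg: types[i % len(types)] for i, reg in enumerate(regulons)}

    def draw(mean: float, size: int) -> np.ndarray:
        if mean <= 0:
            return np.zeros(size)
        if mean >= 1:
            return np.ones(size)
        a = mean * concentration
        b = (1.0 - mean) * concentration
        return rng.beta(a, b, size=size)

    off_mean = (1.0 - specificity) * 0.2
    activity = np.empty((n_regulons, len(cells)))
    for ri, reg in enumerate(regulons):
        in_target = (labels == targets[reg]).to_numpy()
        activity[ri, in_target] = draw(specificity, int(in_target.sum()))
        activity[ri, ~in_target] = draw(off_mean, int((~in_target).sum()))
    ras = RegulonActivityMatrix(
        pd.DataFrame(activity, index=regulons, columns=cells), labels
    )
    return ras, targets


def simulate_ranked_lists(
    n_lists: int,
    universe_size: int,
    planted_items: Mapping[str, float],
    seed: int = 0,
) -> RankedLists:
    """Ranked-list family with planted consensus items.

    The universe consists of the planted item names plus filler items
    ("item0001", ...).  A planted item with consensus strength s draws its
    position in each list uniformly from the first max(1, ⌈(1−s)·U⌉) free
    slots; fillers fill the remaining slots uniformly.
    """
    for item, s in planted_items.items():
        if not 0 <= s <= 1:
            raise ValueError(f"consensus strength for {item!r} must be in [0, 1]")
    if len(planted_items) > universe_size:
        raise ValueError("more planted items than universe slots")
    planted = list(planted_items)
    fillers = []
    i = 0
    while len(planted) + len(fillers) < universe_size:
        i += 1
        name = f"item{i:04d}"
        if name not in planted_items:
            fillers.append(name)
    universe = planted + fillers
    rng = np.random.default_rng(seed)
    lists: dict[str, list[str]] = {}
    for li in range(n_lists):
        slots: list[str | None] = [None] * universe_size
        # strongest items placed first so their windows are least constrained
        for item in sorted(planted, key=lambda it: -planted_items[it]):
            window = max(1, math.ceil((1.0 - planted_items[item]) * universe_size))
            free = [p for p in range(window) if slots[p] is None]
            if not free:
                free = [p for p in range(universe_size) if slots[p] is None][:1]
            slots[free[rng.integers(0, len(free))]] = item
        remaining = [p for p in range(universe_size) if slots[p] is None]
        shuffled = list(rng.permutation(fillers))
        for p, item in zip(remaining, shuffled):
            slots[p] = item
        lists[f"list{li + 1:03d}"] = [s for s in slots if s is not None]
    return RankedLists(universe=sorted(universe), lists=lists)


def simulate_bulk_cohort(
    n_samples: int,
    n_genes: int,
    signature: Sequence[str],
    group_effect_log2: float,
    seed: int = 0,
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.5,
    noise_sd: float = 1.0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Bulk cohort (log-scale expression) with a planted group effect.

    Genes are named "G0001"... as in :func:`simulate_collection`; the
    signature must be a subset of that universe.  Half the samples form the
    "high" group, in which signature genes are shifted by
    ``group_effect_log2``; values are clipped at 0 so the matrix stays
    non-negative on the log scale.
    """
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    missing = [g for g in signature if g not in set(genes)]
    if missing:
        raise ValueError(f"signature gene(s) outside the simulated universe: {missing[:5]}")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    groups = np.array(["low"] * n_samples, dtype=object)
    high_idx = rng.choice(n_samples, size=n_samples // 2, replace=False)
    groups[high_idx] = "high"
    base = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    values = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    sig_rows = [genes.index(g) for g in signature]
    values[np.ix_(sig_rows, high_idx)] += group_effect_log2
    values = np.clip(values, 0.0, None)
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), units="log")
    return expr, pd.Series(groups, index=samples, name="group")
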