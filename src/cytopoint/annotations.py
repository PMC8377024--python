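"""Centre-point annotation data model, I/O, consensus merging and class sizes.

A single expert click marks the centre of a whole cell (not the nucleus) and
assigns one of four immune cell classes. Multiple assessors annotate the same
tile; their clicks are merged into a consensus set by clustering points that
fall within a dedup radius of each other and taking a majority vote on the
class of each cluster.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError, PreconditionError, SchemaError, ValidationError

#: Canonical cell classes, in fixed channel order.
CELL_CLASSES: tuple[str, ...] = (
    "macrophage_lineage",
    "neutrophil",
    "eosinophil",
    "lymphocyte",
)

#: Default reference diameters (px at native 1024-px tile scale), per-class
#: medians of manual longest-span measurements.
DEFAULT_DIAMETERS_PX: dict[str, float] = {
    "macrophage_lineage": 142.0,
    "neutrophil": 104.0,
    "eosinophil": 126.0,
    "lymphocyte": 61.0,
}

CONSENSUS_ASSESSOR = "consensus"

_CSV_COLUMNS = ["tile_id", "x", "y", "cell_class", "assessor_id"]


@dataclass(frozen=True)
class CentreAnnotation:
    """One expert click: tile, (x, y) in native px, cell class, assessor."""

    tile_id: str
    x: float
    y: float
    cell_class: str
    assessor_id: str


@dataclass
class AnnotationSet:
    """All annotations of one assessor (or the consensus) on one tile.

    Coordinates are 0-based, x rightwards, y downwards, sub-pixel values
    permitted; every annotation must lie inside ``[0, width) x [0, height)``.
    """

    tile_id: str
    tile_width: int
    tile_height: int
    annotations: list[CentreAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ann in self.annotations:
            self._check(ann)

    def _check(self, ann: CentreAnnotation) -> None:
        if ann.tile_id != self.tile_id:
            raise ValidationError(
                f"annotation tile_id {ann.tile_id!r} != set tile_id {self.tile_id!r}"
            )
        if not (0 <= ann.x < self.tile_width and 0 <= ann.y < self.tile_height):
            raise ValidationError(
                f"annotation ({ann.x}, {ann.y}) outside tile "
                f"{self.tile_width}x{self.tile_height} on {self.tile_id!r}"
            )

    def add(self, ann: CentreAnnotation) -> None:
        self._check(ann)
        self.annotations.append(ann)

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    def counts_by_class(self) -> Counter:
        return Counter(a.cell_class for a in self.annotations)


@dataclass(frozen=True)
class ClassConfig:
    """Per-class reference diameter and Gaussian spread, in native px."""

    cell_class: str
    diameter_px: float
    sigma_px: float

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ConfigError(f"{self.cell_class}: diameter_px must be > 0")
        if self.sigma_px <= 0:
            raise ConfigError(f"{self.cell_class}: sigma_px must be > 0")


def default_class_configs(
    classes: Sequence[str] = CELL_CLASSES,
    sigma_ratio: float = 0.5,
) -> list[ClassConfig]:
    """Class configs using the default median diameters; sigma = diameter/2."""
    return [
        ClassConfig(c, DEFAULT_DIAMETERS_PX[c], DEFAULT_DIAMETERS_PX[c] * sigma_ratio)
        for c in classes
    ]


@dataclass(frozen=True)
class ClusterResolution:
    """How one merged cluster of clicks was resolved."""

    members: tuple[CentreAnnotation, ...]
    class_votes: Mapping[str, int]
    resolution: str  # "majority" | "flagged_tie"


@dataclass
class ConsensusResult:
    """Consensus annotation set plus the per-cluster audit trail.

    The per-assessor input sets are retained so downstream agreement (ICC)
    and human-baseline AP can be computed against the consensus.
    """

    consensus: AnnotationSet
    conflicts: list[ClusterResolution]
    assessor_sets: list[AnnotationSet]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_annotations(
    path: str | Path,
    tile_width: int = 1024,
    tile_height: int = 1024,
    classes: Sequence[str] = CELL_CLASSES,
) -> list[AnnotationSet]:
    """Read an annotation table into one ``AnnotationSet`` per (tile, assessor).

    Accepts CSV with header ``tile_id,x,y,cell_class,assessor_id`` or an
    equivalent JSON array of records. Row order is preserved within each set.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        df = pd.DataFrame.from_records(records, columns=_CSV_COLUMNS if not records else None)
    else:
        df = pd.read_csv(path)
    return annotations_from_frame(df, tile_width, tile_height, classes)


def annotations_from_frame(
    df: pd.DataFrame,
    tile_width: int = 1024,
    tile_height: int = 1024,
    classes: Sequence[str] = CELL_CLASSES,
) -> list[AnnotationSet]:
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table missing column(s): {', '.join(missing)}")
    sets: dict[tuple[str, str], AnnotationSet] = {}
    class_set = set(classes)
    for i, row in enumerate(df.itertuples(index=False)):
        cell_class = str(row.cell_class)
        if cell_class not in class_set:
            raise ValidationError(f"row {i}: unknown cell class {cell_class!r}")
        x, y = float(row.x), float(row.y)
        if not (0 <= x < tile_width and 0 <= y < tile_height):
            raise ValidationError(
                f"row {i}: coordinates ({x}, {y}) outside tile bounds "
                f"{tile_width}x{tile_height}"
            )
        key = (str(row.tile_id), str(row.assessor_id))
        if key not in sets:
            sets[key] = AnnotationSet(key[0], tile_width, tile_height)
        sets[key].add(CentreAnnotation(key[0], x, y, cell_class, key[1]))
    return list(sets.values())


def annotations_to_frame(sets: Iterable[AnnotationSet]) -> pd.DataFrame:
    rows = [
        (a.tile_id, a.x, a.y, a.cell_class, a.assessor_id)
        for s in sets
        for a in s
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_annotations(sets: Iterable[AnnotationSet], path: str | Path) -> None:
    annotations_to_frame(sets).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def _cluster_single_linkage(xy: np.ndarray, radius: float) -> np.ndarray:
    """Connected components of the pairwise ``distance <= radius`` graph."""
    n = len(xy)
    if n == 1:
        return np.zeros(1, dtype=int)
    dm = squareform(pdist(xy)) <= radius
    graph = coo_matrix(dm)
    _, labels = connected_components(graph, directed=False)
    return labels


def _cluster_greedy(xy: np.ndarray, radius: float) -> np.ndarray:
    """Nearest-first greedy: each point joins the first existing cluster whose
    running centroid lies within ``radius``, else starts a new cluster."""
    labels = np.full(len(xy), -1, dtype=int)
    centroids: list[np.ndarray] = []
    sizes: list[int] = []
    for i, p in enumerate(xy):
        best, best_d = -1, math.inf
        for j, c in enumerate(centroids):
            d = float(np.hypot(*(p - c)))
            if d <= radius and d < best_d:
                best, best_d = j, d
        if best < 0:
            centroids.append(p.astype(float).copy())
            sizes.append(1)
            labels[i] = len(centroids) - 1
        else:
            labels[i] = best
            centroids[best] = (centroids[best] * sizes[best] + p) / (sizes[best] + 1)
            sizes[best] += 1
    return labels


def consolidate_consensus(
    sets: Sequence[AnnotationSet],
    dedup_radius: float = 10.0,
    linkage: str = "single",
) -> ConsensusResult:
    """Merge >= 2 assessor sets for one tile into a consensus set.

    Points from all assessors are clustered by proximity (default:
    single-linkage connected components of the ``distance <= dedup_radius``
    graph). Each cluster emits one consensus annotation at the centroid of
    its members carrying the majority class; tied votes are never
    auto-resolved and are flagged for expert review.
    """
    if len(sets) < 2:
        raise PreconditionError("consensus requires at least 2 assessor sets")
    if dedup_radius <= 0:
        raise ConfigError("dedup_radius must be > 0")
    tile_ids = {s.tile_id for s in sets}
    if len(tile_ids) != 1:
        raise ValidationError(f"mismatched tile ids: {sorted(tile_ids)}")
    tile_id = sets[0].tile_id
    width, height = sets[0].tile_width, sets[0].tile_height

    annotations = [a for s in sets for a in s]
    consensus = AnnotationSet(tile_id, width, height)
    conflicts: list[ClusterResolution] = []
    if annotations:
        xy = np.array([(a.x, a.y) for a in annotations], dtype=float)
        if linkage == "single":
            labels = _cluster_single_linkage(xy, dedup_radius)
        elif linkage == "greedy":
            labels = _cluster_greedy(xy, dedup_radius)
        else:
            raise ConfigError(f"unknown linkage {linkage!r}")
        order: dict[int, int] = {}
        clusters: list[list[int]] = []
        for i, lab in enumerate(labels):
            if lab not in order:
                order[lab] = len(clusters)
                clusters.append([])
            clusters[order[lab]].append(i)
        for member_idx in clusters:
            members = tuple(annotations[i] for i in member_idx)
            votes = Counter(a.cell_class for a in members)
            top = votes.most_common()
            tie = len(top) > 1 and top[0][1] == top[1][1]
            # on a tie the channel-order-first class is carried, but the
            # cluster is flagged rather than treated as resolved
            winner = min(
                (c for c, v in votes.items() if v == top[0][1]),
                key=lambda c: CELL_CLASSES.index(c) if c in CELL_CLASSES else len(CELL_CLASSES),
            )
            cx = float(np.mean([a.x for a in members]))
            cy = float(np.mean([a.y for a in members]))
            cx = min(cx, math.nextafter(width, 0.0))
            cy = min(cy, math.nextafter(height, 0.0))
            consensus.add(CentreAnnotation(tile_id, cx, cy, winner, CONSENSUS_ASSESSOR))
            conflicts.append(
                ClusterResolution(members, dict(votes), "flagged_tie" if tie else "majority")
            )
    return ConsensusResult(consensus, conflicts, list(sets))


# ---------------------------------------------------------------------------
# Class-size configuration
# ---------------------------------------------------------------------------

def compute_class_config(
    measurements: pd.DataFrame | Sequence[tuple[str, float]],
    classes: Sequence[str] = CELL_CLASSES,
    sigma_ratio: float = 0.5,
) -> list[ClassConfig]:
    """Derive per-class reference sizes from manual diameter measurements.

    ``diameter_px`` is the per-class median of the measured longest spans and
    ``sigma_px = sigma_ratio * diameter_px`` (default: half the diameter, i.e.
    the class radius).
    """
    if not isinstance(measurements, pd.DataFrame):
        measurements = pd.DataFrame(measurements, columns=["cell_class", "diameter_px"])
    if not {"cell_class", "diameter_px"} <= set(measurements.columns):
        raise SchemaError("measurements need columns cell_class, diameter_px")
    configs = []
    for c in classes:
        values = measurements.loc[measurements["cell_class"] == c, "diameter_px"]
        if values.empty:
            raise ValidationError(f"no diameter measurements for class {c!r}")
        med = float(values.median())
        configs.append(ClassConfig(c, med, sigma_ratio * med))
    return configs


def load_class_config(path: str | Path) -> list[ClassConfig]:
    """Read a YAML mapping ``class -> {diameter_px, sigma_px}``."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, Mapping):
        raise SchemaError("class config must be a mapping of class -> sizes")
    configs = []
    for name, entry in data.items():
        try:
            configs.append(
                ClassConfig(str(name), float(entry["diameter_px"]), float(entry["sigma_px"]))
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"class {name!r}: expected diameter_px and sigma_px") from exc
    return configs


def save_class_config(configs: Sequence[ClassConfig], path: str | Path) -> None:
    data = {
        c.cell_class: {"diameter_px": c.diameter_px, "sigma_px": c.sigma_px}
        for c in configs
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def scale_class_configs(configs: Sequence[ClassConfig], factor: float) -> list[ClassConfig]:
    """Rescale diameters/sigmas, e.g. when generating smaller synthetic tiles."""
    return [
        replace(c, diameter_px=c.diameter_px * factor, sigma_px=c.sigma_px * factor)
        for c in configs
    ]


def class_config_map(configs: Sequence[ClassConfig]) -> dict[str, ClassConfig]:
    m = {c.cell_class: c for c in configs}
    if len(m) != len(configs):
        raise ConfigError("duplicate class in class config")
    return m
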