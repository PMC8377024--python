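"""Detection evaluation and agreement statistics.

Predicted centres are matched to ground-truth centres of the same class when
they lie within ``delta * class diameter``; matched pairs are true positives,
the rest false positives / false negatives. AP is the area under the
interpolated precision-recall curve over score-ranked pooled predictions.
ICC(A,1) (two-way, absolute agreement, single rater) quantifies
inter-assessor agreement on per-tile counts, and differential counts carry
the categorical determinations (>3% eosinophils, >61% neutrophils).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .annotations import AnnotationSet, CentreAnnotation, ClassConfig, class_config_map
from .errors import ConfigError, PreconditionError, ValidationError
from .heatmap import Prediction

DEFAULT_DELTAS = (0.1, 0.25, 0.5)
TOTAL_CLASS = "total_immune_cell"


@dataclass
class EvalConfig:
    deltas: tuple[float, ...] = DEFAULT_DELTAS
    matching: str = "greedy"  # or "optimal"

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.deltas):
            raise ConfigError("all deltas must be > 0")


@dataclass
class MatchResult:
    """TP/FP/FN decomposition of one tile's predictions at one delta."""

    delta: float
    true_positives: list[tuple[Prediction, CentreAnnotation, float]] = field(
        default_factory=list
    )
    false_positives: list[Prediction] = field(default_factory=list)
    false_negatives: list[CentreAnnotation] = field(default_factory=list)

    def counts(self, cell_class: str | None = None) -> tuple[int, int, int]:
        if cell_class is None:
            return (
                len(self.true_positives),
                len(self.false_positives),
                len(self.false_negatives),
            )
        tp = sum(1 for p, _, _ in self.true_positives if p.cell_class == cell_class)
        fp = sum(1 for p in self.false_positives if p.cell_class == cell_class)
        fn = sum(1 for g in self.false_negatives if g.cell_class == cell_class)
        return tp, fp, fn


@dataclass
class DifferentialCount:
    counts: dict[str, int]
    percentages: dict[str, float] | None
    eosinophilic: bool | None  # eosinophil % > 3
    neutrophilic: bool | None  # neutrophil % > 61


def match_centres(
    predictions: Sequence[Prediction],
    ground_truth: AnnotationSet,
    delta: float,
    classes: Sequence[ClassConfig],
    method: str = "greedy",
    class_agnostic: bool = False,
) -> MatchResult:
    """Match predictions to unmatched ground truths within the delta radius.

    Greedy (default): per class, predictions in descending score order (ties:
    input order) each claim the nearest unmatched ground truth of the same
    class within ``delta * diameter_px``. ``method="optimal"`` instead solves
    the maximum-cardinality assignment (minimum total distance among maximum
    matchings). ``class_agnostic=True`` pools all classes into one, using each
    ground truth's own class diameter for its radius (total-immune-cell
    evaluation).
    """
    if delta <= 0:
        raise ConfigError("delta must be > 0")
    if method not in ("greedy", "optimal"):
        raise ConfigError(f"unknown matching method {method!r}")
    cfg = class_config_map(classes)
    result = MatchResult(delta=delta)
    if class_agnostic:
        groups: Iterable[str | None] = [None]
    else:
        groups = [c.cell_class for c in classes]
    for group in groups:
        preds = [
            (i, p)
            for i, p in enumerate(predictions)
            if group is None or p.cell_class == group
        ]
        gts = [g for g in ground_truth if group is None or g.cell_class == group]
        radii = np.array([delta * cfg[g.cell_class].diameter_px for g in gts])
        if not preds and not gts:
            continue
        dist = np.full((len(preds), len(gts)), np.inf)
        for r, (_, p) in enumerate(preds):
            for c, g in enumerate(gts):
                d = float(np.hypot(p.x - g.x, p.y - g.y))
                if d <= radii[c]:
                    dist[r, c] = d
        if method == "greedy":
            matched = _greedy_match(preds, dist)
        else:
            matched = _optimal_match(dist)
        gt_taken = set()
        for r, (_, p) in enumerate(preds):
            c = matched.get(r)
            if c is None:
                result.false_positives.append(p)
            else:
                result.true_positives.append((p, gts[c], float(dist[r, c])))
                gt_taken.add(c)
        for c, g in enumerate(gts):
            if c not in gt_taken:
                result.false_negatives.append(g)
    return result


def _greedy_match(preds, dist) -> dict[int, int]:
    order = sorted(range(len(preds)), key=lambda r: (-preds[r][1].score, preds[r][0]))
    taken: set[int] = set()
    out: dict[int, int] = {}
    for r in order:
        cands = [(dist[r, c], c) for c in range(dist.shape[1]) if c not in taken
                 and np.isfinite(dist[r, c])]
        if cands:
            _, c = min(cands)
            out[r] = c
            taken.add(c)
    return out


def _optimal_match(dist) -> dict[int, int]:
    """Maximum-cardinality assignment, breaking ties by total distance."""
    if dist.size == 0:
        return {}
    finite = dist[np.isfinite(dist)]
    big = (float(finite.max()) if finite.size else 1.0) * dist.size + 1.0
    cost = np.where(np.isfinite(dist), dist, big)
    rows, cols = linear_sum_assignment(cost)
    return {int(r): int(c) for r, c in zip(rows, cols) if np.isfinite(dist[r, c])}


# ---------------------------------------------------------------------------
# AP / F1
# ---------------------------------------------------------------------------

def average_precision(
    matches: Sequence[MatchResult],
    cell_class: str | None = None,
) -> float | None:
    """AP over pooled, score-ranked predictions from a set of tiles.

    Area under the interpolated precision-recall curve (precision at each
    recall level is the maximum precision at any recall >= it). When every
    prediction carries the same score — human assessors — the ranking is
    uninformative and AP reduces to precision x recall at the single
    operating point. Returns None when there is no ground truth of the class.
    """
    scored: list[tuple[float, bool]] = []
    n_gt = 0
    for m in matches:
        for p, _, _ in m.true_positives:
            if cell_class is None or p.cell_class == cell_class:
                scored.append((p.score, True))
        for p in m.false_positives:
            if cell_class is None or p.cell_class == cell_class:
                scored.append((p.score, False))
        n_gt += sum(
            1
            for p, g, _ in m.true_positives
            if cell_class is None or g.cell_class == cell_class
        )
        n_gt += sum(
            1
            for g in m.false_negatives
            if cell_class is None or g.cell_class == cell_class
        )
    if n_gt == 0:
        return None
    if not scored:
        return 0.0
    scores = np.array([s for s, _ in scored])
    flags = np.array([t for _, t in scored])
    if np.all(scores == scores[0]):
        tp = int(flags.sum())
        precision = tp / len(flags)
        recall = tp / n_gt
        return float(precision * recall)
    order = np.argsort(-scores, kind="stable")
    tp_cum = np.cumsum(flags[order])
    fp_cum = np.cumsum(~flags[order])
    precision = tp_cum / (tp_cum + fp_cum)
    recall = tp_cum / n_gt
    return _pr_area(precision, recall)


def _pr_area(precision: np.ndarray, recall: np.ndarray) -> float:
    """Interpolated PR area: sum over recall steps of max precision beyond."""
    # max precision at any recall >= r
    interp = np.maximum.accumulate(precision[::-1])[::-1]
    area = 0.0
    prev_r = 0.0
    for p, r in zip(interp, recall):
        if r > prev_r:
            area += (r - prev_r) * p
            prev_r = r
    return float(area)


def f1_at(match: MatchResult, cell_class: str | None = None) -> float:
    """F1 = 2TP / (2TP + FP + FN); 0 when the denominator is 0."""
    tp, fp, fn = match.counts(cell_class)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def _f1_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def evaluate_detections(
    predictions_by_tile: Mapping[str, Sequence[Prediction]],
    truth_by_tile: Mapping[str, AnnotationSet],
    classes: Sequence[ClassConfig],
    config: EvalConfig | None = None,
) -> pd.DataFrame:
    """Full evaluation report: per class x delta AP/precision/recall/F1/counts.

    A ``total_immune_cell`` row per delta re-matches all points class-
    agnostically. Returns a flat frame with columns
    (cell_class, delta, AP, precision, recall, F1, TP, FP, FN).
    """
    config = config or EvalConfig()
    rows = []
    for delta in config.deltas:
        matches = []
        matches_total = []
        for tile_id, truth in truth_by_tile.items():
            preds = list(predictions_by_tile.get(tile_id, []))
            matches.append(
                match_centres(preds, truth, delta, classes, method=config.matching)
            )
            matches_total.append(
                match_centres(preds, truth, delta, classes, method=config.matching,
                              class_agnostic=True)
            )
        for c in classes:
            name = c.cell_class
            tp = sum(m.counts(name)[0] for m in matches)
            fp = sum(m.counts(name)[1] for m in matches)
            fn = sum(m.counts(name)[2] for m in matches)
            ap = average_precision(matches, name)
            rows.append(_report_row(name, delta, ap, tp, fp, fn))
        tp = sum(m.counts()[0] for m in matches_total)
        fp = sum(m.counts()[1] for m in matches_total)
        fn = sum(m.counts()[2] for m in matches_total)
        ap = average_precision(matches_total, None)
        rows.append(_report_row(TOTAL_CLASS, delta, ap, tp, fp, fn))
    return pd.DataFrame(rows)


def _report_row(name, delta, ap, tp, fp, fn) -> dict:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {
        "cell_class": name,
        "delta": delta,
        "AP": ap,
        "precision": precision,
        "recall": recall,
        "F1": _f1_from_counts(tp, fp, fn),
        "TP": tp,
        "FP": fp,
        "FN": fn,
    }


def assessor_predictions(assessor_set: AnnotationSet) -> list[Prediction]:
    """View a raw assessor's annotations as a uniform-score prediction set."""
    return [
        Prediction(a.x, a.y, a.cell_class, score=1.0, tile_id=a.tile_id)
        for a in assessor_set
    ]


# ---------------------------------------------------------------------------
# ICC(A,1)
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_raters: int
    degenerate: bool = False


def icc_a1(ratings: np.ndarray | pd.DataFrame) -> ICCResult:
    """Two-way absolute-agreement single-rater ICC (McGraw-Wong ICC(A,1)).

    ``ratings`` is a subjects x raters matrix with no missing cells.
    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)).
    A constant matrix is degenerate and reported as ICC 1 with a flag.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValidationError("ratings must be a 2-D subjects x raters matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise PreconditionError("need >= 2 subjects and >= 2 raters")
    if np.isnan(m).any():
        raise ValidationError("ratings contain missing cells")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom <= 0:
        return ICCResult(1.0, ms_r, ms_c, ms_e, n, k, degenerate=True)
    return ICCResult(float((ms_r - ms_e) / denom), ms_r, ms_c, ms_e, n, k)


def icc_report(result: ICCResult) -> str:
    return json.dumps(
        {
            "ICC(A,1)": result.icc,
            "MS_rows": result.ms_rows,
            "MS_cols": result.ms_cols,
            "MS_error": result.ms_error,
            "n_subjects": result.n_subjects,
            "n_raters": result.n_raters,
            "degenerate": result.degenerate,
        }
    )


def per_tile_count_matrix(
    sets_by_tile: Mapping[str, Mapping[str, AnnotationSet]],
    cell_class: str | None = None,
) -> np.ndarray:
    """Subjects (tiles) x raters matrix of per-tile counts for ICC.

    ``sets_by_tile`` maps tile id -> assessor id -> that assessor's set.
    Missing (tile, assessor) cells count as zero annotations.
    """
    tiles = sorted(sets_by_tile)
    if not tiles:
        raise PreconditionError("no tiles")
    raters = sorted({a for by_assessor in sets_by_tile.values() for a in by_assessor})
    out = np.zeros((len(tiles), len(raters)))
    for i, t in enumerate(tiles):
        for j, r in enumerate(raters):
            s = sets_by_tile[t].get(r)
            if s is None:
                continue
            counts = s.counts_by_class()
            out[i, j] = (
                sum(counts.values()) if cell_class is None else counts.get(cell_class, 0)
            )
    return out


# ---------------------------------------------------------------------------
# Differential counts
# ---------------------------------------------------------------------------

EOSINOPHILIC_THRESHOLD_PCT = 3.0
NEUTROPHILIC_THRESHOLD_PCT = 61.0


def differential_count(
    points: AnnotationSet | Sequence[Prediction] | Sequence[CentreAnnotation],
    classes: Sequence[str] | None = None,
) -> DifferentialCount:
    """Per-class counts and percentages with categorical determinations.

    Flags use strict inequality: eosinophilic iff eosinophil % > 3,
    neutrophilic iff neutrophil % > 61. Zero points yields counts of zero
    with percentages and flags absent.
    """
    items = list(points)
    names = list(classes) if classes else None
    counts: dict[str, int] = {c: 0 for c in names} if names else {}
    for p in items:
        counts[p.cell_class] = counts.get(p.cell_class, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return DifferentialCount(counts, None, None, None)
    pct = {c: 100.0 * v / total for c, v in counts.items()}
    return DifferentialCount(
        counts,
        pct,
        eosinophilic=pct.get("eosinophil", 0.0) > EOSINOPHILIC_THRESHOLD_PCT,
        neutrophilic=pct.get("neutrophil", 0.0) > NEUTROPHILIC_THRESHOLD_PCT,
    )


# ---------------------------------------------------------------------------
# Dataset split
# ---------------------------------------------------------------------------

def dataset_split(
    cytospins: Mapping[str, Sequence[str]],
    holdout_ids: Sequence[str],
) -> tuple[list[str], list[str], dict]:
    """Split tiles by cytospin so no holdout-cytospin tile reaches training.

    Returns (train tiles, holdout tiles, report) where the report carries
    counts and percentages rounded to one decimal.
    """
    all_tiles: list[str] = []
    seen: set[str] = set()
    for cid, tiles in cytospins.items():
        for t in tiles:
            if t in seen:
                raise ValidationError(f"tile {t!r} appears in more than one cytospin")
            seen.add(t)
        all_tiles.extend(tiles)
    unknown = [h for h in holdout_ids if h not in cytospins]
    if unknown:
        raise ValidationError(f"unknown holdout cytospin id(s): {unknown}")
    holdout_set = set(holdout_ids)
    train = [t for cid, tiles in cytospins.items() if cid not in holdout_set for t in tiles]
    holdout = [t for cid in holdout_ids for t in cytospins[cid]]
    total = len(all_tiles)
    report = {
        "n_cytospins": len(cytospins),
        "n_holdout_cytospins": len(holdout_set),
        "n_tiles": total,
        "n_train": len(train),
        "n_holdout": len(holdout),
        "train_pct": round(100.0 * len(train) / total, 1) if total else 0.0,
        "holdout_pct": round(100.0 * len(holdout) / total, 1) if total else 0.0,
    }
    return train, holdout, report
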