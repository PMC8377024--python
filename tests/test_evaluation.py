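"""Matching, AP/F1, ICC(A,1), differential counts and dataset splitting."""

import numpy as np
import pytest

from cytopoint.annotations import CELL_CLASSES, ClassConfig
from cytopoint.errors import ConfigError, PreconditionError, ValidationError
from cytopoint.evaluation import (
    EvalConfig,
    MatchResult,
    average_precision,
    assessor_predictions,
    dataset_split,
    differential_count,
    evaluate_detections,
    f1_at,
    icc_a1,
    match_centres,
    per_tile_count_matrix,
)
from cytopoint.heatmap import Prediction

from conftest import make_set


def flat_classes(diameter=10.0):
    return [ClassConfig(c, diameter, diameter / 2) for c in CELL_CLASSES]


def max_tp_bruteforce(dist):
    """Exhaustive maximum-cardinality matching on a feasibility matrix."""
    n_pred, n_gt = dist.shape

    def best(r, used):
        if r == n_pred:
            return 0
        score = best(r + 1, used)  # leave prediction r unmatched
        for c in range(n_gt):
            if c not in used and np.isfinite(dist[r, c]):
                score = max(score, 1 + best(r + 1, used | {c}))
        return score

    return best(0, frozenset())


class TestMatching:
    def test_identical_points_all_tp(self):
        gt = make_set([(10, 10, "neutrophil"), (50, 50, "eosinophil")])
        preds = [
            Prediction(10, 10, "neutrophil", 0.9),
            Prediction(50, 50, "eosinophil", 0.8),
        ]
        m = match_centres(preds, gt, 0.5, flat_classes())
        assert m.counts() == (2, 0, 0)
        assert all(d == 0.0 for _, _, d in m.true_positives)

    def test_just_outside_threshold_is_fp_and_fn(self):
        radius = 0.5 * 10.0
        gt = make_set([(10, 10, "neutrophil")])
        preds = [Prediction(10 + 1.01 * radius, 10, "neutrophil", 0.9)]
        m = match_centres(preds, gt, 0.5, flat_classes())
        assert m.counts() == (0, 1, 1)

    def test_class_mismatch_never_matches(self):
        gt = make_set([(10, 10, "neutrophil")])
        preds = [Prediction(10, 10, "lymphocyte", 0.9)]
        m = match_centres(preds, gt, 0.5, flat_classes())
        assert m.counts() == (0, 1, 1)

    def test_class_agnostic_allows_cross_class(self):
        gt = make_set([(10, 10, "neutrophil")])
        preds = [Prediction(10, 10, "lymphocyte", 0.9)]
        m = match_centres(preds, gt, 0.5, flat_classes(), class_agnostic=True)
        assert m.counts() == (1, 0, 0)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ConfigError):
            match_centres([], make_set([]), 0.0, flat_classes())

    def test_each_side_matched_at_most_once(self):
        gt = make_set([(10, 10, "neutrophil")])
        preds = [
            Prediction(10, 10, "neutrophil", 0.9),
            Prediction(11, 10, "neutrophil", 0.8),
        ]
        m = match_centres(preds, gt, 0.5, flat_classes())
        assert m.counts() == (1, 1, 0)

    @pytest.mark.parametrize("method", ["greedy", "optimal"])
    def test_counts_conserve_inputs(self, method, rng):
        classes = flat_classes()
        for _ in range(20):
            gt_pts = [(x, y, CELL_CLASSES[int(rng.integers(4))])
                      for x, y in rng.uniform(0, 250, size=(int(rng.integers(0, 8)), 2))]
            preds = [
                Prediction(x, y, CELL_CLASSES[int(rng.integers(4))], float(rng.random()))
                for x, y in rng.uniform(0, 250, size=(int(rng.integers(0, 8)), 2))
            ]
            gt = make_set(gt_pts)
            m = match_centres(preds, gt, 0.5, classes, method=method)
            tp, fp, fn = m.counts()
            assert tp + fp == len(preds)
            assert tp + fn == len(gt_pts)

    def test_agrees_with_exhaustive_enumeration_oracle(self):
        """100 random scenes, <= 6 points per class: both matchers reach the
        enumerated maximum TP count (greedy verified scene by scene)."""
        rng = np.random.default_rng(42)
        classes = flat_classes(diameter=40.0)
        for scene in range(100):
            cls = "neutrophil"
            n_gt = int(rng.integers(0, 7))
            n_pred = int(rng.integers(0, 7))
            gt_pts = [(x, y, cls) for x, y in rng.uniform(0, 100, size=(n_gt, 2))]
            preds = [
                Prediction(x, y, cls, float(rng.random()))
                for x, y in rng.uniform(0, 100, size=(n_pred, 2))
            ]
            gt = make_set(gt_pts)
            radius = 0.5 * 40.0
            dist = np.full((n_pred, n_gt), np.inf)
            for r, p in enumerate(preds):
                for c, (x, y, _) in enumerate(gt_pts):
                    d = np.hypot(p.x - x, p.y - y)
                    if d <= radius:
                        dist[r, c] = d
            oracle_tp = max_tp_bruteforce(dist)
            opt_tp = match_centres(preds, gt, 0.5, classes, method="optimal").counts()[0]
            greedy_tp = match_centres(preds, gt, 0.5, classes, method="greedy").counts()[0]
            assert opt_tp == oracle_tp
            # greedy is maximal, hence at least half the optimum; on these
            # scenes (seed 42) it attains the optimum everywhere
            assert greedy_tp == oracle_tp


class TestAveragePrecision:
    @staticmethod
    def _match_from_pattern(pattern, scores, n_gt):
        """Synthetic MatchResult: pattern True=TP, False=FP, ranked by score."""
        m = MatchResult(delta=0.5)
        gt_used = 0
        for is_tp, s in zip(pattern, scores):
            p = Prediction(0, 0, "neutrophil", s)
            if is_tp:
                g = make_set([(0, 0, "neutrophil")]).annotations[0]
                m.true_positives.append((p, g, 0.0))
                gt_used += 1
            else:
                m.false_positives.append(p)
        for _ in range(n_gt - gt_used):
            m.false_negatives.append(make_set([(1, 1, "neutrophil")]).annotations[0])
        return m

    def test_perfect_detector_ap_one(self):
        m = self._match_from_pattern([True, True, True], [0.9, 0.8, 0.7], 3)
        assert average_precision([m]) == pytest.approx(1.0)

    def test_zero_predictions_ap_zero(self):
        m = self._match_from_pattern([], [], 3)
        assert average_precision([m]) == 0.0

    def test_no_ground_truth_reported_absent(self):
        m = self._match_from_pattern([False], [0.9], 0)
        assert average_precision([m]) is None

    def test_worked_five_prediction_case(self):
        """TP,FP,TP,TP,FP over 3 GT; oracle enumerates the 5 PR points and
        integrates max-interpolated precision over recall steps."""
        pattern = [True, False, True, True, False]
        scores = [0.9, 0.8, 0.7, 0.6, 0.5]
        # independent enumeration
        tp = fp = 0
        points = []
        for is_tp in pattern:
            tp += is_tp
            fp += not is_tp
            points.append((tp / (tp + fp), tp / 3))
        area = 0.0
        prev_r = 0.0
        for prec, rec in points:
            interp = max(p for p, r in points if r >= rec)
            if rec > prev_r:
                area += (rec - prev_r) * interp
                prev_r = rec
        assert area == pytest.approx(2.5 / 3)
        m = self._match_from_pattern(pattern, scores, 3)
        assert average_precision([m]) == pytest.approx(area)

    def test_uniform_scores_fall_back_to_precision_times_recall(self):
        m = self._match_from_pattern([True, False, True], [1.0, 1.0, 1.0], 4)
        assert average_precision([m]) == pytest.approx((2 / 3) * (2 / 4))

    def test_informative_scores_beat_shuffled_scores(self, rng):
        # expectation over shuffles: scores correlated with correctness help
        pattern = [True] * 6 + [False] * 6
        scores = [0.9 - 0.05 * i for i in range(12)]
        m = self._match_from_pattern(pattern, scores, 6)
        ap = average_precision([m])
        shuffled = []
        for _ in range(100):
            perm = rng.permutation(12)
            m2 = self._match_from_pattern(
                [pattern[i] for i in perm], scores, 6
            )
            shuffled.append(average_precision([m2]))
        assert ap >= np.mean(shuffled)

    def test_assessor_predictions_have_uniform_scores(self):
        s = make_set([(10, 10, "neutrophil")])
        preds = assessor_predictions(s)
        assert [p.score for p in preds] == [1.0]


class TestF1:
    def test_perfect(self):
        m = MatchResult(delta=0.5)
        for _ in range(10):
            m.true_positives.append(
                (Prediction(0, 0, "neutrophil", 1.0), None, 0.0)
            )
        assert f1_at(m) == 1.0

    def test_zero_tp(self):
        m = MatchResult(delta=0.5)
        m.false_positives.append(Prediction(0, 0, "neutrophil", 1.0))
        assert f1_at(m) == 0.0

    def test_mixed_counts(self):
        m = MatchResult(delta=0.5)
        for _ in range(3):
            m.true_positives.append((Prediction(0, 0, "neutrophil", 1.0), None, 0.0))
        for _ in range(2):
            m.false_positives.append(Prediction(0, 0, "neutrophil", 1.0))
        m.false_negatives.append(make_set([(1, 1, "neutrophil")]).annotations[0])
        assert f1_at(m) == pytest.approx(6 / 9)

    def test_empty_is_zero(self):
        assert f1_at(MatchResult(delta=0.5)) == 0.0


class TestEvaluateDetections:
    def test_predictions_equal_truth_gives_ap_one(self):
        classes = flat_classes()
        truth = {
            "t0": make_set([(10, 10, "neutrophil"), (50, 50, "lymphocyte")]),
            "t1": make_set([(30, 30, "eosinophil")]),
        }
        preds = {
            t: [Prediction(a.x, a.y, a.cell_class, 0.99, t) for a in s]
            for t, s in truth.items()
        }
        rep = evaluate_detections(preds, truth, classes)
        populated = rep[rep.TP + rep.FN > 0]
        assert (populated.AP == 1.0).all()
        assert (populated.F1 == 1.0).all()

    def test_metrics_non_decreasing_in_delta(self, rng):
        classes = flat_classes(diameter=30.0)
        truth, preds = {}, {}
        for t in range(5):
            pts = [(x, y, CELL_CLASSES[int(rng.integers(4))])
                   for x, y in rng.uniform(20, 230, size=(6, 2))]
            truth[f"t{t}"] = make_set(pts)
            preds[f"t{t}"] = [
                Prediction(x + rng.normal(0, 3), y + rng.normal(0, 3), c,
                           float(rng.uniform(0.5, 1)), f"t{t}")
                for x, y, c in pts
            ]
        rep = evaluate_detections(preds, truth, classes,
                                  EvalConfig(deltas=(0.1, 0.25, 0.5), matching="optimal"))
        for name, sub in rep.groupby("cell_class"):
            sub = sub.sort_values("delta")
            f1 = sub.F1.tolist()
            assert f1 == sorted(f1)


class TestICC:
    @staticmethod
    def icc_oracle(m):
        """From-scratch two-way ANOVA with explicit loops."""
        n, k = m.shape
        grand = sum(m[i][j] for i in range(n) for j in range(k)) / (n * k)
        row = [sum(m[i][j] for j in range(k)) / k for i in range(n)]
        col = [sum(m[i][j] for i in range(n)) / n for j in range(k)]
        ss_r = k * sum((r - grand) ** 2 for r in row)
        ss_c = n * sum((c - grand) ** 2 for c in col)
        ss_t = sum((m[i][j] - grand) ** 2 for i in range(n) for j in range(k))
        ms_r = ss_r / (n - 1)
        ms_c = ss_c / (k - 1)
        ms_e = (ss_t - ss_r - ss_c) / ((n - 1) * (k - 1))
        return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))

    def test_identical_raters_give_one(self):
        col = np.arange(1, 11, dtype=float)
        m = np.tile(col[:, None], (1, 4))
        res = icc_a1(m)
        assert res.icc == pytest.approx(1.0)

    def test_pure_bias_drops_below_one(self):
        col = np.arange(1, 11, dtype=float)
        m = np.stack([col, col + 5.0], axis=1)
        res = icc_a1(m)
        assert res.icc < 1.0
        assert res.ms_cols > res.ms_error

    def test_matches_anova_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            m = rng.integers(0, 30, size=(20, 4)).astype(float)
            if np.allclose(m, m.flat[0]):
                continue
            got = icc_a1(m).icc
            want = self.icc_oracle(m)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        m = rng.integers(0, 30, size=(12, 3)).astype(float)
        df = pd.DataFrame(
            [
                {"subject": i, "rater": j, "score": m[i, j]}
                for i in range(12)
                for j in range(3)
            ]
        )
        out = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        row = out[out.Type.isin(["ICC(A,1)", "ICC2"])]
        want = float(row["ICC"].iloc[0])
        assert icc_a1(m).icc == pytest.approx(want, abs=1e-9)

    def test_constant_matrix_degenerate(self):
        res = icc_a1(np.full((5, 3), 7.0))
        assert res.degenerate and res.icc == 1.0

    def test_invariant_to_common_shift_and_row_permutation(self, rng):
        m = rng.normal(size=(15, 4))
        base = icc_a1(m).icc
        assert icc_a1(m + 100.0).icc == pytest.approx(base, rel=1e-9)
        assert icc_a1(m[rng.permutation(15)]).icc == pytest.approx(base, rel=1e-9)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(PreconditionError):
            icc_a1(np.zeros((1, 4)))
        with pytest.raises(ValidationError):
            icc_a1(np.zeros((3, 3, 3)))

    def test_count_matrix_shape(self):
        sets = {
            "t0": {"a1": make_set([(1, 1, "neutrophil")], assessor="a1"),
                   "a2": make_set([], assessor="a2")},
            "t1": {"a1": make_set([], assessor="a1"),
                   "a2": make_set([(2, 2, "eosinophil")], assessor="a2")},
        }
        m = per_tile_count_matrix(sets)
        assert m.shape == (2, 2)
        assert m[0, 0] == 1 and m[1, 1] == 1
        m_eos = per_tile_count_matrix(sets, "eosinophil")
        assert m_eos.sum() == 1


class TestDifferentialCount:
    def test_five_percent_eosinophils_flags_positive(self):
        pts = [Prediction(0, 0, "eosinophil", 1.0)] * 5 + [
            Prediction(0, 0, "macrophage_lineage", 1.0)
        ] * 95
        dc = differential_count(pts)
        assert dc.percentages["eosinophil"] == pytest.approx(5.0)
        assert dc.eosinophilic is True

    def test_exactly_61_percent_neutrophils_is_negative(self):
        pts = [Prediction(0, 0, "neutrophil", 1.0)] * 61 + [
            Prediction(0, 0, "lymphocyte", 1.0)
        ] * 39
        dc = differential_count(pts)
        assert dc.percentages["neutrophil"] == pytest.approx(61.0)
        assert dc.neutrophilic is False

    def test_worked_mix(self):
        pts = (
            [Prediction(0, 0, "macrophage_lineage", 1.0)] * 45
            + [Prediction(0, 0, "neutrophil", 1.0)] * 45
            + [Prediction(0, 0, "eosinophil", 1.0)] * 5
            + [Prediction(0, 0, "lymphocyte", 1.0)] * 5
        )
        dc = differential_count(pts)
        assert dc.percentages == pytest.approx(
            {"macrophage_lineage": 45, "neutrophil": 45, "eosinophil": 5,
             "lymphocyte": 5}
        )
        assert dc.eosinophilic is True and dc.neutrophilic is False

    def test_percentages_sum_to_hundred(self, rng):
        pts = [
            Prediction(0, 0, CELL_CLASSES[int(rng.integers(4))], 1.0)
            for _ in range(137)
        ]
        dc = differential_count(pts)
        assert sum(dc.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_duplication_scale_invariance(self):
        pts = [Prediction(0, 0, "eosinophil", 1.0)] * 2 + [
            Prediction(0, 0, "neutrophil", 1.0)
        ] * 48
        once = differential_count(pts)
        twice = differential_count(pts + pts)
        assert once.percentages == pytest.approx(twice.percentages)
        assert (once.eosinophilic, once.neutrophilic) == (
            twice.eosinophilic,
            twice.neutrophilic,
        )

    def test_zero_points_reports_counts_without_flags(self):
        dc = differential_count([], classes=CELL_CLASSES)
        assert dc.percentages is None
        assert dc.eosinophilic is None and dc.neutrophilic is None
        assert all(v == 0 for v in dc.counts.values())


class TestDatasetSplit:
    @staticmethod
    def nineteen_by_forty():
        return {
            f"cyt{i:02d}": [f"cyt{i:02d}_t{j}" for j in range(40)] for i in range(19)
        }

    def test_two_of_nineteen_holdout(self):
        train, hold, report = dataset_split(
            self.nineteen_by_forty(), ["cyt00", "cyt01"]
        )
        assert len(train) == 680
        assert len(hold) == 80
        assert report["train_pct"] == 89.5
        assert report["holdout_pct"] == 10.5

    def test_no_holdout(self):
        groups = self.nineteen_by_forty()
        train, hold, report = dataset_split(groups, [])
        assert len(train) == 760 and hold == []

    def test_holdout_tiles_never_in_training(self):
        groups = self.nineteen_by_forty()
        train, hold, _ = dataset_split(groups, ["cyt07"])
        assert set(train).isdisjoint(hold)

    def test_unknown_id_rejected(self):
        with pytest.raises(ValidationError):
            dataset_split(self.nineteen_by_forty(), ["nope"])

    def test_overlapping_groups_rejected(self):
        groups = {"a": ["t1", "t2"], "b": ["t2"]}
        with pytest.raises(ValidationError):
            dataset_split(groups, [])
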