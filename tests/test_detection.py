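"""Detection metrics against independent oracles."""

import numpy as np
import pytest

from phenobox import detection, scenes
from phenobox.annotations import NormalizedBox, PixelBox
from phenobox.errors import ConfigError


def ap_bruteforce(tp_sorted, n_gt):
    """Independent AP oracle: explicit step-function envelope integration.

    At each distinct recall level r the interpolated precision is the best
    precision achieved at any recall >= r; AP sums precision * recall
    increments over the distinct levels.
    """
    tp_sorted = np.asarray(tp_sorted, dtype=float)
    if n_gt == 0 or tp_sorted.size == 0 or tp_sorted.sum() == 0:
        return 0.0
    tps = np.cumsum(tp_sorted)
    fps = np.cumsum(1 - tp_sorted)
    recalls = tps / n_gt
    precisions = tps / (tps + fps)
    ap, prev_r = 0.0, 0.0
    for r in sorted(set(recalls)):
        if r == 0:
            continue
        p_env = max(precisions[recalls >= r])
        ap += (r - prev_r) * p_env
        prev_r = r
    return ap


def random_instance(rng, max_boxes=10):
    """Random preds/gts of one class in the unit square."""

    def rand_boxes(n, conf):
        out = []
        for _ in range(n):
            w, h = rng.uniform(0.05, 0.3, size=2)
            cx = rng.uniform(w / 2, 1 - w / 2)
            cy = rng.uniform(h / 2, 1 - h / 2)
            c = float(rng.uniform(0.05, 1.0)) if conf else None
            out.append(NormalizedBox(0, cx, cy, float(w), float(h), confidence=c))
        return out

    return rand_boxes(rng.integers(0, max_boxes + 1), True), rand_boxes(
        rng.integers(0, max_boxes + 1), False
    )


class TestIoU:
    def test_identical_boxes(self):
        b = PixelBox(0, 0, 4, 4)
        assert detection.iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert detection.iou(PixelBox(0, 0, 1, 1), PixelBox(2, 2, 3, 3)) == 0.0

    def test_hand_geometry(self):
        assert detection.iou(PixelBox(0, 0, 2, 2), PixelBox(1, 0, 3, 2)) == pytest.approx(2 / 6)

    def test_symmetry(self):
        a, b = PixelBox(0, 0, 2, 3), PixelBox(1, 1, 4, 2.5)
        assert detection.iou(a, b) == detection.iou(b, a)


class TestMatching:
    def test_perfect_predictions_all_tp(self):
        gts = [NormalizedBox(0, 0.5, 0.5, 0.2, 0.2), NormalizedBox(1, 0.2, 0.2, 0.1, 0.1)]
        preds = [NormalizedBox(b.class_id, b.cx, b.cy, b.w, b.h, confidence=1.0) for b in gts]
        m = detection.match_detections(preds, gts)
        assert (m.n_tp, m.n_fp, m.n_fn) == (2, 0, 0)

    def test_prediction_without_gt_is_fp(self):
        m = detection.match_detections([NormalizedBox(0, 0.5, 0.5, 0.2, 0.2, confidence=0.9)], [])
        assert (m.n_tp, m.n_fp, m.n_fn) == (0, 1, 0)

    def test_two_preds_one_gt_higher_confidence_wins(self):
        gt = [NormalizedBox(0, 0.5, 0.5, 0.2, 0.2)]
        preds = [
            NormalizedBox(0, 0.5, 0.5, 0.2, 0.2, confidence=0.6),
            NormalizedBox(0, 0.51, 0.5, 0.2, 0.2, confidence=0.9),
        ]
        m = detection.match_detections(preds, gt)
        assert (m.n_tp, m.n_fp, m.n_fn) == (1, 1, 0)
        assert m.order[0] == 1 and m.tp[0]  # the 0.9-confidence pred is the TP
        assert not m.tp[1]  # the lower-confidence duplicate is the FP

    def test_each_gt_matched_at_most_once(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            preds, gts = random_instance(rng, max_boxes=6)
            m = detection.match_detections(preds, gts)
            claimed = [g for g in m.matched_gt if g is not None]
            assert len(claimed) == len(set(claimed))
            assert m.n_tp <= min(len(preds), len(gts))


class TestPrecisionRecall:
    def test_arithmetic(self):
        m = detection.MatchResult(
            order=list(range(10)),
            tp=np.array([True] * 9 + [False]),
            matched_gt=[0] * 9 + [None],
            gt_matched=np.array([True] * 9 + [False] * 3),
            confidences=np.ones(10),
        )
        p, r = detection.precision_recall(m)
        assert (p, r) == (0.9, 0.75)

    def test_no_predictions_convention(self):
        m = detection.match_detections([], [NormalizedBox(0, 0.5, 0.5, 0.2, 0.2)])
        assert detection.precision_recall(m) == (0.0, 0.0)


class TestAveragePrecision:
    def test_all_correct_full_recall(self):
        assert detection.average_precision(np.ones(5), 5).ap == pytest.approx(1.0)

    def test_no_tp_gives_zero(self):
        assert detection.average_precision(np.zeros(4), 3).ap == 0.0

    def test_toy_case_against_oracle(self):
        flags = np.array([1.0, 0.0, 1.0])  # (TP, FP, TP) with 2 ground truths
        got = detection.average_precision(flags, 2).ap
        assert got == pytest.approx(ap_bruteforce(flags, 2))
        # hand value: envelope is 1.0 up to recall 0.5, then 2/3 to recall 1
        assert got == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            preds, gts = random_instance(rng)
            m = detection.match_detections(preds, gts)
            n_gt = len(gts)
            got = detection.average_precision(m.tp, n_gt).ap if n_gt else 0.0
            assert got == pytest.approx(ap_bruteforce(m.tp, n_gt), abs=1e-12)


class TestMeanAP:
    def _zero_noise_pairs(self, n=10):
        cohort = scenes.generate_cohort([scenes.default_treatments()["CK"]], n, seed=1)
        return [
            (scenes.corrupt_detections(s.image, scenes.NoiseSpec(), seed=0).boxes, s.image.boxes)
            for s in cohort
        ]

    def test_perfect_detections_score_one(self):
        res = detection.mean_ap(self._zero_noise_pairs())
        assert res.map50 == 1.0
        assert res.map50_95 == 1.0

    def test_map50_95_never_exceeds_map50(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pairs = [random_instance(rng) for _ in range(3)]
            if not any(gts for _, gts in pairs):
                continue
            res = detection.mean_ap(pairs)
            assert res.map50_95 <= res.map50 + 1e-12

    def test_map_decreases_with_jitter(self):
        cohort = scenes.generate_cohort([scenes.default_treatments()["CK"]], 15, seed=2)
        maps = []
        for level, jitter in enumerate((0.0, 0.08, 0.25)):
            noise = scenes.NoiseSpec(jitter_sd=jitter)
            pairs = [
                (
                    scenes.corrupt_detections(s.image, noise, seed=100 + i).boxes,
                    s.image.boxes,
                )
                for i, s in enumerate(cohort)
            ]
            maps.append(detection.mean_ap(pairs).map50_95)
        assert maps[0] > maps[1] > maps[2]


class TestConfusionMatrix:
    def test_perfect_detections_identity_after_normalization(self):
        cohort = scenes.generate_cohort([scenes.default_treatments()["CK"]], 5, seed=3)
        pairs = [
            (scenes.corrupt_detections(s.image, scenes.NoiseSpec(), seed=0).boxes, s.image.boxes)
            for s in cohort
        ]
        mat = detection.confusion_matrix(pairs, class_ids=[0, 1, 2, 3], normalize=True)
        assert np.allclose(mat[:4, :4], np.eye(4))

    def test_systematic_mislabeling_shifts_row_mass(self):
        gts = [NormalizedBox(0, 0.3, 0.3, 0.1, 0.1), NormalizedBox(0, 0.7, 0.7, 0.1, 0.1)]
        preds = [NormalizedBox(1, b.cx, b.cy, b.w, b.h, confidence=0.9) for b in gts]
        mat = detection.confusion_matrix([(preds, gts)], class_ids=[0, 1], normalize=True)
        assert mat[0, 1] == 1.0  # all leaf mass lands in the petiole column

    def test_grand_total_and_row_sums(self):
        rng = np.random.default_rng(11)
        pairs = [random_instance(rng) for _ in range(5)]
        mat = detection.confusion_matrix(pairs, class_ids=[0])
        n_gt = sum(len(g) for _, g in pairs)
        n_pred_unmatched = mat[-1, :].sum()
        assert mat.sum() == n_gt + n_pred_unmatched
        norm = detection.confusion_matrix(pairs, class_ids=[0], normalize=True)
        for row in norm:
            assert row.sum() == pytest.approx(1.0) or row.sum() == 0.0

    def test_confusion_rate_matches_binomial(self):
        """leaf->petiole confusion at rate 0.1 recovered within 3 SE."""
        cohort = scenes.generate_cohort([scenes.default_treatments()["CK"]], 60, seed=4)
        noise = scenes.NoiseSpec(confusion_prob=0.1)
        pairs = [
            (scenes.corrupt_detections(s.image, noise, seed=i).boxes, s.image.boxes)
            for i, s in enumerate(cohort)
        ]
        mat = detection.confusion_matrix(pairs, class_ids=[0, 1, 2, 3])
        n_leaf = mat[0, :].sum()
        rate = mat[0, 1] / n_leaf
        se = np.sqrt(0.1 * 0.9 / n_leaf)
        assert abs(rate - 0.1) < 3 * se


class TestConvFlops:
    @pytest.mark.parametrize(
        "args, expected",
        [((1, 1, 1, 1, 1), 2), ((3, 16, 3, 10, 10), 86_400)],
    )
    def test_known_values(self, args, expected):
        assert detection.conv_flops(*args) == expected

    def test_linearity_in_output_size(self):
        assert detection.conv_flops(3, 8, 3, 20, 10) == 2 * detection.conv_flops(3, 8, 3, 10, 10)

    def test_nonpositive_rejected(self):
        with pytest.raises(ConfigError):
            detection.conv_flops(0, 1, 1, 1, 1)
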