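"""Detection metrics against hand counts and brute-force oracles."""
import numpy as np
import pytest
from conftest import naive_average_precision, naive_iou
from hypothesis import given, settings
from hypothesis import strategies as st

from uwdetect.metrics import (ConfusionCounts, average_precision, iou,
                              map_metrics, match_detections, match_flags,
                              precision_recall)


def test_iou_basic_cases():
    assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0
    assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0
    assert iou((0, 0, 2, 2), (1, 0, 3, 2)) == pytest.approx(1 / 3)


def test_iou_degenerate_box_raises():
    with pytest.raises(ValueError):
        iou((0, 0, 0, 2), (0, 0, 1, 1))


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_iou_matches_naive_formula(seed):
    rng = np.random.default_rng(seed)
    def box():
        x1, y1 = rng.uniform(0, 10, 2)
        w, h = rng.uniform(0.1, 8, 2)
        return (x1, y1, x1 + w, y1 + h)
    a, b = box(), box()
    assert iou(a, b) == pytest.approx(naive_iou(a, b), abs=1e-9)


def test_matching_perfect_empty_and_duplicate():
    gts = np.array([[0, 0, 10, 10], [20, 20, 30, 30]], dtype=float)
    perfect = match_detections(gts, [0.9, 0.8], gts, 0.5)
    assert (perfect.tp, perfect.fp, perfect.fn) == (2, 0, 0)
    empty = match_detections(np.empty((0, 4)), [], gts, 0.5)
    assert (empty.tp, empty.fp, empty.fn) == (0, 0, 2)
    # two identical detections on one gt: first (higher conf) is TP
    dup = match_detections(np.array([[0, 0, 10, 10], [0, 0, 10, 10]]),
                           [0.9, 0.8], gts[:1], 0.5)
    assert (dup.tp, dup.fp, dup.fn) == (1, 1, 0)


def test_precision_recall_and_zero_conventions():
    assert precision_recall(ConfusionCounts(7, 3, 0))[0] == pytest.approx(0.7)
    assert precision_recall(ConfusionCounts(7, 0, 3))[1] == pytest.approx(0.7)
    assert precision_recall(ConfusionCounts(0, 0, 5)) == (0.0, 0.0)


def test_average_precision_hand_sequence():
    """Outcomes [TP,FP,TP,FP,FP] over 2 gts, against the brute-force
    101-point oracle."""
    conf = [0.9, 0.8, 0.7, 0.6, 0.5]
    flags = [True, False, True, False, False]
    expected = naive_average_precision(conf, flags, 2)
    assert average_precision(conf, flags, 2) == pytest.approx(expected, abs=1e-9)


def test_average_precision_extremes():
    assert average_precision([0.9, 0.8], [True, True], 2) == pytest.approx(1.0)
    assert average_precision([0.9, 0.8], [False, False], 2) == 0.0
    assert average_precision([], [], 0) != average_precision([], [], 0)  # NaN


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_ap_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 20))
    conf = rng.uniform(0, 1, n)
    flags = rng.random(n) < 0.5
    n_gt = int(flags.sum() + rng.integers(0, 5))
    if n_gt == 0:
        return
    assert average_precision(conf, flags, n_gt) == pytest.approx(
        naive_average_precision(conf, flags, n_gt), abs=0.01)


def _one_image(seed, n_det=8, n_gt=5, nc=3):
    rng = np.random.default_rng(seed)
    def boxes(n):
        xy = rng.uniform(0, 80, (n, 2))
        wh = rng.uniform(4, 20, (n, 2))
        return np.concatenate([xy, xy + wh], axis=1)
    return ((boxes(n_det), rng.integers(0, nc, n_det), rng.uniform(0, 1, n_det)),
            (boxes(n_gt), rng.integers(0, nc, n_gt)))


def test_map_permutation_invariance():
    dets, gts = zip(*[_one_image(s) for s in range(4)])
    base = map_metrics(list(dets), list(gts), 3)
    shuffled = []
    for db, dc, dconf in dets:
        p = np.random.default_rng(0).permutation(len(dc))
        shuffled.append((db[p], dc[p], dconf[p]))
    assert map_metrics(shuffled, list(gts), 3) == pytest.approx(base)


def test_map_iou_threshold_enumeration():
    """Detections overlapping every gt at IoU exactly 0.55 score AP 1 at
    thresholds {0.50, 0.55} and 0 above: mAP50 = 1, mAP50:95 = 0.2."""
    gt = np.array([[0.0, 0.0, 100.0, 100.0]])
    # shift right so intersection/union = 0.55: x solves (100-x)/(100+x)=0.55
    # (nudged a hair smaller so float rounding cannot land below 0.55)
    x = 100 * (1 - 0.55) / (1 + 0.55) - 1e-4
    det = gt + np.array([x, 0, x, 0])
    dets = [(det, np.array([0]), np.array([0.9]))]
    gts = [(gt, np.array([0]))]
    m50, m5095 = map_metrics(dets, gts, 1)
    assert m50 == pytest.approx(1.0)
    assert m5095 == pytest.approx(0.2, abs=1e-6)


def test_map_ignores_classes_without_ground_truth():
    dets, gts = zip(*[_one_image(s, nc=2) for s in range(3)])
    base = map_metrics(list(dets), list(gts), 2)
    assert map_metrics(list(dets), list(gts), 5) == pytest.approx(base)


def test_perfect_detections_give_unit_map():
    gts = [_one_image(s)[1] for s in range(3)]
    dets = [(b, c, np.ones(len(c))) for b, c in gts]
    assert map_metrics(dets, gts, 3) == (1.0, 1.0)
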