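"""Evaluation metrics against brute-force oracles and closed-form cases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafseg.metrics import (
    MetricError,
    boundary_band,
    boundary_iou,
    confusion,
    default_boundary_width,
    evaluate,
    mask_contour,
    mean_iou,
    mean_pixel_accuracy,
    pixel_accuracy,
)

from conftest import random_binary_mask


def brute_force_metrics(pred, truth, k=2):
    """Triple-loop PA / MPA / MIoU straight from the confusion-sum formulas."""
    p = np.zeros((k, k), dtype=np.int64)
    for r in range(truth.shape[0]):
        for c in range(truth.shape[1]):
            p[truth[r, c], pred[r, c]] += 1
    pa = sum(p[i, i] for i in range(k)) / p.sum()
    recalls, ious = [], []
    for i in range(k):
        row = sum(p[i, j] for j in range(k))
        col = sum(p[j, i] for j in range(k))
        if row > 0:
            recalls.append(p[i, i] / row)
        if row + col - p[i, i] > 0:
            ious.append(p[i, i] / (row + col - p[i, i]))
    return pa, float(np.mean(recalls)), float(np.mean(ious))


HALF_TRUTH = np.repeat([[1], [1], [0], [0]], 4, axis=1)  # top half foreground
HALF_PRED = np.tile([1, 1, 0, 0], (4, 1))  # left half foreground


def test_confusion_enumerated_half_case():
    cm = confusion(HALF_PRED, HALF_TRUTH)
    # true fg (top half): 4 predicted fg, 4 predicted bg; true bg likewise
    np.testing.assert_array_equal(cm, [[4, 4], [4, 4]])


def test_confusion_identity_and_single_class():
    mask = random_binary_mask(np.random.default_rng(0), 4, 4)
    cm = confusion(mask, mask)
    assert np.trace(cm) == 16 and cm[0, 1] == cm[1, 0] == 0
    zeros = np.zeros((4, 4), dtype=int)
    np.testing.assert_array_equal(confusion(zeros, zeros), [[16, 0], [0, 0]])


def test_confusion_is_additive_over_images():
    rng = np.random.default_rng(1)
    a_p, a_t = random_binary_mask(rng, 6, 6), random_binary_mask(rng, 6, 6)
    b_p, b_t = random_binary_mask(rng, 6, 6), random_binary_mask(rng, 6, 6)
    both = confusion(np.concatenate([a_p, b_p]), np.concatenate([a_t, b_t]))
    np.testing.assert_array_equal(both, confusion(a_p, a_t) + confusion(b_p, b_t))


def test_confusion_rejects_bad_inputs():
    with pytest.raises(MetricError):
        confusion(np.zeros((2, 2)), np.zeros((3, 3)))
    with pytest.raises(MetricError):
        confusion(np.full((2, 2), 5), np.zeros((2, 2)), num_classes=2)


def test_worked_half_case_scores():
    cm = confusion(HALF_PRED, HALF_TRUTH)
    assert pixel_accuracy(cm) == 0.5
    assert mean_pixel_accuracy(cm) == 0.5
    miou, per_class = mean_iou(cm)
    assert miou == pytest.approx(1 / 3)
    np.testing.assert_allclose(per_class, [4 / 12, 4 / 12])


def test_perfect_and_complement_predictions():
    mask = HALF_TRUTH
    cm = confusion(mask, mask)
    assert pixel_accuracy(cm) == mean_pixel_accuracy(cm) == 1.0
    assert mean_iou(cm)[0] == 1.0
    cm_bad = confusion(1 - mask, mask)
    assert mean_iou(cm_bad)[0] == 0.0


def test_single_class_truth_excludes_absent_class():
    ones = np.ones((4, 4), dtype=int)
    cm = confusion(ones, ones)
    assert mean_pixel_accuracy(cm) == 1.0
    assert mean_iou(cm)[0] == 1.0


def test_uniform_confusion_matrix_gives_half():
    cm = np.full((2, 2), 7)
    assert pixel_accuracy(cm) == 0.5
    assert mean_pixel_accuracy(cm) == 0.5


def test_metrics_match_brute_force_on_random_masks(rng):
    for _ in range(50):
        h, w = rng.integers(2, 17, size=2)
        pred = random_binary_mask(rng, h, w)
        truth = random_binary_mask(rng, h, w)
        cm = confusion(pred, truth)
        pa_o, mpa_o, miou_o = brute_force_metrics(pred, truth)
        assert pixel_accuracy(cm) == pa_o
        assert mean_pixel_accuracy(cm) == mpa_o
        assert mean_iou(cm)[0] == miou_o


def test_metrics_invariant_under_joint_pixel_permutation(rng):
    pred = random_binary_mask(rng, 8, 8)
    truth = random_binary_mask(rng, 8, 8)
    perm = rng.permutation(64)
    pred_p = pred.ravel()[perm].reshape(8, 8)
    truth_p = truth.ravel()[perm].reshape(8, 8)
    np.testing.assert_array_equal(
        np.sort(confusion(pred, truth), axis=None),
        np.sort(confusion(pred_p, truth_p), axis=None),
    )
    assert pixel_accuracy(confusion(pred, truth)) == pixel_accuracy(
        confusion(pred_p, truth_p)
    )


# -- boundary band ---------------------------------------------------------

def brute_force_band(mask, d):
    contour = mask_contour(mask)
    coords = np.argwhere(contour)
    band = np.zeros_like(mask, dtype=bool)
    if len(coords) == 0:
        return band
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            dist = np.hypot(coords[:, 0] - r, coords[:, 1] - c).min()
            band[r, c] = dist <= d
    return band


def test_single_pixel_band_d1():
    mask = np.zeros((7, 7), dtype=np.uint8)
    mask[3, 3] = 1
    band = boundary_band(mask, 1).band
    assert band.sum() == 5  # the pixel and its 4-neighbours at distance 1
    np.testing.assert_array_equal(band, brute_force_band(mask, 1))


def test_band_covers_image_for_huge_d(rng):
    mask = random_binary_mask(rng, 8, 8)
    if mask.sum() == 0:
        mask[0, 0] = 1
    d = int(np.ceil(np.hypot(8, 8)))
    assert boundary_band(mask, d).band.all()


def test_band_matches_brute_force_and_is_monotone(rng):
    for _ in range(10):
        mask = random_binary_mask(rng, 9, 9, p=0.4)
        for d in (1, 2, 3):
            band = boundary_band(mask, d).band
            np.testing.assert_array_equal(band, brute_force_band(mask, d))
        assert (
            boundary_band(mask, 1).band <= boundary_band(mask, 2).band
        ).all()


def test_empty_foreground_band_warns_and_flags():
    with pytest.warns(UserWarning, match="empty foreground"):
        bb = boundary_band(np.zeros((5, 5), dtype=np.uint8), 2)
    assert bb.empty_foreground and not bb.band.any()


def test_contour_includes_image_border_foreground():
    mask = np.ones((4, 4), dtype=np.uint8)
    contour = mask_contour(mask)
    assert contour[0].all() and contour[-1].all()
    assert not contour[1:-1, 1:-1].any()


# -- boundary IoU ----------------------------------------------------------

def test_boundary_iou_identity_and_symmetry(rng):
    for _ in range(10):
        g = random_binary_mask(rng, 10, 10)
        p = random_binary_mask(rng, 10, 10)
        assert boundary_iou(g, g, d=2) == 1.0
        assert boundary_iou(g, p, d=2) == boundary_iou(p, g, d=2)


def test_boundary_iou_reduces_to_foreground_iou_at_large_d(rng):
    d = int(np.ceil(np.hypot(12, 12)))
    for _ in range(20):
        g = random_binary_mask(rng, 12, 12)
        p = random_binary_mask(rng, 12, 12)
        union = (g | p).sum()
        fg_iou = 1.0 if union == 0 else (g & p).sum() / union
        assert boundary_iou(g, p, d=d) == fg_iou


def test_boundary_iou_half_case_at_large_d():
    d = int(np.ceil(np.hypot(4, 4)))
    assert boundary_iou(HALF_TRUTH, HALF_PRED, d=d) == pytest.approx(1 / 3)


def test_boundary_iou_empty_sets_and_default_width():
    empty = np.zeros((10, 10), dtype=np.uint8)
    assert boundary_iou(empty, empty, d=3) == 1.0
    assert default_boundary_width((512, 512)) == round(0.02 * np.hypot(512, 512))
    assert default_boundary_width((10, 10)) == 1


def test_boundary_iou_penalises_boundary_errors_more_than_miou():
    # big disk vs. eroded disk: interior agreement dominates MIoU but not BIoU
    yy, xx = np.mgrid[0:64, 0:64]
    g = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 25**2).astype(np.uint8)
    p = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 22**2).astype(np.uint8)
    miou = mean_iou(confusion(p, g))[0]
    biou = boundary_iou(g, p, d=2)
    assert biou < miou


# -- dataset-level aggregation ---------------------------------------------

def test_evaluate_single_image_equals_per_image_metrics(rng):
    g = random_binary_mask(rng, 8, 8)
    p = random_binary_mask(rng, 8, 8)
    report = evaluate([p], [g], d=2)
    cm = confusion(p, g)
    assert report.PA == pixel_accuracy(cm)
    assert report.MIoU == mean_iou(cm)[0]
    assert report.BIoU == boundary_iou(g, p, d=2)
    assert report.n_images == 1


def test_evaluate_is_invariant_under_duplication(rng):
    g = random_binary_mask(rng, 8, 8)
    p = random_binary_mask(rng, 8, 8)
    once = evaluate([p], [g], d=2)
    twice = evaluate([p, p], [g, g], d=2)
    assert once.PA == twice.PA and once.MIoU == twice.MIoU
    assert once.BIoU == twice.BIoU


def test_evaluate_averages_biou_per_image():
    a_g = np.zeros((8, 8), dtype=np.uint8)
    a_g[2:6, 2:6] = 1
    b_g = a_g.copy()
    a_p = a_g.copy()  # perfect: BIoU 1
    b_p = np.zeros_like(b_g)
    b_p[2:6, 2:7] = 1  # shifted edge
    report = evaluate([a_p, b_p], [a_g, b_g], d=1)
    expected = (boundary_iou(a_g, a_p, 1) + boundary_iou(b_g, b_p, 1)) / 2
    assert report.BIoU == pytest.approx(expected)


def test_all_metrics_are_one_iff_prediction_equals_truth(rng):
    g = random_binary_mask(rng, 8, 8)
    perfect = evaluate([g.copy()], [g], d=2)
    assert perfect.PA == perfect.MPA == perfect.MIoU == perfect.BIoU == 1.0
    p = g.copy()
    p[0, 0] ^= 1
    imperfect = evaluate([p], [g], d=2)
    assert imperfect.PA < 1.0


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    h=st.integers(2, 12),
    w=st.integers(2, 12),
    seed=st.integers(0, 2**31 - 1),
)
def test_metric_bounds_and_perfect_prediction_property(h, w, seed):
    """All scores lie in [0, 1]; they hit 1 exactly when pred == truth."""
    local = np.random.default_rng(seed)
    pred = random_binary_mask(local, h, w)
    truth = random_binary_mask(local, h, w)
    cm = confusion(pred, truth)
    assert cm.sum() == h * w
    scores = [pixel_accuracy(cm), mean_pixel_accuracy(cm), mean_iou(cm)[0],
              boundary_iou(truth, pred, d=1)]
    assert all(0.0 <= s <= 1.0 for s in scores)
    if np.array_equal(pred, truth):
        assert all(s == 1.0 for s in scores)
    else:
        assert pixel_accuracy(cm) < 1.0


def test_evaluate_rejects_empty_or_mismatched_lists():
    with pytest.raises(MetricError):
        evaluate([], [])
    with pytest.raises(MetricError):
        evaluate([np.zeros((2, 2), int)], [])
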