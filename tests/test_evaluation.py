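"""Evaluation protocol: IoU, components, flags, accuracy, means, SSIM."""

import numpy as np
import pytest

from disccascade.evaluation import (
    EvalRecord,
    accuracy,
    count_components,
    evaluate,
    image_flag,
    iou,
    mean_iou_disc,
    mean_iou_overall,
    ssim_score,
)
from disccascade.labels import DISC_LABELS


def blob(shape, ys, xs):
    m = np.zeros(shape, dtype=bool)
    m[ys, xs] = True
    return m


# ---------------------------------------------------------------- references
def iou_reference(pred, truth):
    inter = union = 0
    for y in range(pred.shape[0]):
        for x in range(pred.shape[1]):
            p, t = bool(pred[y, x]), bool(truth[y, x])
            inter += p and t
            union += p or t
    return inter / union


def components_reference(mask):
    """Flood-fill 8-connected component count."""
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    count = 0
    for y0 in range(h):
        for x0 in range(w):
            if mask[y0, x0] and not seen[y0, x0]:
                count += 1
                stack = [(y0, x0)]
                seen[y0, x0] = True
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                                seen[yy, xx] = True
                                stack.append((yy, xx))
    return count


# --------------------------------------------------------------------- tests
def test_iou_examples():
    a = blob((20, 20), slice(2, 12), slice(2, 12))
    assert iou(a, a) == 1.0
    b = blob((20, 20), slice(2, 12), slice(7, 17))  # shifted 5 columns
    assert iou(a, b) == pytest.approx(1 / 3)
    c = blob((20, 20), slice(15, 18), slice(15, 18))
    assert iou(a, c) == 0.0


def test_iou_both_empty_raises():
    with pytest.raises(ValueError):
        iou(np.zeros((4, 4), dtype=bool), np.zeros((4, 4), dtype=bool))
    with pytest.raises(ValueError):
        iou(np.zeros((4, 4), dtype=bool), np.zeros((5, 5), dtype=bool))


def test_component_counting():
    assert count_components(np.zeros((6, 6), dtype=bool)) == 0
    two = blob((10, 10), slice(0, 2), slice(0, 2)) | blob((10, 10), slice(6, 8), slice(6, 8))
    assert count_components(two) == 2
    diag = np.zeros((4, 4), dtype=bool)
    diag[1, 1] = diag[2, 2] = True  # touching only diagonally
    assert count_components(diag) == 1


def make_masks(ious, components=(1, 1, 1), shape=(40, 110)):
    """Construct pred/truth pairs with prescribed per-disc IoU.

    Truth is a 10x100 strip; the prediction keeps the first round(100*v)
    columns, so pred ⊂ truth and IoU = kept/100 = v exactly.
    """
    preds, truths = {}, {}
    for i, (k, v) in enumerate(zip(DISC_LABELS, ious)):
        base_rows = slice(i * 12, i * 12 + 10)
        truth = blob(shape, base_rows, slice(0, 100))
        pred = blob(shape, base_rows, slice(0, round(100 * v)))
        if components[i] == 2:
            pred |= blob(shape, i * 12, slice(104, 107))
        preds[k], truths[k] = pred, truth
    return preds, truths


@pytest.mark.parametrize(
    "ious, comps, expected_flag",
    [
        ((0.8, 0.75, 0.71), (1, 1, 1), 1),
        ((0.8, 0.69, 0.9), (1, 1, 1), 0),   # one disc below 0.7
        ((0.8, 0.75, 0.9), (1, 2, 1), 0),   # split prediction
    ],
)
def test_image_flag_rule(ious, comps, expected_flag):
    preds, truths = make_masks(ious, comps)
    assert image_flag(preds, truths) == expected_flag


def test_accuracy_and_means():
    assert accuracy([1, 0, 1, 1]) == 0.75
    records = [
        EvalRecord(0, dict(zip(DISC_LABELS, [0.8, 0.7, 0.6])), {}, 1),
        EvalRecord(1, dict(zip(DISC_LABELS, [0.9, 0.8, 0.7])), {}, 1),
    ]
    assert mean_iou_overall(records) == pytest.approx(0.75)
    per_disc = [mean_iou_disc(records, k) for k in DISC_LABELS]
    assert per_disc == pytest.approx([0.85, 0.75, 0.65])
    # grand mean equals the mean of the three per-disc means
    assert mean_iou_overall(records) == pytest.approx(np.mean(per_disc))


def test_metrics_match_bruteforce_references(rng):
    """IoU, component counts and flags agree with naive loops on 200 cases."""
    for _ in range(200):
        shape = tuple(rng.integers(8, 16, size=2))
        pred = rng.random(shape) > 0.6
        truth = rng.random(shape) > 0.6
        if truth.any() or pred.any():
            assert iou(pred, truth) == pytest.approx(iou_reference(pred, truth))
        assert count_components(pred) == components_reference(pred)


def test_flag_and_accuracy_consistency(rng):
    """A = B/T with B counted independently from the per-image flags."""
    flags = []
    for j in range(25):
        ious = rng.uniform(0.5, 1.0, size=3)
        preds, truths = make_masks(ious)
        actual = [iou(preds[k], truths[k]) for k in DISC_LABELS]
        expected = int(all(v >= 0.7 for v in actual))
        flags.append(image_flag(preds, truths))
        assert flags[-1] == expected
    assert accuracy(flags) == sum(flags) / len(flags)


def test_ssim_identical_and_constant():
    img = np.random.default_rng(0).random((64, 64))
    assert ssim_score(img, img) == pytest.approx(1.0)
    c1 = 0.01**2
    got = ssim_score(np.ones((64, 64)), np.zeros((64, 64)))
    assert got == pytest.approx(c1 / (1 + c1), rel=1e-6)


def test_ssim_decreases_with_mask_corruption(sample):
    """Flipping a growing fraction of pixels lowers structural similarity."""
    from disccascade.pipeline import integrate_masks

    truth_lab, _ = integrate_masks(sample.masks)
    truth = truth_lab / 3.0
    rng = np.random.default_rng(0)
    noise = rng.random(truth.shape)
    scores = []
    for frac in (0.0, 0.05, 0.2, 0.5):
        corrupted = truth.copy()
        flip = noise < frac
        corrupted[flip] = 1.0 - corrupted[flip]
        scores.append(ssim_score(corrupted, truth))
    assert scores[0] == pytest.approx(1.0)
    assert all(a > b for a, b in zip(scores, scores[1:]))


def test_evaluate_perfect_and_partial(sample):
    truths = [sample.masks] * 10
    assert evaluate(truths, truths).accuracy == 1.0
    assert evaluate(truths, truths).mean_iou_overall == 1.0

    # break one disc (split into two components) in 3 of 10 images
    broken = dict(sample.masks)
    m = sample.masks["L1L2"].copy()
    ys, xs = np.nonzero(m)
    mid = int(np.median(xs))
    m[:, mid] = False  # split the ellipse into two components
    broken["L1L2"] = m
    preds = [broken] * 3 + [dict(sample.masks)] * 7
    summ = evaluate(preds, truths)
    assert summ.accuracy == pytest.approx(0.7)
    assert summ.B == 7


def test_evaluate_bootstrap_deterministic(sample):
    truths = [sample.masks] * 6
    a = evaluate(truths, truths, bootstrap=200, seed=5)
    b = evaluate(truths, truths, bootstrap=200, seed=5)
    assert a.ci95 == b.ci95
    assert set(a.ci95) == {"accuracy", "mean_iou_overall", "mean_ssim"}


def test_evaluate_length_mismatch_raises(sample):
    with pytest.raises(ValueError):
        evaluate([sample.masks], [sample.masks] * 2)
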