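"""Saliency targets, center recovery and the center-error rule."""

import numpy as np
import pytest

from disccascade.saliency import (
    CenterPoint,
    center_error,
    compute_saliency_target,
    extract_center,
    is_center_correct,
    mask_centroid,
)


def saliency_reference(center, shape, n):
    """Independent per-pixel double loop implementation of the target map."""
    h, w = shape
    powered = np.empty(shape, dtype=np.float64)
    for y in range(h):
        for x in range(w):
            d2 = (x - center.x) ** 2 + (y - center.y) ** 2
            powered[y, x] = d2 ** (1.0 / n)
    return 1.0 - powered / powered.max()


def test_matches_bruteforce_reference(rng):
    """Vectorized map equals the naive double loop on 100 random grids."""
    for _ in range(100):
        h, w = rng.integers(2, 33, size=2)
        c = CenterPoint(x=int(rng.integers(0, w)), y=int(rng.integers(0, h)))
        n = int(rng.integers(1, 6))
        got = compute_saliency_target(c, (h, w), n).values
        ref = saliency_reference(c, (h, w), n)
        assert np.abs(got - ref).max() <= 1e-12


def test_known_values_5x5_center():
    c = CenterPoint(2, 2)
    m1 = compute_saliency_target(c, (5, 5), n=1).values
    assert m1[2, 2] == 1.0                      # zero distance
    assert m1[0, 0] == 0.0                      # farthest pixel (corner, d2=8)
    assert m1[4, 2] == pytest.approx(0.5)       # d2=4 over max 8
    m2 = compute_saliency_target(c, (5, 5), n=2).values
    assert m2[4, 2] == pytest.approx(1 - 2 / np.sqrt(8))


def test_sharpening_with_larger_power(rng):
    """Off-center values are non-increasing in n: larger n = sharper peak."""
    for _ in range(20):
        h, w = rng.integers(4, 33, size=2)
        c = CenterPoint(x=int(rng.integers(0, w)), y=int(rng.integers(0, h)))
        prev = compute_saliency_target(c, (h, w), 1).values
        for n in range(2, 6):
            cur = compute_saliency_target(c, (h, w), n).values
            assert (cur <= prev + 1e-12).all()
            prev = cur


def test_strictly_decreasing_in_distance():
    c = CenterPoint(10, 10)
    m = compute_saliency_target(c, (21, 21), n=3).values
    yy, xx = np.mgrid[:21, :21]
    d2 = (xx - 10) ** 2 + (yy - 10) ** 2
    order = np.argsort(d2.ravel())
    vals = m.ravel()[order]
    dsorted = d2.ravel()[order]
    # strictly decreasing wherever distance strictly increases
    inc = np.diff(dsorted) > 0
    assert (np.diff(vals)[inc] < 0).all()


def test_power_mode_is_the_alternative_reading():
    c = CenterPoint(2, 2)
    m = compute_saliency_target(c, (5, 5), n=2, exponent_mode="power").values
    # n=2 power reading: d^2 normalized by max d^2 -> 1 - 4/8 at (2,4)
    assert m[4, 2] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        compute_saliency_target(c, (5, 5), n=2, exponent_mode="cubic")


def test_center_outside_raises():
    with pytest.raises(ValueError):
        compute_saliency_target(CenterPoint(5, 0), (5, 5), 1)


@pytest.mark.parametrize(
    "pixels, expected",
    [
        ([(y, x) for y in range(2, 5) for x in range(3, 6)], (4, 3)),  # 3x3 block
        ([(9, 7)], (7, 9)),
        ([(0, 0), (0, 3)], (1, 0)),  # mean x 1.5 rounds half DOWN
    ],
)
def test_mask_centroid_rounding(pixels, expected):
    mask = np.zeros((12, 12), dtype=bool)
    for y, x in pixels:
        mask[y, x] = True
    assert mask_centroid(mask).as_tuple() == expected


def test_mask_centroid_empty_raises():
    with pytest.raises(ValueError):
        mask_centroid(np.zeros((4, 4), dtype=bool))


def test_extract_center_roundtrip_all_interior():
    """extract_center inverts compute_saliency_target for interior centers."""
    for y in range(1, 63, 1):
        for x in range(1, 63, 7):  # stride x to keep runtime low; full y sweep
            c = CenterPoint(x, y)
            got = extract_center(compute_saliency_target(c, (64, 64), n=3))
            assert got == c


def test_extract_center_tie_midpoint():
    m = np.zeros((8, 8))
    m[3, 4] = m[3, 6] = 1.0
    assert extract_center(m).as_tuple() == (5, 3)


def test_extract_center_constant_raises():
    with pytest.raises(ValueError):
        extract_center(np.full((6, 6), 0.3))


def test_extract_center_under_noise():
    """Median L1 error stays within 2 px under 0.01-amplitude uniform noise."""
    rng = np.random.default_rng(0)
    errs = []
    for _ in range(100):
        c = CenterPoint(int(rng.integers(5, 123)), int(rng.integers(5, 123)))
        m = compute_saliency_target(c, (128, 128), n=3).values
        noisy = m + rng.uniform(0, 0.01, m.shape)
        errs.append(center_error(extract_center(noisy), c))
    assert np.median(errs) <= 2


@pytest.mark.parametrize(
    "p, q, err, correct",
    [
        (CenterPoint(3, 4), CenterPoint(3, 4), 0, True),
        (CenterPoint(10, 20), CenterPoint(14, 25), 9, True),
        (CenterPoint(0, 0), CenterPoint(10, 0), 10, False),
    ],
)
def test_center_error_rule(p, q, err, correct):
    e = center_error(p, q)
    assert e == err
    assert is_center_correct(e) is correct
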