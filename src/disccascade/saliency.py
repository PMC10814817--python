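"""Saliency targets that peak at a disc center, and center recovery.

The localization stage does not regress coordinates directly.  Instead each
target disc is represented by a dense "saliency" image built from the distance
transform to its center point ``(x0, y0)``:

    D_i = 1 - d_i^(2/n) / max_j d_j^(2/n)

with ``d_i`` the Euclidean distance of pixel ``i`` to the center and ``n`` the
power of distance.  The map is 1 at the center, 0 at the farthest pixel of the
image, and with the root exponent reading larger ``n`` gives a sharper peak
(lower values everywhere off-center).  A segmentation network is trained to
regress these maps, and the center is recovered from a predicted map by taking
the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np

__all__ = [
    "CenterPoint",
    "SaliencyMap",
    "compute_saliency_target",
    "mask_centroid",
    "extract_center",
    "center_error",
    "is_center_correct",
    "CENTER_ERROR_THRESHOLD",
]

#: L1 center error below which a localization counts as correct.
CENTER_ERROR_THRESHOLD = 10

ExponentMode = Literal["root", "power"]


@dataclass(frozen=True)
class CenterPoint:
    """Pixel coordinate of a disc center: ``x`` is the column, ``y`` the row."""

    x: int
    y: int

    def as_tuple(self) -> Tuple[int, int]:
        return (self.x, self.y)


@dataclass(frozen=True)
class SaliencyMap:
    """A dense center-saliency image together with the exponent used."""

    values: np.ndarray
    n: int

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


def round_half_down(v: float) -> int:
    """Round to the nearest integer, halves toward minus infinity (1.5 -> 1)."""
    return int(np.ceil(v - 0.5))


def compute_saliency_target(
    center: CenterPoint,
    shape: Tuple[int, int],
    n: int = 3,
    exponent_mode: ExponentMode = "root",
) -> SaliencyMap:
    """Build the saliency target for a known center.

    Parameters
    ----------
    center
        Disc center, must lie inside ``shape``.
    shape
        ``(rows, cols)`` of the output grid.
    n
        Power of distance (>= 1).  ``n`` sharpens the peak in ``root`` mode.
    exponent_mode
        ``"root"`` uses ``(d^2)^(1/n)`` (default), ``"power"`` uses ``d^n``.
        Both normalize by the per-image maximum, so D is 1 at the center and
        0 at the farthest pixel in either mode.
    """
    h, w = shape
    if not (0 <= center.x < w and 0 <= center.y < h):
        raise ValueError(f"center {center} outside image of shape {shape}")
    if n < 1:
        raise ValueError("power of distance n must be >= 1")
    yy, xx = np.ogrid[:h, :w]
    d2 = (xx - center.x) ** 2.0 + (yy - center.y) ** 2.0
    if exponent_mode == "root":
        powered = d2 ** (1.0 / n)
    elif exponent_mode == "power":
        powered = d2 ** (n / 2.0)
    else:
        raise ValueError(f"unknown exponent mode {exponent_mode!r}")
    m = powered.max()
    if m == 0:  # degenerate 1x1 image
        return SaliencyMap(np.ones(shape, dtype=np.float64), n)
    return SaliencyMap(1.0 - powered / m, n)


def mask_centroid(mask: np.ndarray) -> CenterPoint:
    """Centroid of a binary mask, coordinates rounded half down.

    Raises ``ValueError`` on an empty mask.
    """
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("cannot take the centroid of an empty mask")
    return CenterPoint(x=round_half_down(xs.mean()), y=round_half_down(ys.mean()))


def extract_center(saliency: SaliencyMap | np.ndarray) -> CenterPoint:
    """Recover the center from a (predicted) saliency map.

    Takes the location of the maximum value; if the maximum is attained at
    several pixels, the rounded centroid of the argmax set is returned.  A
    constant map carries no localization information and raises.
    """
    values = saliency.values if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    if values.size == 0:
        raise ValueError("empty saliency map")
    vmax = values.max()
    if vmax == values.min() and values.size > 1:
        raise ValueError("constant saliency map: center is ambiguous")
    ys, xs = np.nonzero(values == vmax)
    return CenterPoint(x=round_half_down(xs.mean()), y=round_half_down(ys.mean()))


def center_error(p: CenterPoint, q: CenterPoint) -> int:
    """L1 distance ``|x - x0| + |y - y0|`` between two centers."""
    return abs(p.x - q.x) + abs(p.y - q.y)


def is_center_correct(err: int, threshold: int = CENTER_ERROR_THRESHOLD) -> bool:
    """A localization is correct when the L1 error is strictly below threshold."""
    return err < threshold
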