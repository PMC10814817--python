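"""Square sub-image windows around target discs.

Windows are half-open ``[top, top+size) x [left, left+size)`` in 0-based row /
column coordinates and are always clamped fully inside the image.  Sub-image
predictions are pasted back into a full-size canvas with
:func:`restore_to_full`; the window used for each disc is recorded so that the
restoration is exact.

Two localization routes produce windows: :func:`window_from_center` around a
center recovered from a saliency map, and :func:`scanning_localize`, the
baseline that slides a window over the image bottom-up and stops when the
predicted disc area no longer changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

from .saliency import CenterPoint

__all__ = [
    "CropWindow",
    "window_from_center",
    "crop",
    "restore_to_full",
    "scanning_localize",
    "NoDiscFoundError",
]


class NoDiscFoundError(RuntimeError):
    """The scanning baseline found no window with predicted foreground."""


@dataclass(frozen=True)
class CropWindow:
    top: int
    left: int
    size: int

    def slices(self) -> Tuple[slice, slice]:
        return (slice(self.top, self.top + self.size), slice(self.left, self.left + self.size))

    def contains_mask(self, mask: np.ndarray) -> bool:
        """True when every foreground pixel of ``mask`` lies inside the window."""
        ys, xs = np.nonzero(mask)
        if ys.size == 0:
            return True
        return bool(
            (ys >= self.top).all()
            and (ys < self.top + self.size).all()
            and (xs >= self.left).all()
            and (xs < self.left + self.size).all()
        )


def window_from_center(center: CenterPoint, size: int, image_shape: Tuple[int, int]) -> CropWindow:
    """Center a ``size`` x ``size`` window on ``center``, clamped into bounds.

    For even sizes the center lands at offset ``size // 2`` inside the window
    (bias toward top-left).
    """
    h, w = image_shape
    if size > min(h, w):
        raise ValueError(f"window size {size} exceeds image shape {image_shape}")
    top = min(max(center.y - size // 2, 0), h - size)
    left = min(max(center.x - size // 2, 0), w - size)
    return CropWindow(top=top, left=left, size=size)


def crop(grid: np.ndarray, window: CropWindow) -> np.ndarray:
    """Exact half-open slice of an image or mask; no resampling."""
    h, w = grid.shape[-2:]
    if not (0 <= window.top <= h - window.size and 0 <= window.left <= w - window.size):
        raise ValueError(f"window {window} out of bounds for shape {(h, w)}")
    return grid[..., window.slices()[0], window.slices()[1]].copy()


def restore_to_full(sub_mask: np.ndarray, window: CropWindow, full_shape: Tuple[int, int]) -> np.ndarray:
    """Place a sub-image mask back at its original position in a zero canvas."""
    if sub_mask.shape != (window.size, window.size):
        raise ValueError(
            f"sub-mask shape {sub_mask.shape} does not match window size {window.size}"
        )
    full = np.zeros(full_shape, dtype=sub_mask.dtype)
    full[window.slices()] = sub_mask
    return full


def _predict_fn(model) -> Callable[[np.ndarray], np.ndarray]:
    if callable(model):
        return model
    # SegModel route: probability map binarized at the model's default threshold
    from .model import binarize_map

    return lambda sub: binarize_map(model.predict(sub[None])[0], 0.5)


def scanning_localize(
    image: np.ndarray,
    model,
    size: int,
    stride: int = 32,
    area_tol: int = 0,
) -> CropWindow:
    """Baseline localization by scanning windows left-to-right, bottom-to-top.

    The predicted foreground area is tracked along the scan; the first window
    whose (nonzero) area differs from the previous window's by at most
    ``area_tol`` pixels is returned — the disc no longer changes, so it is
    fully contained.  If the area never stabilizes the maximal-area window is
    returned with a warning; if every window predicts an empty mask a
    :class:`NoDiscFoundError` is raised.

    ``model`` is either a ``SegModel`` or any callable mapping a sub-image to
    a binary mask (tests use the ground-truth oracle).
    """
    h, w = image.shape
    if size > min(h, w):
        raise ValueError("scan window larger than image")
    predict = _predict_fn(model)

    tops = list(range(h - size, -1, -stride))
    if tops[-1] != 0:
        tops.append(0)
    lefts = list(range(0, w - size + 1, stride))
    if lefts[-1] != w - size:
        lefts.append(w - size)

    prev_area = None
    best: Tuple[int, CropWindow] | None = None
    for top in tops:  # bottom row of window positions first
        for left in lefts:
            win = CropWindow(top=top, left=left, size=size)
            area = int(np.count_nonzero(predict(crop(image, win))))
            if area > 0 and prev_area is not None and prev_area > 0 and abs(area - prev_area) <= area_tol:
                return win
            if best is None or area > best[0]:
                best = (area, win)
            prev_area = area
    if best is None or best[0] == 0:
        raise NoDiscFoundError("no window produced a nonempty predicted mask")
    warnings.warn("predicted disc area never stabilized; returning maximal-area window")
    return best[1]
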