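"""Distance-map channels derived from already-segmented lower discs.

Once the two lower target discs (L4/L5 and L5/S1) are segmented, their
positions become auxiliary information for finding the upper target (L1/L2)
among its look-alike neighbours.  Each segmented disc yields a distance map:
zero at the disc's center point, growing with Euclidean distance, normalized
to [0, 1] by the per-image maximum.  The two maps are stacked with the
original image into a 3-channel input for the third-stage model.

The distance map to a center is the exact complement of the ``n = 2``
saliency target: ``distance + saliency = 1`` everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .saliency import CenterPoint, mask_centroid

__all__ = ["DistanceMap", "MultiChannelImage", "compute_distance_map", "stack_channels"]

#: fixed channel order of the stage-3 input
CHANNEL_ORDER = ("image", "distmap_L4L5", "distmap_L5S1")


@dataclass(frozen=True)
class DistanceMap:
    values: np.ndarray
    source_center: CenterPoint


@dataclass(frozen=True)
class MultiChannelImage:
    """Stage-3 input: ``(image, distmap_L4L5, distmap_L5S1)`` stacked first-axis."""

    channels: np.ndarray  # (3, H, W)

    @property
    def image(self) -> np.ndarray:
        return self.channels[0]

    @property
    def distmap_l4l5(self) -> np.ndarray:
        return self.channels[1]

    @property
    def distmap_l5s1(self) -> np.ndarray:
        return self.channels[2]


def compute_distance_map(mask: np.ndarray, shape: Tuple[int, int] | None = None) -> DistanceMap:
    """Normalized Euclidean distance to the mask's (rounded) centroid.

    Raises ``ValueError`` on an empty mask — an empty stage-2 prediction has
    no center, and the pipeline records the image as a failure instead.
    """
    if not np.any(mask):
        raise ValueError("cannot build a distance map from an empty mask")
    center = mask_centroid(mask)
    if shape is None:
        shape = mask.shape
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    d = np.sqrt((xx - center.x) ** 2.0 + (yy - center.y) ** 2.0)
    m = d.max()
    values = d / m if m > 0 else d
    return DistanceMap(values=values, source_center=center)


def stack_channels(image: np.ndarray, map_l4l5: DistanceMap, map_l5s1: DistanceMap) -> MultiChannelImage:
    """Stack the image with the two lower-disc distance maps, fixed order."""
    if image.shape != map_l4l5.values.shape or image.shape != map_l5s1.values.shape:
        raise ValueError(
            "shape mismatch between image and distance maps: "
            f"{image.shape}, {map_l4l5.values.shape}, {map_l5s1.values.shape}"
        )
    return MultiChannelImage(
        channels=np.stack([image, map_l4l5.values, map_l5s1.values]).astype(np.float32)
    )
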