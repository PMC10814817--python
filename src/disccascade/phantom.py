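"""Synthetic midsagittal spine phantoms with per-target annotations.

The cascade is designed for a hard instance-selection problem: a vertical
column of many nearly identical bright elliptical discs separated by darker
vertebral tissue, of which only three specific levels are wanted — the two
adjacent lowest discs (analogs of L5/S1 and L4/L5) and one disc several
levels up (analog of L1/L2) surrounded by look-alikes.  The generator renders
exactly that statistical structure:

* ``n_discs`` rotated ellipses on a smoothly bowed vertebral column,
* per-disc intensity, size, tilt and spacing jitter,
* a random global vertical offset of the whole column (patient positioning),
* additive Gaussian noise, clipped to [0, 1].

Ground truth consists of one binary mask per designated target and its center
point (rounded mask centroid).  Non-target discs are rendered but not
annotated — they are the distractors that make the third stage nontrivial.

Also provided: the conservative sample-size formula ``ceil((z·sigma/m)^2)``
used to justify a dataset size from a confidence-interval requirement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .labels import DISC_LABELS
from .saliency import CenterPoint, mask_centroid

__all__ = [
    "PhantomConfig",
    "AnnotatedSample",
    "generate_sample",
    "generate_dataset",
    "conservative_sample_size",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and photometry of the spine phantom.

    Lengths are in pixels; ranges are inclusive ``(low, high)`` intervals
    sampled uniformly per disc or per sample.  ``target_indices`` count discs
    from the bottom of the column starting at 1; the defaults (1, 2, 5) mirror
    the clinical targets L5/S1, L4/L5 and L1/L2.
    """

    image_size: int = 512
    n_discs: int = 7
    target_indices: Tuple[int, int, int] = (1, 2, 5)
    disc_semi_width: Tuple[float, float] = (44.0, 54.0)   # horizontal semi-axis
    disc_semi_height: Tuple[float, float] = (20.0, 23.0)  # vertical semi-axis
    disc_gap: Tuple[float, float] = (14.0, 18.0)          # vertebra height between discs
    # distance from the image bottom to the lowest disc center: sacral anatomy
    # sits below L5/S1, so the disc column ends well above the image border
    bottom_margin: Tuple[float, float] = (152.0, 184.0)
    curvature: float = 24.0                               # max lateral bow of the column
    rotation_deg: float = 6.0                             # per-disc tilt, uniform +/- range
    noise_sigma: float = 0.03
    disc_intensity: Tuple[float, float] = (0.70, 0.95)
    vertebra_intensity: Tuple[float, float] = (0.30, 0.50)
    background_intensity: Tuple[float, float] = (0.05, 0.20)
    seed: int = 0

    @classmethod
    def desk(cls, **overrides) -> "PhantomConfig":
        """Quarter-scale profile (128 px) with proportionally scaled geometry."""
        params = dict(
            image_size=128,
            disc_semi_width=(11.0, 13.5),
            disc_semi_height=(5.0, 5.75),
            disc_gap=(3.5, 4.5),
            bottom_margin=(34.0, 42.0),
            curvature=6.0,
        )
        params.update(overrides)
        return cls(**params)

    def validate(self) -> None:
        if self.n_discs < 7:
            raise ValueError("phantom requires at least 7 discs")
        idx = self.target_indices
        if len(set(idx)) != 3 or not all(1 <= i <= self.n_discs for i in idx):
            raise ValueError("target_indices must be three distinct indices in [1, n_discs]")
        if max(idx) > self.n_discs - 2:
            raise ValueError(
                "need at least two discs above the top target to act as distractors"
            )
        for name in ("disc_semi_width", "disc_semi_height", "disc_gap",
                     "disc_intensity", "vertebra_intensity", "background_intensity"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


@dataclass
class AnnotatedSample:
    """One phantom image with per-target masks and centers."""

    image: np.ndarray                 # (H, W) float32 in [0, 1]
    masks: Dict[str, np.ndarray]      # label -> (H, W) bool, pairwise disjoint
    centers: Dict[str, CenterPoint]   # label -> rounded mask centroid
    meta: dict = field(default_factory=dict)


def _target_label_map(cfg: PhantomConfig) -> Dict[int, str]:
    # smallest index = lowest disc = L5/S1; largest = upper target = L1/L2
    lo, mid, hi = sorted(cfg.target_indices)
    return {lo: "L5S1", mid: "L4L5", hi: "L1L2"}


def generate_sample(cfg: PhantomConfig, seed: int | None = None) -> AnnotatedSample:
    """Render one annotated phantom, deterministic in ``(cfg, seed)``."""
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    H = W = cfg.image_size

    n = cfg.n_discs
    a = rng.uniform(*cfg.disc_semi_width, size=n)
    b = rng.uniform(*cfg.disc_semi_height, size=n)
    gap = rng.uniform(*cfg.disc_gap, size=n - 1)
    tilt = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg, size=n))
    disc_val = rng.uniform(*cfg.disc_intensity, size=n)
    vert_val = rng.uniform(*cfg.vertebra_intensity)
    bg_val = rng.uniform(*cfg.background_intensity)

    # vertical placement, bottom disc first.  The column is anchored above a
    # bottom margin (sacral region); discs beyond the topmost target may run
    # off the top of the image, as thoracic levels do in real scans.
    spacing = b[:-1] + b[1:] + gap
    bottom_margin = rng.uniform(*cfg.bottom_margin)
    ys = (H - 1.0 - bottom_margin) - np.concatenate([[0.0], np.cumsum(spacing)])
    top_target = max(cfg.target_indices)  # 1-based from the bottom
    reach = b + a * math.sin(np.deg2rad(cfg.rotation_deg))
    if ys[top_target - 1] - reach[top_target - 1] < 2.0:
        raise ValueError(
            f"cannot fit the top target disc (index {top_target}) in an image of "
            f"{H} px with this geometry; reduce sizes, gaps or bottom_margin"
        )
    if ys[top_target] < 3.0:  # first distractor above must stay visible
        raise ValueError(
            "cannot fit a visible distractor disc above the top target; "
            "reduce sizes, gaps or bottom_margin"
        )

    # bowed centerline: zero offset at column ends, maximal at mid-column
    cx = W / 2.0 + rng.uniform(-0.06 * W, 0.06 * W)
    bow = rng.uniform(-cfg.curvature, cfg.curvature)
    t = (ys - ys[-1]) / (ys[0] - ys[-1])  # 1 at bottom disc, 0 at top disc
    xs = cx + bow * 4.0 * t * (1.0 - t)

    image = np.full((H, W), bg_val, dtype=np.float64)
    band_half = float(a.mean()) * 1.1
    row_t = np.clip((np.arange(H) - ys[-1]) / (ys[0] - ys[-1]), 0.0, 1.0)
    col_x = cx + bow * 4.0 * row_t * (1.0 - row_t)
    col_rows = (np.arange(H) >= ys[-1] - b[-1] - gap.mean()) & (
        np.arange(H) <= ys[0] + b[0] + gap.mean()
    )
    xx = np.arange(W)[None, :]
    band = col_rows[:, None] & (np.abs(xx - col_x[:, None]) <= band_half)
    image[band] = vert_val

    label_of = _target_label_map(cfg)
    masks: Dict[str, np.ndarray] = {}
    for k in range(n):  # k = 0 is the bottom disc, index k+1 from the bottom
        rr, cc = draw_ellipse(ys[k], xs[k], b[k], a[k], shape=(H, W), rotation=tilt[k])
        image[rr, cc] = disc_val[k]
        if (k + 1) in label_of:
            m = np.zeros((H, W), dtype=bool)
            m[rr, cc] = True
            masks[label_of[k + 1]] = m

    if cfg.noise_sigma > 0:
        image = image + rng.normal(0.0, cfg.noise_sigma, size=(H, W))
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    masks = {k: masks[k] for k in DISC_LABELS}
    centers = {k: mask_centroid(m) for k, m in masks.items()}
    _check_sample_invariants(masks)
    return AnnotatedSample(
        image=image,
        masks=masks,
        centers=centers,
        meta={
            "seed": int(seed),
            "config": asdict(cfg),
            # rendered positions of ALL discs (bottom first), targets included —
            # lets tests verify that distractor discs surround the upper target
            "disc_centers_xy": [(float(x), float(y)) for x, y in zip(xs, ys)],
        },
    )


def _check_sample_invariants(masks: Dict[str, np.ndarray]) -> None:
    from skimage.measure import label as cc_label

    total = np.zeros_like(next(iter(masks.values())), dtype=np.int32)
    for name, m in masks.items():
        if not m.any():
            raise RuntimeError(f"generated mask {name} is empty")
        if cc_label(m, connectivity=2).max() != 1:
            raise RuntimeError(f"generated mask {name} is not a single component")
        total += m
    if total.max() > 1:
        raise RuntimeError("generated target masks overlap")


def generate_dataset(n: int, cfg: PhantomConfig, seed: int = 0) -> List[AnnotatedSample]:
    """Generate ``n`` samples with per-sample seeds derived from ``(seed, i)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_sample(cfg, seed=(seed * 100003 + i) % (2**31)) for i in range(n)]


def conservative_sample_size(z: float, sigma: float, margin: float) -> int:
    """Most conservative sample size ``ceil((z * sigma / margin)^2)``.

    For a 95% confidence level (z = 1.96), standard deviation 0.01 and a
    margin of error of 0.0004 this gives 2401 (~2400 images).
    """
    if z <= 0 or sigma <= 0 or margin <= 0:
        raise ValueError("z, sigma and margin must all be positive")
    val = (z * sigma / margin) ** 2
    nearest = round(val)
    if abs(val - nearest) < 1e-6 * max(1.0, abs(val)):
        return int(nearest)
    return int(math.ceil(val))
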