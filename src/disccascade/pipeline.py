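"""Three-stage cascade: localize lower discs, segment them, then find L1/L2.

Training (all supervision from ground-truth annotation):

1. Model 1 regresses one saliency channel per lower target disc (L4/L5,
   L5/S1) from the full image.
2. Model 2 segments a single disc inside a square sub-image cropped around
   the (ground-truth) disc center.
3. Model 3 segments the upper target (L1/L2) from the image stacked with the
   two lower-disc distance maps computed from ground-truth masks.

Testing replaces every ground-truth ingredient by the previous stage's
prediction: centers come from predicted saliency maps, distance maps from
predicted lower masks.  This train/test asymmetry for stage 3 is deliberate
and kept.  A branch that fails (ambiguous saliency, empty stage-2 mask)
yields an empty mask plus a failure flag instead of an exception, so the
evaluation can count the image as an error.

The networks may run at a reduced internal resolution (``stage1_size`` /
``stage3_size``): inputs are downsampled bilinearly and predicted probability
maps upsampled back before thresholding.  Stage 2 always works at the native
crop resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize

from .cropping import CropWindow, crop, restore_to_full, window_from_center
from .distance import compute_distance_map, stack_channels
from .labels import DISC_LABELS, LOWER_LABELS, UPPER_LABEL
from .model import ModelConfig, SegModel, TrainConfig, binarize_map, build_model, train_model
from .phantom import AnnotatedSample
from .saliency import CenterPoint, compute_saliency_target, extract_center

__all__ = [
    "PipelineConfig",
    "PipelineBundle",
    "DiscPrediction",
    "train_pipeline",
    "predict_discs",
    "integrate_masks",
    "train_upper_model",
    "predict_upper",
]

#: integration label values, low priority first
LABEL_VALUES = {"L1L2": 1, "L4L5": 2, "L5S1": 3}


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the cascade; profiles differ only in scale."""

    image_size: int = 512
    crop_size: int = 256
    saliency_n: int = 3
    exponent_mode: str = "root"
    binarize_threshold: float = 0.5
    # Gaussian sigma applied to predicted saliency maps before the argmax
    # extraction; suppresses single-pixel argmax jitter (0 = off)
    saliency_smooth_sigma: float = 2.0
    stage1_size: Optional[int] = None  # network resolution; None = native
    stage3_size: Optional[int] = None
    # stage-2 crops are trained with the window center jittered around the
    # ground-truth center so the model tolerates stage-1 localization error
    crop_jitter: int = 24
    base_filters: int = 32
    depth: int = 4
    # stage 3 may use a shallower net: its receptive field should mirror the
    # full-scale situation where no pixel sees both the sacrum and L1/L2
    stage3_depth: Optional[int] = None
    alpha: float = 1.67
    arch: str = "multires"
    max_respath_len: int = 4
    epochs1: int = 500
    epochs2: int = 500
    epochs3: int = 500
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0

    @classmethod
    def desk(cls, **overrides) -> "PipelineConfig":
        """Quarter-scale profile used by the test suite (CPU-friendly)."""
        params = dict(
            image_size=128,
            crop_size=64,
            stage1_size=64,
            stage3_size=64,
            crop_jitter=4,
            base_filters=8,
            depth=3,
            stage3_depth=1,
            max_respath_len=1,
            epochs1=15,
            epochs2=16,
            epochs3=15,
            learning_rate=2e-3,
        )
        params.update(overrides)
        return cls(**params)

    def model_config(self, stage: int) -> ModelConfig:
        in_ch = {1: 1, 2: 1, 3: 3}[stage]
        out_ch = {1: 2, 2: 1, 3: 1}[stage]
        depth = self.depth
        if stage == 3 and self.stage3_depth is not None:
            depth = self.stage3_depth
        return ModelConfig(
            in_channels=in_ch,
            out_channels=out_ch,
            base_filters=self.base_filters,
            depth=depth,
            alpha=self.alpha,
            arch=self.arch,
            max_respath_len=self.max_respath_len,
            seed=self.seed + stage,
        )

    def train_config(self, stage: int) -> TrainConfig:
        return TrainConfig(
            epochs={1: self.epochs1, 2: self.epochs2, 3: self.epochs3}[stage],
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            loss="mse" if stage == 1 else "bce_dice",
            seed=self.seed + 10 * stage,
        )


@dataclass
class PipelineBundle:
    model1: SegModel
    model2: SegModel
    model3: SegModel
    config: PipelineConfig


@dataclass
class DiscPrediction:
    """Per-image cascade output: three full-size masks plus provenance."""

    masks: Dict[str, np.ndarray]
    windows: Dict[str, CropWindow] = field(default_factory=dict)
    centers: Dict[str, CenterPoint] = field(default_factory=dict)
    failures: Dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _resize_grid(grid: np.ndarray, size: int) -> np.ndarray:
    if grid.shape[-1] == size:
        return grid.astype(np.float32)
    if grid.ndim == 2:
        return resize(grid, (size, size), order=1, anti_aliasing=False).astype(np.float32)
    return np.stack(
        [resize(c, (size, size), order=1, anti_aliasing=False) for c in grid]
    ).astype(np.float32)


def _scale_center(c: CenterPoint, factor: float) -> CenterPoint:
    return CenterPoint(x=int(c.x * factor), y=int(c.y * factor))


def train_pipeline(samples: Sequence[AnnotatedSample], cfg: PipelineConfig) -> PipelineBundle:
    """Train the three models from annotated samples, fully seeded.

    Stage 2 sees one sub-image per lower disc per sample (2 N pairs).
    """
    for i, s in enumerate(samples):
        missing = [k for k in DISC_LABELS if k not in s.masks]
        if missing:
            raise ValueError(f"sample {i} lacks masks for {missing}")

    model1 = build_model(cfg.model_config(1))
    model1.stage = "saliency"
    train_model(model1, stage1_pairs(samples, cfg), cfg.train_config(1))

    model2 = build_model(cfg.model_config(2))
    model2.stage = "subimage-segmentation"
    train_model(model2, stage2_pairs(samples, cfg), cfg.train_config(2))

    # stage 3: image + ground-truth distance maps -> upper disc mask
    model3 = train_upper_model(samples, cfg, with_distance=True)

    return PipelineBundle(model1=model1, model2=model2, model3=model3, config=cfg)


def stage1_pairs(samples: Sequence[AnnotatedSample], cfg: PipelineConfig):
    """(image, 2-channel saliency target) training pairs for model 1."""
    h = cfg.image_size
    s1 = cfg.stage1_size or h
    factor1 = s1 / h
    pairs = []
    for s in samples:
        target = np.stack(
            [
                compute_saliency_target(
                    _scale_center(s.centers[k], factor1), (s1, s1), cfg.saliency_n,
                    cfg.exponent_mode,
                ).values
                for k in LOWER_LABELS
            ]
        )
        pairs.append((_resize_grid(s.image, s1)[None], target.astype(np.float32)))
    return pairs


def stage2_pairs(samples: Sequence[AnnotatedSample], cfg: PipelineConfig):
    """(sub-image, sub-mask) pairs around lower-disc centers — one per lower
    disc per sample, hence 2 N pairs.

    The window center is jittered uniformly within ``crop_jitter`` px of the
    ground-truth center (seeded), so the segmenter sees discs at the kind of
    offsets the saliency localization produces at test time.
    """
    rng = np.random.default_rng(cfg.seed + 20_000)
    j = cfg.crop_jitter
    pairs = []
    for s in samples:
        for k in LOWER_LABELS:
            c = s.centers[k]
            if j > 0:
                dx, dy = rng.integers(-j, j + 1, size=2)
                c = CenterPoint(
                    x=int(np.clip(c.x + dx, 0, s.image.shape[1] - 1)),
                    y=int(np.clip(c.y + dy, 0, s.image.shape[0] - 1)),
                )
            win = window_from_center(c, cfg.crop_size, s.image.shape)
            pairs.append(
                (crop(s.image, win)[None], crop(s.masks[k], win)[None].astype(np.float32))
            )
    return pairs


def train_upper_model(
    samples: Sequence[AnnotatedSample], cfg: PipelineConfig, with_distance: bool = True
) -> SegModel:
    """Train the stage-3 model; ``with_distance=False`` is the ablation arm
    (image-only input, otherwise identical)."""
    h = cfg.image_size
    s3 = cfg.stage3_size or h
    pairs3 = []
    for s in samples:
        if with_distance:
            stacked = stack_channels(
                s.image,
                compute_distance_map(s.masks["L4L5"]),
                compute_distance_map(s.masks["L5S1"]),
            ).channels
        else:
            stacked = s.image[None]
        target = _resize_grid(s.masks[UPPER_LABEL].astype(np.float32), s3) >= 0.5
        pairs3.append((_resize_grid(stacked, s3), target[None].astype(np.float32)))
    mc = cfg.model_config(3)
    if not with_distance:
        mc = replace(mc, in_channels=1)
    model3 = build_model(mc)
    model3.stage = "distance-augmented" if with_distance else "image-only"
    train_model(model3, pairs3, cfg.train_config(3))
    return model3


def predict_discs(bundle: PipelineBundle, image: np.ndarray) -> DiscPrediction:
    """Run the full testing cascade on one image."""
    cfg = bundle.config
    h = cfg.image_size
    if image.shape != (h, h):
        raise ValueError(f"expected image of shape {(h, h)}, got {image.shape}")
    pred = DiscPrediction(masks={k: np.zeros((h, h), dtype=bool) for k in DISC_LABELS})

    # stage 1: saliency -> centers
    s1 = cfg.stage1_size or h
    prob1 = bundle.model1.predict(_resize_grid(image, s1)[None])
    for ch, k in enumerate(LOWER_LABELS):
        sal = _resize_grid(prob1[ch], h)
        if cfg.saliency_smooth_sigma > 0:
            from scipy.ndimage import gaussian_filter

            sal = gaussian_filter(sal, cfg.saliency_smooth_sigma)
        try:
            pred.centers[k] = extract_center(sal)
        except ValueError as e:
            pred.failures[k] = f"stage1: {e}"

    # stage 2: crop -> segment -> restore
    for k in LOWER_LABELS:
        if k not in pred.centers:
            continue
        win = window_from_center(pred.centers[k], cfg.crop_size, image.shape)
        pred.windows[k] = win
        prob = bundle.model2.predict(crop(image, win)[None])[0]
        sub = binarize_map(prob, cfg.binarize_threshold)
        if not sub.any():
            pred.failures[k] = "stage2: empty predicted mask"
            continue
        pred.masks[k] = restore_to_full(sub, win, image.shape)

    # stage 3: distance maps from predicted lower masks -> upper disc
    upper = predict_upper(
        bundle.model3,
        image,
        lower_masks={k: pred.masks[k] for k in LOWER_LABELS},
        cfg=cfg,
    )
    if upper is None:
        pred.failures[UPPER_LABEL] = "stage3: lower-disc mask missing, distance map undefined"
    else:
        pred.masks[UPPER_LABEL] = upper
        if not upper.any():
            pred.failures[UPPER_LABEL] = "stage3: empty predicted mask"
    return pred


def predict_upper(
    model3: SegModel,
    image: np.ndarray,
    lower_masks: Optional[Dict[str, np.ndarray]] = None,
    cfg: Optional[PipelineConfig] = None,
) -> Optional[np.ndarray]:
    """Stage-3 prediction; returns None when a needed lower mask is empty.

    With an image-only (ablation) model, ``lower_masks`` is ignored.
    """
    h = image.shape[0]
    s3 = (cfg.stage3_size if cfg else None) or h
    thr = cfg.binarize_threshold if cfg else 0.5
    if model3.config.in_channels == 3:
        if lower_masks is None or any(
            not lower_masks.get(k, np.zeros(1)).any() for k in LOWER_LABELS
        ):
            return None
        stacked = stack_channels(
            image,
            compute_distance_map(lower_masks["L4L5"]),
            compute_distance_map(lower_masks["L5S1"]),
        ).channels
    else:
        stacked = image[None]
    prob = model3.predict(_resize_grid(stacked, s3))[0]
    return binarize_map(_resize_grid(prob, h), thr)


def integrate_masks(masks: Dict[str, np.ndarray]) -> Tuple[np.ndarray, int]:
    """Merge per-disc masks into one labeled grid.

    Labels: 0 background, 1 L1/L2, 2 L4/L5, 3 L5/S1.  Overlapping pixels go
    to the higher-priority (lower) disc; the overlap pixel count is returned.
    """
    shapes = {m.shape for m in masks.values()}
    if len(shapes) != 1:
        raise ValueError("masks must share one shape")
    out = np.zeros(next(iter(shapes)), dtype=np.uint8)
    count = np.zeros_like(out)
    for k in ("L1L2", "L4L5", "L5S1"):  # ascending priority
        m = masks[k].astype(bool)
        out[m] = LABEL_VALUES[k]
        count += m
    return out, int((count > 1).sum())
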