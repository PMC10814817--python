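"""Segmentation model surface shared by the three cascade stages.

A :class:`SegModel` wraps a U-shaped convolutional backbone (MultiResUNet by
default, plain U-Net as an alternative) behind a stage-agnostic contract:
inputs are ``(C_in, H, W)`` grids in [0, 1], outputs are ``(C_out, H, W)``
probability maps in [0, 1].  Stage 1 regresses two saliency channels with an
MSE loss; stages 2 and 3 segment a single disc with BCE + Dice.  Training is
plain mini-batch Adam, fully seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Sequence, Tuple

import numpy as np

from .nn.backbones import EncoderDecoderNet
from .nn.losses import LOSSES, sigmoid
from .nn.optim import Adam

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "SegModel",
    "build_model",
    "train_model",
    "predict_map",
    "binarize_map",
]


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 1
    out_channels: int = 1
    base_filters: int = 32
    depth: int = 4
    alpha: float = 1.67
    arch: str = "multires"  # or "unet"
    max_respath_len: int = 4  # reference skip-path lengths are depth-level, capped here
    seed: int = 0

    def validate(self) -> None:
        if min(self.in_channels, self.out_channels, self.base_filters, self.depth) < 1:
            raise ValueError("all ModelConfig counts must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 500
    batch_size: int = 8
    learning_rate: float = 1e-3
    loss: str = "bce_dice"  # mse | bce | bce_dice
    seed: int = 0
    device: str = "cpu"

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}; choose from {sorted(LOSSES)}")


@dataclass
class SegModel:
    """Opaque trained predictor with its configuration and history."""

    net: EncoderDecoderNet
    config: ModelConfig
    stage: str = ""
    history: List[float] = field(default_factory=list)

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.net.params()))

    def predict(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Probability maps for a batch ``(N, C_in, H, W)`` (or one sample)."""
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {x.shape[1]}"
            )
        outs = []
        for i in range(0, len(x), batch_size):
            logits = self.net.forward(x[i : i + batch_size].astype(np.float32), train=False)
            outs.append(sigmoid(logits))
        out = np.concatenate(outs)
        return out[0] if single else out

    # -- checkpointing ----------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.net.params())}
        bns = _bn_layers(self.net)
        for i, bn in enumerate(bns):
            arrays[f"rm{i}"] = bn.running_mean
            arrays[f"rv{i}"] = bn.running_var
        meta = {"config": asdict(self.config), "stage": self.stage, "history": self.history}
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "SegModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        model = build_model(ModelConfig(**meta["config"]))
        for i, p in enumerate(model.net.params()):
            p.value[...] = data[f"p{i}"]
        for i, bn in enumerate(_bn_layers(model.net)):
            bn.running_mean[...] = data[f"rm{i}"]
            bn.running_var[...] = data[f"rv{i}"]
        model.stage = meta["stage"]
        model.history = list(meta["history"])
        return model


def _bn_layers(net) -> list:
    from .nn.layers import BatchNorm2d

    found = []
    seen = set()

    def walk(obj):
        if id(obj) in seen:
            return
        seen.add(id(obj))
        if isinstance(obj, BatchNorm2d):
            found.append(obj)
            return
        if isinstance(obj, dict):
            for v in obj.values():
                walk(v)
            return
        if isinstance(obj, (list, tuple)):
            for v in obj:
                walk(v)
            return
        if hasattr(obj, "__dict__"):
            for v in vars(obj).values():
                walk(v)

    walk(net)
    return found


def build_model(cfg: ModelConfig) -> SegModel:
    """Instantiate a backbone with seeded He initialization."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    net = EncoderDecoderNet(
        cfg.in_channels, cfg.out_channels, cfg.base_filters, cfg.depth, cfg.alpha,
        cfg.arch, rng, max_respath_len=cfg.max_respath_len,
    )
    return SegModel(net=net, config=cfg)


def train_model(
    model: SegModel,
    pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
) -> SegModel:
    """Mini-batch Adam training; appends per-epoch mean loss to the history.

    ``pairs`` holds ``(input (C_in,H,W), target (C_out,H,W))`` float grids.
    Training aborts with a diagnostic on NaN loss.
    """
    cfg.validate()
    if not pairs:
        raise ValueError("empty training set")
    xs = np.stack([np.asarray(x, dtype=np.float32) for x, _ in pairs])
    ts = np.stack([np.asarray(t, dtype=np.float32) for _, t in pairs])
    if xs.shape[1] != model.config.in_channels or ts.shape[1] != model.config.out_channels:
        raise ValueError(
            f"channel mismatch: inputs {xs.shape[1]} vs {model.config.in_channels}, "
            f"targets {ts.shape[1]} vs {model.config.out_channels}"
        )
    if xs.shape[2:] != ts.shape[2:]:
        raise ValueError("input / target spatial shape mismatch")

    loss_fn = LOSSES[cfg.loss]
    opt = Adam(model.net.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    n = len(xs)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            opt.zero_grad()
            logits = model.net.forward(xs[idx], train=True)
            loss, dz = loss_fn(logits, ts[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {len(model.history)}, batch {i}"
                )
            model.net.backward(dz)
            opt.step()
            losses.append(loss)
        model.history.append(float(np.mean(losses)))
    return model


def predict_map(model: SegModel, x: np.ndarray) -> np.ndarray:
    """Probability map(s) for one input grid ``(C_in, H, W)``."""
    return model.predict(x)


def binarize_map(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map: foreground where ``prob >= threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    return np.asarray(prob) >= threshold
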