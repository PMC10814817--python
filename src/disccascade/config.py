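"""Run configuration: one YAML file describes a full reproducible experiment.

A run config bundles the phantom generator settings, the cascade/pipeline
settings, the dataset split and the global seed.  Two profiles exist:

* ``desk``  — 128-px phantoms, 64-px crops, 8 base filters, short training;
  what the test suite exercises on one CPU.
* ``paper`` — 512-px images, 256-px crops, 32 base filters, 500 epochs; the
  full-scale configuration (not run routinely).

Defaults follow the stated protocol constants: saliency power n = 3, IoU
threshold 0.7, center-error threshold 10 px, crop side = half the image side,
train fraction 0.9.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .phantom import PhantomConfig
from .pipeline import PipelineConfig

__all__ = ["RunConfig", "load_run_config"]


@dataclass(frozen=True)
class RunConfig:
    profile: str = "desk"
    phantom: PhantomConfig = field(default_factory=PhantomConfig.desk)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig.desk)
    n_train: int = 200
    n_test: int = 50
    iou_threshold: float = 0.7
    center_error_threshold: int = 10
    bootstrap: int = 0
    seed: int = 0
    out_dir: Optional[str] = None

    @classmethod
    def desk(cls, **overrides) -> "RunConfig":
        return cls(**overrides)

    @classmethod
    def paper(cls, **overrides) -> "RunConfig":
        params = dict(
            profile="paper",
            phantom=PhantomConfig(),
            pipeline=PipelineConfig(),
            n_train=2674,
            n_test=308,
        )
        params.update(overrides)
        return cls(**params)

    def with_seed(self, seed: int) -> "RunConfig":
        from dataclasses import replace

        return replace(
            self,
            seed=seed,
            phantom=type(self.phantom)(**{**asdict(self.phantom), "seed": seed}),
            pipeline=type(self.pipeline)(**{**asdict(self.pipeline), "seed": seed}),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def load_run_config(path) -> RunConfig:
    """Read a YAML run config; the ``profile`` key selects the defaults and
    any other key overrides a field of the corresponding section."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    profile = raw.pop("profile", "desk")
    base = RunConfig.paper() if profile == "paper" else RunConfig.desk()
    phantom_over = raw.pop("phantom", {})
    pipeline_over = raw.pop("pipeline", {})
    phantom = type(base.phantom)(**{**asdict(base.phantom), **phantom_over})
    pipeline = type(base.pipeline)(**{**asdict(base.pipeline), **pipeline_over})
    return RunConfig(
        profile=profile, phantom=phantom, pipeline=pipeline,
        **{**{k: getattr(base, k) for k in
              ("n_train", "n_test", "iou_threshold", "center_error_threshold",
               "bootstrap", "seed", "out_dir")}, **raw},
    )
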