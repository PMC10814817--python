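"""Dataset and model-bundle persistence.

Datasets live in a directory of 8-bit PNG images, 0/255 PNG masks and a
``manifest.json`` listing, per sample: id, file paths, target labels, centers
as 0-based ``[x, y]`` and the generation seed.  Loading validates the
annotation invariants (nonempty, single-component, pairwise-disjoint masks)
and returns samples ordered by id.  Saliency / distance maps, when exported,
go to 32-bit float TIFF.  Trained bundles are a directory of three ``.npz``
checkpoints plus the pipeline configuration as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import List, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .labels import DISC_LABELS
from .model import SegModel
from .phantom import AnnotatedSample, _check_sample_invariants
from .pipeline import PipelineBundle, PipelineConfig
from .saliency import CenterPoint, mask_centroid

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_bundle",
    "load_bundle",
    "write_float_map",
]


def save_dataset(samples: Sequence[AnnotatedSample], out_dir) -> Path:
    """Write images, masks and manifest.json; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(samples):
        sid = f"sample_{i:04d}"
        img_path = f"{sid}.png"
        iio.imwrite(out / img_path, (s.image * 255).round().astype(np.uint8))
        mask_paths = {}
        for k in DISC_LABELS:
            mp = f"{sid}_{k}.png"
            iio.imwrite(out / mp, (s.masks[k].astype(np.uint8)) * 255)
            mask_paths[k] = mp
        entries.append(
            {
                "id": sid,
                "image": img_path,
                "masks": mask_paths,
                "centers": {k: [s.centers[k].x, s.centers[k].y] for k in DISC_LABELS},
                "seed": s.meta.get("seed"),
            }
        )
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"samples": entries}, indent=1))
    return manifest


def _load_gray(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        return arr.astype(np.float32) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float32) / 65535.0
    return arr.astype(np.float32)


def load_dataset(manifest_path) -> List[AnnotatedSample]:
    """Read a dataset back; raises with the sample id on any broken entry."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    entries = json.loads(manifest_path.read_text())["samples"]
    ids = [e["id"] for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in manifest")
    samples = []
    for e in sorted(entries, key=lambda e: e["id"]):
        try:
            image = _load_gray(root / e["image"])
            masks = {}
            for k in DISC_LABELS:
                m = iio.imread(root / e["masks"][k])
                masks[k] = m > 127
                if masks[k].shape != image.shape:
                    raise ValueError("mask/image shape mismatch")
            _check_sample_invariants(masks)
            centers = {k: CenterPoint(*e["centers"][k]) for k in DISC_LABELS}
            for k in DISC_LABELS:
                if centers[k] != mask_centroid(masks[k]):
                    raise ValueError(f"center of {k} does not match mask centroid")
        except Exception as exc:
            raise ValueError(f"invalid sample {e['id']!r}: {exc}") from exc
        samples.append(
            AnnotatedSample(image=image, masks=masks, centers=centers,
                            meta={"id": e["id"], "seed": e.get("seed")})
        )
    return samples


def write_float_map(values: np.ndarray, path) -> None:
    """Serialize a saliency or distance map as 32-bit float TIFF."""
    tifffile.imwrite(path, values.astype(np.float32))


def save_bundle(bundle: PipelineBundle, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.model1.save(out / "model1.npz")
    bundle.model2.save(out / "model2.npz")
    bundle.model3.save(out / "model3.npz")
    (out / "pipeline.json").write_text(json.dumps(asdict(bundle.config), indent=1))
    return out


def load_bundle(run_dir) -> PipelineBundle:
    run_dir = Path(run_dir)
    cfg = PipelineConfig(**json.loads((run_dir / "pipeline.json").read_text()))
    return PipelineBundle(
        model1=SegModel.load(run_dir / "model1.npz"),
        model2=SegModel.load(run_dir / "model2.npz"),
        model3=SegModel.load(run_dir / "model3.npz"),
        config=cfg,
    )
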