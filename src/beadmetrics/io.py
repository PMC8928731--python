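"""Reading and writing scenes (16-bit TIFF/PNG) and ground-truth sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .scenes import GroundTruth, Scene

__all__ = ["save_scene", "load_scene", "save_ground_truth", "load_ground_truth"]


def save_scene(scene: Scene, path: str | Path) -> Path:
    """Write a scene as a single-channel 16-bit image (.tif/.tiff or .png)."""
    path = Path(path)
    raw = np.clip(scene.image, 0.0, 1.0)
    data = np.round(raw * 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, data)
    else:
        raise ValueError(f"unsupported image extension {path.suffix!r}")
    return path


def load_scene(path: str | Path, pixel_size_um: float, modality: str,
               scene_id: str | None = None) -> Scene:
    """Load an 8/16-bit single-channel image and rescale to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    if data.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if np.issubdtype(data.dtype, np.integer):
        img = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        img = data.astype(np.float64)
    return Scene(img, pixel_size_um, modality,
                 scene_id if scene_id is not None else path.stem)


def save_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    return path


def load_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))
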