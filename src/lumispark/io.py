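"""File I/O: multi-page TIFF movies, label-mask/polygon ROIs, JSON/YAML sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml
from skimage import draw

from .phantom.camera import Movie


def save_movie(path, movie: Movie, dtype=np.uint16) -> None:
    """Write a movie as multi-page grayscale TIFF plus a ``.meta.json`` sidecar."""
    path = Path(path)
    frames = movie.frames
    if np.issubdtype(np.dtype(dtype), np.integer):
        frames = np.clip(np.round(frames), 0, np.iinfo(dtype).max)
    tifffile.imwrite(path, frames.astype(dtype), photometric="minisblack")
    meta = {
        "frame_interval": movie.frame_interval,
        "pixel_scale": movie.pixel_scale,
        "channel_label": movie.channel_label,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def load_movie(path) -> Movie:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = (json.loads(meta_path.read_text()) if meta_path.exists()
            else {"frame_interval": 1.0, "pixel_scale": 1.0, "channel_label": ""})
    return Movie(frames.astype(np.float64), **meta)


def save_masks(path, masks: np.ndarray) -> None:
    """Write a (S, H, W) bool stack as a single label-image TIFF (0 = none)."""
    masks = np.asarray(masks, dtype=bool)
    label = np.zeros(masks.shape[1:], dtype=np.uint16)
    for i, m in enumerate(masks, start=1):
        label[m] = i
    tifffile.imwrite(Path(path), label)


def load_masks(path) -> np.ndarray:
    label = tifffile.imread(Path(path))
    n = int(label.max())
    return np.stack([label == i for i in range(1, n + 1)]) if n else \
        np.zeros((0,) + label.shape, dtype=bool)


def polygons_to_masks(polygons, shape) -> np.ndarray:
    """Rasterize ``[{"name": ..., "vertices": [[y, x], ...]}, ...]`` to masks."""
    masks = np.zeros((len(polygons),) + tuple(shape), dtype=bool)
    for i, poly in enumerate(polygons):
        v = np.asarray(poly["vertices"], dtype=float)
        rr, cc = draw.polygon(v[:, 0], v[:, 1], shape=shape)
        masks[i, rr, cc] = True
    return masks


def load_rois(path, shape) -> np.ndarray:
    """Load ROIs from a polygon JSON file or a label-mask TIFF."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return polygons_to_masks(json.loads(path.read_text()), shape)
    return load_masks(path)


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_coerce))


def load_json(path):
    return json.loads(Path(path).read_text())


def save_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def _coerce(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"cannot serialize {type(o)!r}")
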