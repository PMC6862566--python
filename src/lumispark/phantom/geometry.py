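"""Synthetic embryo geometry.

The phantom is a 2-D, binned-camera-frame view of a zebrafish embryo trunk:
a row of rectangular somites laid out along the rostro-caudal (horizontal)
axis, vertically centred in the field of view.  Somite masks partition the
trunk mask, and centroids are expressed in micrometres so that downstream
propagation analysis can work in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EmbryoPhantom:
    """Somite geometry of a synthetic embryo.

    Attributes
    ----------
    somite_centroids : (S, 2) float array
        Somite centroids in µm as (y, x), ordered rostral to caudal.
    somite_masks : (S, H, W) bool array
        Per-somite pixel masks (disjoint).
    trunk_mask : (H, W) bool array
        Union of the somite masks.
    image_shape : tuple of int
        Binned image shape (H, W) in pixels.
    pixel_scale : float
        µm per (binned) pixel.
    """

    somite_centroids: np.ndarray
    somite_masks: np.ndarray
    trunk_mask: np.ndarray
    image_shape: tuple[int, int]
    pixel_scale: float
    somite_size: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.somite_centroids = np.asarray(self.somite_centroids, dtype=float)
        self.somite_masks = np.asarray(self.somite_masks, dtype=bool)
        if self.somite_masks.shape[1:] != tuple(self.image_shape):
            raise ValueError("somite masks do not match image_shape")
        if self.somite_masks.sum(axis=0).max() > 1:
            raise ValueError("somite masks overlap")
        x = self.somite_centroids[:, 1]
        if len(x) > 1 and not np.all(np.diff(x) > 0):
            raise ValueError("somite centroids must increase rostro-caudally")

    @property
    def n_somites(self) -> int:
        return self.somite_masks.shape[0]

    def centroid_distances_mm(self) -> np.ndarray:
        """Distance of each somite centroid from the rostral reference, in mm."""
        ref = self.somite_centroids[0]
        d = np.linalg.norm(self.somite_centroids - ref, axis=1)
        return d / 1000.0


def make_embryo_phantom(
    n_somites: int = 10,
    somite_size: float = 100.0,
    image_shape: tuple[int, int] = (128, 128),
    pixel_scale: float = 12.8,
    aspect: float = 1.5,
) -> EmbryoPhantom:
    """Lay out ``n_somites`` rectangular somites along the horizontal axis.

    Parameters
    ----------
    n_somites : int
        Number of somites (≥ 1).
    somite_size : float
        Rostro-caudal somite extent in µm.
    image_shape : (H, W)
        Binned image shape in pixels.
    pixel_scale : float
        µm per pixel.
    aspect : float
        Dorso-ventral somite extent as a multiple of ``somite_size``.

    Raises
    ------
    ValueError
        If the somite row does not fit in the image; the message names the
        offending dimension.
    """
    if n_somites < 1:
        raise ValueError("n_somites must be >= 1")
    if somite_size <= 0 or pixel_scale <= 0:
        raise ValueError("somite_size and pixel_scale must be positive")
    h, w = image_shape
    size_px = max(1, int(round(somite_size / pixel_scale)))
    height_px = max(1, int(round(aspect * somite_size / pixel_scale)))
    total_w = n_somites * size_px
    if total_w > w:
        raise ValueError(
            f"somite row ({total_w} px) exceeds image width ({w} px)"
        )
    if height_px > h:
        raise ValueError(
            f"somite height ({height_px} px) exceeds image height ({h} px)"
        )
    x0 = (w - total_w) // 2
    y0 = (h - height_px) // 2
    masks = np.zeros((n_somites, h, w), dtype=bool)
    centroids = np.zeros((n_somites, 2), dtype=float)
    for i in range(n_somites):
        left = x0 + i * size_px
        masks[i, y0 : y0 + height_px, left : left + size_px] = True
        cy = (y0 + height_px / 2.0) * pixel_scale
        cx = (left + size_px / 2.0) * pixel_scale
        centroids[i] = (cy, cx)
    return EmbryoPhantom(
        somite_centroids=centroids,
        somite_masks=masks,
        trunk_mask=masks.any(axis=0),
        image_shape=(h, w),
        pixel_scale=pixel_scale,
        somite_size=somite_size,
    )
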