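"""Two-component background model and per-frame detection threshold.

Bioluminescence movies carry two background terms: a *general background*
(GB) from detector noise, estimated on each frame from an artifact-free
region outside the embryo (ROI2), and an *embryo background* (EB) from
spontaneous substrate (coelenterazine) emission over the embryo, estimated
once per experiment from reference frames without visible transients.

GB(frame)  = mean(ROI2 pixels) + 2 × SD(ROI2 pixels)
EB         = mean over reference frames of (mean ROI1 − mean ROI2)
             + 2 × SD of those per-frame differences
threshold(frame) = GB(frame) + EB
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom.geometry import EmbryoPhantom

DEFAULT_N_REFERENCE = 15


@dataclass
class RoiPair:
    """Embryo ROI (ROI1) and an identically sized off-embryo ROI (ROI2)."""

    roi1: np.ndarray
    roi2: np.ndarray

    def __post_init__(self) -> None:
        self.roi1 = np.asarray(self.roi1, dtype=bool)
        self.roi2 = np.asarray(self.roi2, dtype=bool)
        if self.roi1.shape != self.roi2.shape:
            raise ValueError("ROI masks must share one image shape")
        n1, n2 = int(self.roi1.sum()), int(self.roi2.sum())
        if n1 == 0 or n2 == 0:
            raise ValueError("ROIs must be non-empty")
        if n1 != n2:
            raise ValueError(f"ROIs must have equal pixel counts ({n1} != {n2})")
        if np.any(self.roi1 & self.roi2):
            raise ValueError("ROI1 and ROI2 must be disjoint")


@dataclass
class BackgroundEstimate:
    """Per-frame GB, scalar EB and the resulting detection thresholds."""

    gb_per_frame: np.ndarray
    eb: float
    threshold_per_frame: np.ndarray
    reference_frames: np.ndarray

    def __post_init__(self) -> None:
        self.gb_per_frame = np.asarray(self.gb_per_frame, dtype=float)
        self.threshold_per_frame = np.asarray(self.threshold_per_frame, dtype=float)
        if np.any(self.threshold_per_frame < self.gb_per_frame - 1e-9):
            raise ValueError("threshold must not fall below GB")


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def compute_gb(frame: np.ndarray, roi2: np.ndarray) -> float:
    """General background of one frame: mean(ROI2) + 2 × sample SD(ROI2)."""
    roi2 = np.asarray(roi2, dtype=bool)
    px = np.asarray(frame, dtype=float)[roi2]
    if px.size == 0:
        raise ValueError("ROI2 is empty")
    return float(px.mean()) + 2.0 * _sample_sd(px)


def compute_eb(
    frames: np.ndarray,
    roi_pair: RoiPair,
    reference_frames,
    n_reference: int = DEFAULT_N_REFERENCE,
) -> float:
    """Embryo background from transient-free reference frames.

    EB = mean of the per-frame (mean ROI1 − mean ROI2) differences
    + 2 × their sample SD, clamped at zero (a background term cannot be
    negative).
    """
    frames = np.asarray(frames, dtype=float)
    idx = np.asarray(reference_frames, dtype=int)
    if len(idx) < n_reference:
        raise ValueError(
            f"need {n_reference} reference frames, got {len(idx)}"
        )
    if idx.min() < 0 or idx.max() >= frames.shape[0]:
        raise ValueError("reference frame index out of range")
    diffs = np.array([
        frames[i][roi_pair.roi1].mean() - frames[i][roi_pair.roi2].mean()
        for i in idx
    ])
    eb = float(diffs.mean()) + 2.0 * _sample_sd(diffs)
    return max(eb, 0.0)


def select_reference_frames(frames: np.ndarray, roi1: np.ndarray,
                            n: int = DEFAULT_N_REFERENCE) -> np.ndarray:
    """Automatic fallback: the ``n`` frames with lowest ROI1 integrated intensity."""
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < n:
        raise ValueError(f"movie has fewer than {n} frames")
    totals = frames[:, np.asarray(roi1, dtype=bool)].sum(axis=1)
    return np.sort(np.argsort(totals, kind="stable")[:n])


def frame_thresholds(
    frames: np.ndarray,
    roi_pair: RoiPair,
    reference_frames=None,
    n_reference: int = DEFAULT_N_REFERENCE,
) -> BackgroundEstimate:
    """Per-frame detection thresholds: GB(frame) + EB.

    ``reference_frames`` may be given explicitly (the interactive workflow);
    when omitted, the transient-free frames are chosen automatically as the
    ``n_reference`` frames with the lowest ROI1 integrated intensity.
    """
    frames = np.asarray(frames, dtype=float)
    if reference_frames is None:
        reference_frames = select_reference_frames(frames, roi_pair.roi1,
                                                   n_reference)
    reference_frames = np.asarray(reference_frames, dtype=int)
    gb = np.array([compute_gb(f, roi_pair.roi2) for f in frames])
    eb = compute_eb(frames, roi_pair, reference_frames, n_reference)
    return BackgroundEstimate(gb, eb, gb + eb, reference_frames)


def default_roi_pair(phantom: EmbryoPhantom, margin_px: int = 2) -> RoiPair:
    """ROI1 over the trunk and an identically shaped ROI2 above the embryo."""
    trunk = phantom.trunk_mask
    rows = np.where(trunk.any(axis=1))[0]
    height = rows.max() - rows.min() + 1
    shift = height + margin_px
    if rows.min() - shift < 0:
        raise ValueError("no room above the embryo for an off-embryo ROI")
    roi2 = np.roll(trunk, -shift, axis=0)
    return RoiPair(trunk, roi2)
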