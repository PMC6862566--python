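"""Size- and intensity-gated detection of Ca²⁺ transients.

A transient is a connected component of suprathreshold pixels over the
embryo trunk that is larger than 9 adjacent pixels (component size ≥ 10 by
default, 8-connectivity).  Movies reduce to a per-frame integrated-density
trace (sum of raw pixel values over accepted components), which is then
segmented into events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure


@dataclass
class DetectionParams:
    """Component acceptance rule."""

    min_component_size: int = 10  # "larger than 9 adjacent pixels"
    connectivity: int = 8  # 4 or 8, FIJI-style default 8
    restrict_mask: np.ndarray | None = None  # embryo trunk ROI

    def __post_init__(self) -> None:
        if self.min_component_size < 1:
            raise ValueError("min_component_size must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.restrict_mask is not None:
            self.restrict_mask = np.asarray(self.restrict_mask, dtype=bool)


@dataclass
class IntegratedDensityTrace:
    """Per-frame integrated density over accepted components."""

    values: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("integrated density must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.frame_interval


@dataclass
class EventWindow:
    """Inclusive frame span of one detected event."""

    start_frame: int
    end_frame: int
    peak_frame: int

    def __post_init__(self) -> None:
        if not (self.start_frame <= self.peak_frame <= self.end_frame):
            raise ValueError("require start <= peak <= end")


def detect_components(frame: np.ndarray, threshold: float,
                      params: DetectionParams) -> np.ndarray:
    """Label accepted suprathreshold components of one frame.

    Returns an int label image: connected components of pixels strictly above
    ``threshold``, intersected with the restriction mask, with components
    smaller than ``min_component_size`` removed (labels are re-packed to
    1..n).
    """
    frame = np.asarray(frame, dtype=float)
    mask = params.restrict_mask
    if mask is not None and mask.shape != frame.shape:
        raise ValueError("frame and restriction mask shapes differ")
    supra = frame > threshold
    if mask is not None:
        supra &= mask
    conn = 1 if params.connectivity == 4 else 2
    labels = measure.label(supra, connectivity=conn)
    if labels.max() == 0:
        return labels
    sizes = np.bincount(labels.ravel())
    keep = np.where(sizes >= params.min_component_size)[0]
    keep = keep[keep != 0]
    remap = np.zeros(sizes.size, dtype=labels.dtype)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labels]


def integrated_density(
    frames: np.ndarray,
    thresholds,
    params: DetectionParams,
    frame_interval: float = 1.0,
) -> IntegratedDensityTrace:
    """Per-frame sum of raw pixel values over accepted components.

    ``thresholds`` is a scalar or a per-frame sequence (e.g. the
    ``threshold_per_frame`` of a background estimate).  Values are not
    background-subtracted.
    """
    frames = np.asarray(frames, dtype=float)
    thr = np.broadcast_to(np.asarray(thresholds, dtype=float),
                          (frames.shape[0],))
    values = np.empty(frames.shape[0])
    for i, frame in enumerate(frames):
        labels = detect_components(frame, thr[i], params)
        values[i] = frame[labels > 0].sum()
    return IntegratedDensityTrace(values, frame_interval)


def segment_events(values, merge_gap: int = 0,
                   threshold: float = 0.0) -> list[EventWindow]:
    """Segment a trace into events.

    Events are maximal runs of values strictly above ``threshold``; runs
    separated by at most ``merge_gap`` sub-threshold frames are merged.  The
    peak frame is the earliest maximum within the run.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be non-negative")
    values = np.asarray(values, dtype=float)
    above = values > threshold
    runs: list[list[int]] = []
    i = 0
    n = len(values)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    events = []
    for start, end in merged:
        peak = start + int(np.argmax(values[start : end + 1]))
        events.append(EventWindow(start, end, peak))
    return events
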