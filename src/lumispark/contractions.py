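"""Dual-ROI detection of spontaneous contractions in transmitted-light movies.

Two identical ROIs are placed close together, one on a somite inside the
embryo trunk and one outside the embryo; the ratio of their mean intensities
changes whenever a contraction displaces the embryo.  A contraction is a
maximal run of frames where the ratio deviates from its baseline median by
more than k × the scaled median absolute deviation; runs closer together
than the refractory period are merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom.camera import Movie
from .phantom.geometry import EmbryoPhantom

MAD_SCALE = 1.4826  # consistent-with-Gaussian-SD scaling


@dataclass
class ContractionTrace:
    """Per-frame dual-ROI intensity ratio and its baseline statistics."""

    ratio_values: np.ndarray
    frame_interval: float
    baseline_median: float
    baseline_spread: float

    def __post_init__(self) -> None:
        self.ratio_values = np.asarray(self.ratio_values, dtype=float)
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def duration(self) -> float:
        return len(self.ratio_values) * self.frame_interval


def dual_roi_ratio(movie, roi_on_somite: np.ndarray,
                   roi_off_embryo: np.ndarray,
                   frame_interval: float | None = None) -> ContractionTrace:
    """Per-frame ratio of the on-somite and off-embryo ROI means.

    Baseline statistics (median, scaled MAD) are taken over the whole trace,
    since contractions are sparse.
    """
    if isinstance(movie, Movie):
        frames = movie.frames
        dt = movie.frame_interval
    else:
        frames = np.asarray(movie, dtype=float)
        if frame_interval is None:
            raise ValueError("frame_interval required for raw stacks")
        dt = frame_interval
    on = np.asarray(roi_on_somite, dtype=bool)
    off = np.asarray(roi_off_embryo, dtype=bool)
    if on.sum() != off.sum():
        raise ValueError("ROIs must have equal pixel counts")
    num = frames[:, on].mean(axis=1)
    den = frames[:, off].mean(axis=1)
    bad = np.where(den <= 0)[0]
    if bad.size:
        raise ValueError(f"off-embryo ROI mean is zero in frame {bad[0]}")
    ratio = num / den
    med = float(np.median(ratio))
    spread = MAD_SCALE * float(np.median(np.abs(ratio - med)))
    return ContractionTrace(ratio, dt, med, spread)


def detect_contractions(trace: ContractionTrace, k: float = 5.0,
                        refractory: float = 0.5):
    """Detect contraction events on a dual-ROI ratio trace.

    Returns ``(events, frequency)`` where events are inclusive
    ``(start_frame, end_frame)`` pairs and frequency = count / duration (Hz).
    """
    if k <= 0:
        raise ValueError("spread multiplier k must be positive")
    r = trace.ratio_values
    dev = np.abs(r - trace.baseline_median)
    excursion = dev > k * trace.baseline_spread
    events: list[tuple[int, int]] = []
    i, n = 0, len(r)
    while i < n:
        if excursion[i]:
            j = i
            while j + 1 < n and excursion[j + 1]:
                j += 1
            events.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge runs separated by less than the refractory period
    gap_frames = refractory / trace.frame_interval
    merged: list[list[int]] = []
    for s, e in events:
        if merged and (s - merged[-1][1] - 1) < gap_frames:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = [(s, e) for s, e in merged]
    frequency = len(events) / trace.duration
    return events, frequency


def paired_frequency_change(pre_freq, post_freq) -> dict:
    """Descriptive per-embryo percent change between paired frequency measurements.

    Embryos with zero pre-drug frequency are flagged and excluded from the
    percent-change summary.  Returns per-embryo changes plus mean ± SEM.
    """
    pre = np.asarray(pre_freq, dtype=float)
    post = np.asarray(post_freq, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post arrays must have equal length")
    valid = pre > 0
    pct = np.full(pre.shape, np.nan)
    pct[valid] = 100.0 * (post[valid] - pre[valid]) / pre[valid]
    vals = pct[valid]
    n = int(valid.sum())
    return {
        "percent_change": pct,
        "excluded": np.where(~valid)[0].tolist(),
        "n": n,
        "mean": float(vals.mean()) if n else float("nan"),
        "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
    }


def edge_roi_pair(phantom: EmbryoPhantom, roi_height: int = 6,
                  roi_width: int = 10, clearance_px: int = 6):
    """Build the on-somite / off-embryo ROI pair for contraction detection.

    The on-ROI straddles the dorsal edge of a central somite (so that a
    lateral displacement of the embryo changes its mean intensity); the
    off-ROI is the same rectangle translated above the embryo, with
    ``clearance_px`` of margin so the displaced embryo never enters it.
    """
    trunk = phantom.trunk_mask
    h, w = trunk.shape
    rows = np.where(trunk.any(axis=1))[0]
    top = rows.min()
    mid = phantom.n_somites // 2
    cols = np.where(phantom.somite_masks[mid].any(axis=0))[0]
    c0 = cols[0] + max(0, (len(cols) - roi_width) // 2)
    r0 = top - roi_height // 2
    on = np.zeros((h, w), dtype=bool)
    on[r0 : r0 + roi_height, c0 : c0 + roi_width] = True
    off_r0 = r0 - roi_height - clearance_px
    if off_r0 < 0:
        raise ValueError("no room above the embryo for the off-ROI")
    off = np.zeros((h, w), dtype=bool)
    off[off_r0 : off_r0 + roi_height, c0 : c0 + roi_width] = True
    if np.any(off & trunk):
        raise ValueError("off-ROI overlaps the embryo")
    return on, off
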