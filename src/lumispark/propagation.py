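"""Rostro-caudal wave quantification: ROI grouping, onsets, speed, amplitude.

Somite ROIs are merged in consecutive groups (of three by default, mirroring
the ROI convention of the propagation experiments), each event's onset in
each grouped ROI is the 50% rising-amplitude crossing (shared definition
with the kinetics module), and the conduction speed is 1/slope of an
ordinary least-squares fit of onset time versus centroid distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import EventWindow, segment_events
from .kinetics import DEFAULT_BASELINE_FRAMES, _rising_crossing
from .phantom.camera import Movie
from .phantom.geometry import EmbryoPhantom


@dataclass
class PropagationResult:
    """Speed fit for one propagating event."""

    roi_centroid_distance: np.ndarray  # mm from the rostral reference
    onset_time: np.ndarray  # s per ROI (NaN where invalid)
    speed: float  # mm/s
    speed_fit_r2: float
    amplitude_per_roi: np.ndarray
    flag: str = "ok"  # "ok", "simultaneous", "caudo-rostral", "non-propagating"

    def __post_init__(self) -> None:
        d = np.asarray(self.roi_centroid_distance, dtype=float)
        if len(d) > 1 and not np.all(np.diff(d) > 0):
            raise ValueError("ROI distances must strictly increase")


def group_somite_rois(phantom: EmbryoPhantom, group_size: int = 3):
    """Merge consecutive somites into grouped ROIs with area-weighted centroids.

    Returns ``(masks, centroids_um)``; a trailing remainder group is kept if
    it contains at least one somite.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if phantom.n_somites == 0:
        raise ValueError("phantom has no somites")
    masks, centroids = [], []
    for i in range(0, phantom.n_somites, group_size):
        chunk = phantom.somite_masks[i : i + group_size]
        areas = chunk.sum(axis=(1, 2)).astype(float)
        cents = phantom.somite_centroids[i : i + group_size]
        masks.append(chunk.any(axis=0))
        centroids.append((cents * areas[:, None]).sum(axis=0) / areas.sum())
    return np.asarray(masks), np.asarray(centroids)


def onset_time(
    values,
    frame_interval: float,
    window: EventWindow,
    baseline_frames: int = DEFAULT_BASELINE_FRAMES,
    baseline: float | None = None,
) -> float | None:
    """Time of the 50% rising-amplitude crossing of an event, or None.

    Linear interpolation between samples; amplitude is measured from
    ``baseline`` when given, else from the mean of the ``baseline_frames``
    preceding the window.  ROIs with a non-positive amplitude are excluded
    (None).
    """
    values = np.asarray(values, dtype=float)
    start = window.start_frame
    if baseline is None:
        if start > 0 and baseline_frames > 0:
            baseline = float(values[max(0, start - baseline_frames) : start].mean())
        else:
            baseline = 0.0
    seg = values[window.start_frame : window.end_frame + 1]
    peak_idx = window.start_frame + int(np.argmax(seg))
    amplitude = float(values[peak_idx]) - baseline
    if amplitude <= 0:
        return None
    return _rising_crossing(values, baseline + 0.5 * amplitude, peak_idx,
                            frame_interval,
                            search_from=max(0, start - max(baseline_frames, 1)))


def wave_speed(onsets, distances_mm, amplitudes=None) -> PropagationResult:
    """OLS fit of onset time vs. distance; speed = 1/slope, with r².

    All ROIs participate in one regression (rather than a first/last pair),
    which uses all data and yields a fit-quality flag.  A zero slope reports
    infinite speed ("simultaneous"); a negative slope is flagged
    caudo-rostral.
    """
    onsets = np.asarray(onsets, dtype=float)
    d = np.asarray(distances_mm, dtype=float)
    amplitudes = (np.full_like(d, np.nan) if amplitudes is None
                  else np.asarray(amplitudes, dtype=float))
    valid = np.isfinite(onsets)
    if valid.sum() < 2:
        return PropagationResult(d, onsets, float("nan"), float("nan"),
                                 amplitudes, flag="non-propagating")
    x, y = d[valid], onsets[valid]
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if abs(slope) < 1e-12:
        return PropagationResult(d, onsets, float("inf"), r2, amplitudes,
                                 flag="simultaneous")
    flag = "caudo-rostral" if slope < 0 else "ok"
    return PropagationResult(d, onsets, 1.0 / slope, r2, amplitudes, flag=flag)


def analyze_wave_movie(
    movie: Movie,
    phantom: EmbryoPhantom,
    group_size: int = 3,
    baseline_frames: int = DEFAULT_BASELINE_FRAMES,
    merge_gap: int = 2,
    event_fraction: float = 0.25,
) -> list[PropagationResult]:
    """Estimate per-event wave speed from grouped-ROI traces of a movie.

    Events are segmented on the group-mean trace at baseline + a fraction of
    its dynamic range; each event's onsets are the per-ROI 50% crossings.
    ROIs without a positive-amplitude excursion in an event are excluded;
    events with fewer than two valid ROIs are flagged non-propagating.
    """
    masks, centroids = group_somite_rois(phantom, group_size)
    ref = centroids[0]
    distances = np.linalg.norm(centroids - ref, axis=1) / 1000.0
    traces = np.array([movie.frames[:, m].mean(axis=1) for m in masks])
    mean_trace = traces.mean(axis=0)
    base = float(np.median(mean_trace))
    thr = base + event_fraction * (mean_trace.max() - base)
    windows = segment_events(mean_trace, merge_gap=merge_gap, threshold=thr)
    dt = movie.frame_interval
    results = []
    for win in windows:
        # Per-ROI median baseline: frames just before the shared window can
        # already contain the rostral ROIs' rising phase.
        onsets = np.array([
            np.nan if (t := onset_time(tr, dt, win, baseline_frames,
                                       baseline=float(np.median(tr)))) is None
            else t
            for tr in traces
        ])
        # Amplitude against the per-ROI trace median: at low event duty
        # cycle the median is the resting level, and unlike a pre-window
        # mean it cannot be contaminated by the rostral ROIs' early rise.
        amps = np.array([
            tr[win.start_frame : win.end_frame + 1].max() - np.median(tr)
            for tr in traces
        ])
        results.append(wave_speed(onsets, distances, amps))
    return results
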