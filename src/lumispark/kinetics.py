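"""Crossing-based kinetic parameters of detected events.

For each event the pre-event baseline is subtracted and the 10%, 50% and 90%
amplitude crossings are located by linear interpolation between samples
(electrophysiology-software convention):

rise time 10–90% = t(90%↑) − t(10%↑)
decay time 90–10% = t(10%↓) − t(90%↓)
half-width = t(50%↓) − t(50%↑)
duration = t(10%↓) − t(10%↑)
time to peak = t(peak) − t(10%↑)

Events whose falling crossings run off the recording edge are flagged as
truncated and carry NaN decay statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import EventWindow, IntegratedDensityTrace

DEFAULT_BASELINE_FRAMES = 5


@dataclass
class KineticParams:
    """Kinetic parameters of one event (times in s, amplitude in trace units)."""

    time_to_peak: float
    peak_amplitude: float
    rise_10_90: float
    decay_90_10: float
    half_width: float
    duration: float
    baseline: float
    status: str = "ok"  # "ok", "rejected", "truncated"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _interp_time(i: int, v_lo: float, v_hi: float, level: float,
                 dt: float) -> float:
    return (i + (level - v_lo) / (v_hi - v_lo)) * dt


def _rising_crossing(values, level, peak_idx, dt, search_from=0):
    """Time of the first upward crossing of ``level`` before the peak.

    Anchoring to the first (rather than last) crossing keeps the rise
    measurement attached to the upstroke when noise makes the trace dip and
    re-cross a level close to the peak.
    """
    for i in range(search_from, peak_idx):
        if values[i] < level <= values[i + 1]:
            return _interp_time(i, values[i], values[i + 1], level, dt)
    return None


def _falling_crossing(values, level, peak_idx, dt):
    """Time of the first downward crossing of ``level`` after the peak."""
    for i in range(peak_idx, len(values) - 1):
        if values[i] >= level > values[i + 1]:
            return _interp_time(i, values[i], values[i + 1], level, dt)
    return None


def _rejected(baseline: float) -> KineticParams:
    nan = float("nan")
    return KineticParams(nan, nan, nan, nan, nan, nan, baseline,
                         status="rejected")


def event_kinetics(
    trace,
    window: EventWindow,
    baseline_frames: int = DEFAULT_BASELINE_FRAMES,
    frame_interval: float | None = None,
    peak_tolerance: float = 0.0,
) -> KineticParams:
    """Kinetic parameters of one event window on a trace.

    Parameters
    ----------
    trace : IntegratedDensityTrace or 1-D array
        When an array is given, ``frame_interval`` must be provided.
    window : EventWindow
        Frame span of the event (from segmentation).
    baseline_frames : int
        Number of frames immediately preceding the window averaged into the
        baseline; when the window starts at frame 0 the baseline is 0.

    Notes
    -----
    The crossing search extends beyond the window edges (towards the nearest
    crossing), so levels below the segmentation threshold are still resolved.
    A non-positive amplitude rejects the event; missing falling crossings at
    the recording edge flag it truncated.
    """
    if isinstance(trace, IntegratedDensityTrace):
        values = trace.values
        dt = trace.frame_interval
    else:
        values = np.asarray(trace, dtype=float)
        if frame_interval is None:
            raise ValueError("frame_interval required for raw arrays")
        dt = frame_interval
    n = len(values)
    if not (0 <= window.start_frame <= window.end_frame < n):
        raise ValueError("event window outside trace")

    start = window.start_frame
    if start > 0 and baseline_frames > 0:
        lo = max(0, start - baseline_frames)
        baseline = float(values[lo:start].mean())
    else:
        baseline = 0.0

    seg = values[window.start_frame : window.end_frame + 1]
    vmax = float(seg.max())
    if vmax - baseline <= 0:
        return _rejected(baseline)
    # Earliest frame within `peak_tolerance` of the maximum.  The default
    # (0) is the earliest exact maximum; a small positive tolerance anchors
    # the peak to the upstroke on noisy plateaus instead of a late noise
    # excursion, and is the convention for event statistics on stochastic
    # photon-limited traces.
    near = vmax - peak_tolerance * (vmax - baseline)
    peak_idx = window.start_frame + int(np.argmax(seg >= near))
    amplitude = float(values[peak_idx]) - baseline
    if amplitude <= 0:
        return _rejected(baseline)

    levels = {frac: baseline + frac * amplitude for frac in (0.1, 0.5, 0.9)}
    t_peak = peak_idx * dt
    search_from = max(0, start - max(baseline_frames, 1))
    rise = {f: _rising_crossing(values, lv, peak_idx, dt, search_from)
            for f, lv in levels.items()}
    fall = {f: _falling_crossing(values, lv, peak_idx, dt)
            for f, lv in levels.items()}

    if any(v is None for v in rise.values()):
        return _rejected(baseline)
    truncated = any(v is None for v in fall.values())
    nan = float("nan")
    return KineticParams(
        time_to_peak=t_peak - rise[0.1],
        peak_amplitude=amplitude,
        rise_10_90=rise[0.9] - rise[0.1],
        decay_90_10=nan if truncated else fall[0.1] - fall[0.9],
        half_width=nan if truncated else fall[0.5] - rise[0.5],
        duration=nan if truncated else fall[0.1] - rise[0.1],
        baseline=baseline,
        status="truncated" if truncated else "ok",
    )


def series_frequency(events, recording_duration: float) -> float:
    """Mean event frequency in Hz: count / recording duration."""
    if recording_duration <= 0:
        raise ValueError("recording duration must be positive")
    n = events if np.isscalar(events) else len(events)
    return n / recording_duration


def resample_trace(values, source_rate: float, target_rate: float):
    """Integrate a photon-count trace into longer bins (sums, not means).

    Emulates acquiring at a lower frame rate with proportionally longer
    integration.  Only integer decimation factors are supported; a trailing
    partial bin is summed too, so total counts are conserved.
    """
    if target_rate > source_rate:
        raise ValueError("target rate must not exceed source rate")
    factor_f = source_rate / target_rate
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9:
        raise ValueError("rate ratio must be an integer decimation factor")
    values = np.asarray(values, dtype=float)
    if factor == 1:
        return values.copy()
    edges = np.arange(0, len(values), factor)
    return np.add.reduceat(values, edges)


def summarize_kinetics(params_list, recording_duration: float | None = None) -> dict:
    """Mean ± SD summary of the seven kinetic parameters over accepted events."""
    ok = [p for p in params_list if p.ok]
    # Truncated events keep valid rise-phase measurements; only their decay
    # statistics are excluded.
    with_rise = [p for p in params_list if p.status in ("ok", "truncated")]
    rise_fields = ("time_to_peak", "peak_amplitude", "rise_10_90")
    decay_fields = ("decay_90_10", "half_width", "duration")
    out: dict = {"n_events": len(ok), "n_rejected":
                 sum(p.status == "rejected" for p in params_list),
                 "n_truncated": sum(p.status == "truncated" for p in params_list)}
    for f, pool in [(f, with_rise) for f in rise_fields] + \
                   [(f, ok) for f in decay_fields]:
        vals = np.array([getattr(p, f) for p in pool], dtype=float)
        out[f"{f}_mean"] = float(np.nanmean(vals)) if len(vals) else float("nan")
        out[f"{f}_sd"] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
    if recording_duration:
        out["frequency_hz"] = series_frequency(len(with_rise), recording_duration)
    return out
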