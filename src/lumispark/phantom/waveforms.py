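"""Ca²⁺ transient waveforms and rostro-caudal wave propagation.

Each event contributes a difference-of-exponentials pulse, normalized so the
pulse peak equals the scheduled amplitude; overlapping events superpose on a
constant resting baseline.  Propagation along the trunk delays event onsets
by distance/speed, attenuates amplitudes per mm, and can optionally slow the
rise kinetics towards the tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import SpikeSchedule
from .geometry import EmbryoPhantom

#: Resting free Ca²⁺ in µM.
RESTING_CA_UM = 0.05


@dataclass
class TransientWaveform:
    """Difference-of-exponentials pulse kinetics for one compartment."""

    rise_time_constant: float  # s
    decay_time_constant: float  # s
    compartment: str = "cytosol"

    def __post_init__(self) -> None:
        if self.rise_time_constant <= 0 or self.decay_time_constant <= 0:
            raise ValueError("time constants must be positive")

    @classmethod
    def cytosolic(cls) -> "TransientWaveform":
        return cls(rise_time_constant=0.3, decay_time_constant=0.6,
                   compartment="cytosol")

    @classmethod
    def mitochondrial(cls) -> "TransientWaveform":
        # Matrix Ca²⁺ clearance is slower than sarcoplasmic re-uptake; the
        # rise constant is set so both compartments share the same pulse
        # upstroke (10–90%) despite the different decay normalization.
        return cls(rise_time_constant=0.144, decay_time_constant=2.5,
                   compartment="mitochondria")


@dataclass
class PropagationParams:
    """Rostro-caudal wave parameters."""

    conduction_speed: float = 1.6  # mm/s
    amplitude_decrement: float = 0.15  # fractional loss per mm
    rise_slowing_per_mm: float = 0.0  # fractional rise-constant increase per mm

    def __post_init__(self) -> None:
        if self.conduction_speed <= 0:
            raise ValueError("conduction_speed must be positive")
        if not (0.0 <= self.amplitude_decrement < 1.0):
            raise ValueError("amplitude_decrement must be in [0, 1)")
        if self.rise_slowing_per_mm < 0:
            raise ValueError("rise_slowing_per_mm must be non-negative")


def pulse_shape(t, rise_tau: float, decay_tau: float):
    """Unit-peak difference-of-exponentials pulse evaluated at times ``t`` (s).

    Zero for t < 0.  For equal time constants the limit (alpha function)
    t/τ·e^(1−t/τ) is used.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    if np.isclose(rise_tau, decay_tau):
        tau = decay_tau
        out[pos] = (tp / tau) * np.exp(1.0 - tp / tau)
        return out
    raw = np.exp(-tp / decay_tau) - np.exp(-tp / rise_tau)
    t_peak = (np.log(decay_tau) - np.log(rise_tau)) * rise_tau * decay_tau / (
        decay_tau - rise_tau
    )
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    out[pos] = raw / peak
    return out


def frame_times(n_frames: int, frame_interval: float) -> np.ndarray:
    """Midpoints of frame spans [i·Δt, (i+1)·Δt)."""
    return (np.arange(n_frames) + 0.5) * frame_interval


def ca_timecourse(
    schedule: SpikeSchedule,
    waveform: TransientWaveform,
    sampling: float,
    duration: float,
    baseline: float = RESTING_CA_UM,
    onset_shift: float = 0.0,
    amplitude_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Free-Ca²⁺ trace (µM) sampled at ``sampling`` Hz over ``duration`` s.

    Returns ``(times, ca)``; times are frame-span midpoints.
    """
    if sampling <= 0:
        raise ValueError("sampling rate must be positive")
    n = int(round(duration * sampling))
    t = frame_times(n, 1.0 / sampling)
    ca = np.full(n, baseline, dtype=float)
    for onset, amp in zip(schedule.event_onsets, schedule.event_amplitudes):
        ca += amp * amplitude_scale * pulse_shape(
            t - (onset + onset_shift),
            waveform.rise_time_constant,
            waveform.decay_time_constant,
        )
    return t, ca


def propagate_wave(
    schedule: SpikeSchedule,
    phantom: EmbryoPhantom,
    prop: PropagationParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-somite onset delays (s) and amplitude scalings for a travelling wave.

    Delay of somite *s* is its centroid distance from the rostral reference
    divided by the conduction speed; amplitude scales as
    (1 − decrement)^distance_mm.
    """
    d_mm = phantom.centroid_distances_mm()
    delays = d_mm / prop.conduction_speed
    scales = (1.0 - prop.amplitude_decrement) ** d_mm
    return delays, scales


def somite_ca_traces(
    phantom: EmbryoPhantom,
    schedule: SpikeSchedule,
    waveform: TransientWaveform,
    prop: PropagationParams | None = None,
    sampling: float = 11.9,
    duration: float | None = None,
    baseline: float = RESTING_CA_UM,
    amplitude_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-somite Ca²⁺ traces for a propagating (or synchronous) wave.

    Returns ``(times, ca, truth)`` where ``ca`` has shape
    (n_somites, n_frames) and ``truth`` records the ground-truth delays,
    amplitude scalings and per-somite rise constants.
    """
    if duration is None:
        duration = schedule.duration
    if prop is None:
        delays = np.zeros(phantom.n_somites)
        scales = np.ones(phantom.n_somites)
        rise_taus = np.full(phantom.n_somites, waveform.rise_time_constant)
    else:
        delays, scales = propagate_wave(schedule, phantom, prop)
        d_mm = phantom.centroid_distances_mm()
        rise_taus = waveform.rise_time_constant * (
            1.0 + prop.rise_slowing_per_mm * d_mm
        )
    n = int(round(duration * sampling))
    t = frame_times(n, 1.0 / sampling)
    ca = np.full((phantom.n_somites, n), baseline, dtype=float)
    for s in range(phantom.n_somites):
        wf = TransientWaveform(rise_taus[s], waveform.decay_time_constant,
                               waveform.compartment)
        _, ca[s] = ca_timecourse(
            schedule, wf, sampling, duration, baseline=baseline,
            onset_shift=delays[s], amplitude_scale=amplitude_scale * scales[s],
        )
    truth = {
        "event_onsets": schedule.event_onsets.tolist(),
        "event_amplitudes": schedule.event_amplitudes.tolist(),
        "delays_s": delays.tolist(),
        "amplitude_scalings": scales.tolist(),
        "rise_time_constants": rise_taus.tolist(),
        "decay_time_constant": waveform.decay_time_constant,
        "compartment": waveform.compartment,
        "baseline_uM": baseline,
        "sampling_hz": sampling,
    }
    return t, ca, truth
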