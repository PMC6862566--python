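"""Spontaneous-event schedules and experimental scenario presets.

Events (muscle contractions and their Ca²⁺ transients) are modelled as a
homogeneous Poisson process thinned by a refractory period.  The requested
``rate`` is the *realized* mean event rate after thinning: the underlying
Poisson intensity is compensated as λ = r / (1 − r·τ) so that the
non-paralyzable dead-time rate λ / (1 + λ·τ) equals r.  This keeps scenario
rates (0.02 Hz in long recordings, ~0.2 Hz in short ones) directly
interpretable as observed event frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Developmental signalling windows (hours post-fertilization): activity
#: between 17.5–19.5 hpf (SP1) and after 23 hpf (SP2), separated by a quiet
#: gap of about 3.5 h.
SP1_WINDOW_HPF = (17.5, 19.5)
SP2_START_HPF = 23.0

LONG_RUN_RATE = 0.02  # Hz, long (hours) recordings
SHORT_RUN_RATE = 0.2  # Hz, short (minutes) recordings
UNCOUPLER_RATE_FACTOR = 1.5  # FCCP / MCU-inhibitor frequency increase (~+50%)


@dataclass
class SpikeSchedule:
    """Ground-truth event schedule at the rostral reference somite."""

    event_onsets: np.ndarray  # s, strictly increasing
    event_amplitudes: np.ndarray  # peak free Ca²⁺, µM
    scenario_label: str = "custom"
    duration: float = 0.0  # s
    refractory: float = 0.0  # s

    def __post_init__(self) -> None:
        self.event_onsets = np.asarray(self.event_onsets, dtype=float)
        self.event_amplitudes = np.asarray(self.event_amplitudes, dtype=float)
        if self.event_onsets.shape != self.event_amplitudes.shape:
            raise ValueError("onsets and amplitudes must have equal length")
        if len(self.event_onsets) > 1:
            gaps = np.diff(self.event_onsets)
            if not np.all(gaps > 0):
                raise ValueError("event onsets must be strictly increasing")
            if self.refractory > 0 and np.any(gaps < self.refractory):
                raise ValueError("inter-event gap below refractory period")
        if np.any(self.event_amplitudes <= 0):
            raise ValueError("event amplitudes must be positive")

    @property
    def n_events(self) -> int:
        return len(self.event_onsets)


@dataclass
class ScenarioFlags:
    """Side conditions a pharmacological scenario imposes on the generator."""

    mito_uptake: bool = True
    cyto_amplitude_scale: float = 1.0
    contractile: bool = True


def _thinned_poisson(rate, duration, refractory, rng):
    if rate == 0:
        return np.empty(0)
    if refractory * rate >= 1.0:
        raise ValueError("rate * refractory must be < 1")
    lam = rate / (1.0 - rate * refractory)  # realized-rate compensation
    n = rng.poisson(lam * duration)
    arrivals = np.sort(rng.uniform(0.0, duration, size=n))
    kept = []
    last = -np.inf
    for t in arrivals:
        if t - last >= refractory:
            kept.append(t)
            last = t
    return np.asarray(kept)


def schedule_events(
    rate: float,
    duration: float,
    refractory: float = 3.0,
    seed=None,
    amplitude_mean: float = 1.0,
    amplitude_sigma: float = 0.25,
    label: str = "custom",
) -> SpikeSchedule:
    """Draw a refractory-thinned Poisson event schedule.

    Parameters
    ----------
    rate : float
        Realized mean event rate in Hz (see module docstring).
    duration : float
        Recording duration in s.
    refractory : float
        Dead time after each accepted event; later arrivals inside the window
        are discarded, not delayed.
    seed : int, ``numpy.random.Generator`` or None
        Randomness source.
    amplitude_mean, amplitude_sigma : float
        Event peak amplitudes (µM free Ca²⁺) are log-normal with this mean
        and log-scale sigma.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if refractory < 0:
        raise ValueError("refractory must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    onsets = _thinned_poisson(rate, duration, refractory, rng)
    mu = np.log(amplitude_mean) - 0.5 * amplitude_sigma**2
    amps = np.exp(rng.normal(mu, amplitude_sigma, size=len(onsets)))
    return SpikeSchedule(onsets, amps, scenario_label=label, duration=duration,
                         refractory=refractory)


def _piecewise_schedule(windows, duration, refractory, rng, label):
    """Concatenate homogeneous segments, enforcing the refractory across joins."""
    onsets = []
    last = -np.inf
    for (t0, t1, rate) in windows:
        t0, t1 = max(0.0, t0), min(duration, t1)
        if t1 <= t0 or rate == 0:
            continue
        seg = _thinned_poisson(rate, t1 - t0, refractory, rng) + t0
        for t in seg:
            if t - last >= refractory:
                onsets.append(t)
                last = t
    onsets = np.asarray(onsets)
    sigma = 0.25
    mu = np.log(1.0) - 0.5 * sigma**2
    amps = np.exp(rng.normal(mu, sigma, size=len(onsets)))
    return SpikeSchedule(onsets, amps, scenario_label=label, duration=duration,
                         refractory=refractory)


def scenario_schedule(
    scenario: str,
    duration: float = 600.0,
    seed=None,
    base_rate: float = SHORT_RUN_RATE,
    refractory: float = 3.0,
    start_hpf: float = 17.0,
) -> tuple[SpikeSchedule, ScenarioFlags]:
    """Build the event schedule and generator flags for a named scenario.

    Scenarios
    ---------
    ``sp2-short``
        Short recording in the second signalling period; realized rate
        ``base_rate`` (default 0.2 Hz).
    ``sp1-sp2-long``
        Hours-long recording starting at ``start_hpf``; activity at 0.02 Hz
        inside SP1 (17.5–19.5 hpf) and SP2 (after 23 hpf), quiet in between.
    ``tricaine``
        Anaesthetic block of neural input: no events at all.
    ``fccp`` / ``ds``
        Mitochondrial uncoupler / MCU inhibitor: event rate ×1.5,
        mitochondrial Ca²⁺ uptake disabled.  FCCP additionally reduces the
        cytosolic transient amplitude.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    scenario = scenario.lower()
    if scenario == "sp2-short":
        sched = schedule_events(base_rate, duration, refractory, rng, label=scenario)
        return sched, ScenarioFlags()
    if scenario == "tricaine":
        sched = SpikeSchedule(np.empty(0), np.empty(0), scenario_label=scenario,
                              duration=duration, refractory=refractory)
        return sched, ScenarioFlags(contractile=False)
    if scenario in ("fccp", "ds"):
        sched = schedule_events(base_rate * UNCOUPLER_RATE_FACTOR, duration,
                                refractory, rng, label=scenario)
        amp_scale = 0.8 if scenario == "fccp" else 1.0
        return sched, ScenarioFlags(mito_uptake=False, cyto_amplitude_scale=amp_scale)
    if scenario == "sp1-sp2-long":
        to_s = lambda hpf: (hpf - start_hpf) * 3600.0
        windows = [
            (to_s(SP1_WINDOW_HPF[0]), to_s(SP1_WINDOW_HPF[1]), LONG_RUN_RATE),
            (to_s(SP2_START_HPF), duration, LONG_RUN_RATE),
        ]
        sched = _piecewise_schedule(windows, duration, refractory, rng, scenario)
        return sched, ScenarioFlags()
    raise ValueError(f"unknown scenario {scenario!r}")
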