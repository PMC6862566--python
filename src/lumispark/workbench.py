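"""End-to-end pipelines tying the simulator to the analysis modules.

The two headline experiment designs are reproduced here:

* a *paired experiment*: contractions (transmitted light) and Ca²⁺
  transients (luminescence) measured sequentially on co-generated movies
  from one event schedule per embryo, compared by frequency;
* an *indicator comparison*: the same Ca²⁺ waveforms viewed through
  aequorin-based luminescence (11.9 Hz) and a ratiometric FRET indicator
  (33 Hz), summarized by the seven kinetic parameters.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import background, contractions, fret
from .detection import DetectionParams, integrated_density, segment_events
from .kinetics import event_kinetics, summarize_kinetics
from .phantom import (
    AequorinModel,
    BleachingModel,
    CameraModel,
    EmbryoPhantom,
    Movie,
    PropagationParams,
    ScenarioFlags,
    SpikeSchedule,
    TransientWaveform,
    TwitchModel,
    aequorin_emission,
    make_embryo_phantom,
    render_fret_movie,
    render_luminescence_movie,
    render_transmitted_movie,
    scenario_schedule,
    somite_ca_traces,
)

logger = logging.getLogger("lumispark")

#: Acquisition frame rates (Hz) used by the study designs.
RATE_TRANSMITTED = 4.2
RATE_LUM_SLOW = 4.7
RATE_LUM_STANDARD = 11.9
RATE_LUM_FAST = 30.0
RATE_FLUORESCENCE = 33.0


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping, embedded in reports."""
    text = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha1(text.encode()).hexdigest()[:12]


@dataclass
class RunConfig:
    """Configuration of one simulation/analysis run."""

    scenario: str = "sp2-short"
    indicator: str = "GA"
    seed: int = 0
    duration: float = 600.0
    frame_rate: float = RATE_LUM_SLOW
    n_embryos: int = 6
    detection: dict = field(default_factory=dict)
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def hash(self) -> str:
        return config_hash(asdict(self))


@dataclass
class SimulatedEmbryo:
    """One rendered movie with its full generative ground truth."""

    movie: Movie
    phantom: EmbryoPhantom
    schedule: SpikeSchedule
    flags: ScenarioFlags
    truth: dict


def _luminescence_camera(frame_rate: float, shape) -> CameraModel:
    return CameraModel.for_binned_shape(tuple(shape),
                                        integration_time=1.0 / frame_rate)


def simulate_embryo(
    indicator: str,
    schedule: SpikeSchedule,
    flags: ScenarioFlags,
    seed=None,
    phantom: EmbryoPhantom | None = None,
    frame_rate: float | None = None,
    prop: PropagationParams | None = None,
    stochastic: bool = True,
    aequorin: AequorinModel | None = None,
    twitch: TwitchModel | None = None,
    bleach: BleachingModel | None = None,
) -> SimulatedEmbryo:
    """Render one movie for the given indicator from a ground-truth schedule.

    ``indicator`` is one of ``GA`` (cytosolic luminescence), ``mitoGA``
    (mitochondrial luminescence), ``twitch4`` (split-field FRET) or
    ``transmitted`` (contraction movie).
    """
    if phantom is None:
        phantom = make_embryo_phantom()
    if prop is None:
        prop = PropagationParams()
    logger.info("simulate indicator=%s scenario=%s n_events=%d",
                indicator, schedule.scenario_label, schedule.n_events)

    if indicator == "transmitted":
        rate = frame_rate or RATE_TRANSMITTED
        cam = _luminescence_camera(rate, phantom.image_shape)
        movie = render_transmitted_movie(phantom, schedule, cam, seed=seed,
                                         stochastic=stochastic)
        truth = {"event_onsets": schedule.event_onsets.tolist()}
        return SimulatedEmbryo(movie, phantom, schedule, flags, truth)

    if indicator in ("GA", "mitoGA"):
        rate = frame_rate or (RATE_LUM_SLOW if indicator == "GA"
                              else RATE_LUM_STANDARD)
        if indicator == "mitoGA" and not flags.mito_uptake:
            # Uncoupled/uniporter-blocked mitochondria see no Ca²⁺ transients.
            effective = SpikeSchedule(np.empty(0), np.empty(0),
                                      scenario_label=schedule.scenario_label,
                                      duration=schedule.duration,
                                      refractory=schedule.refractory)
        else:
            effective = schedule
        waveform = (TransientWaveform.cytosolic() if indicator == "GA"
                    else TransientWaveform.mitochondrial())
        amp_scale = flags.cyto_amplitude_scale if indicator == "GA" else 1.0
        # Supersample the photophysics so each frame integrates the emission
        # over its span (sub-frame onset timing survives frame quantization).
        ss = 4
        _, ca, truth = somite_ca_traces(phantom, effective, waveform, prop,
                                        sampling=rate * ss,
                                        duration=schedule.duration,
                                        amplitude_scale=amp_scale)
        model = aequorin or AequorinModel()
        fine_rates, _ = aequorin_emission(ca, 1.0 / (rate * ss), model)
        n_frames = fine_rates.shape[1] // ss
        rates = fine_rates[:, : n_frames * ss].reshape(
            phantom.n_somites, n_frames, ss).mean(axis=2)
        cam = _luminescence_camera(rate, phantom.image_shape)
        movie = render_luminescence_movie(phantom, rates, cam, seed=seed,
                                          stochastic=stochastic)
        return SimulatedEmbryo(movie, phantom, schedule, flags, truth)

    if indicator == "twitch4":
        rate = frame_rate or RATE_FLUORESCENCE
        waveform = TransientWaveform.cytosolic()
        _, ca, truth = somite_ca_traces(phantom, schedule, waveform, prop,
                                        sampling=rate,
                                        duration=schedule.duration,
                                        amplitude_scale=flags.cyto_amplitude_scale)
        h, w = phantom.image_shape
        cam = CameraModel.for_binned_shape((h, 2 * w),
                                           integration_time=1.0 / rate)
        movie = render_fret_movie(phantom, ca, twitch or TwitchModel(),
                                  bleach, cam, seed=seed,
                                  stochastic=stochastic)
        return SimulatedEmbryo(movie, phantom, schedule, flags, truth)

    raise ValueError(f"unknown indicator {indicator!r}")


def central_somite_mask(phantom: EmbryoPhantom, n: int = 3) -> np.ndarray:
    """Union mask of ``n`` central somites.

    Kinetic parameters are measured over a small contiguous somite group
    (mirroring ROI placement over mid-trunk somites) rather than the whole
    trunk, so that rostro-caudal wave delays do not smear the event shape.
    """
    mid = phantom.n_somites // 2
    lo = max(0, mid - n // 2)
    return phantom.somite_masks[lo : lo + n].any(axis=0)


def transient_frequency(movie: Movie, phantom: EmbryoPhantom,
                        merge_gap_s: float = 0.5, detection_params=None):
    """Detected Ca²⁺-transient frequency of a luminescence movie (Hz).

    Runs the full background → threshold → component gating → integrated
    density → event segmentation chain.  Returns
    ``(frequency, events, trace, background_estimate)``.
    """
    pair = background.default_roi_pair(phantom)
    est = background.frame_thresholds(movie.frames, pair)
    params = detection_params or DetectionParams(restrict_mask=phantom.trunk_mask)
    trace = integrated_density(movie.frames, est.threshold_per_frame, params,
                               movie.frame_interval)
    merge_gap = int(round(merge_gap_s / movie.frame_interval))
    events = segment_events(trace.values, merge_gap=merge_gap)
    freq = len(events) / movie.duration
    return freq, events, trace, est


def contraction_frequency(movie: Movie, phantom: EmbryoPhantom,
                          k: float = 5.0, refractory: float = 0.5):
    """Detected contraction frequency of a transmitted-light movie (Hz)."""
    on, off = contractions.edge_roi_pair(phantom)
    trace = contractions.dual_roi_ratio(movie, on, off)
    events, freq = contractions.detect_contractions(trace, k=k,
                                                    refractory=refractory)
    return freq, events, trace


def run_paired_experiment(
    n_embryos: int = 6,
    duration: float = 600.0,
    seed: int = 0,
    indicator: str = "GA",
    scenario: str = "sp2-short",
    frame_rate: float = RATE_LUM_SLOW,
    stochastic: bool = True,
):
    """Contraction vs. Ca²⁺-transient frequency on co-generated movies.

    Contractions and Ca²⁺ cannot be filmed simultaneously in a light-tight
    luminescence setup, so each embryo's two movies are generated
    sequentially from one shared event schedule.  Returns ``(frame, summary)``
    where ``frame`` has one row per embryo.
    """
    streams = np.random.SeedSequence(seed).spawn(n_embryos)
    rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        schedule, flags = scenario_schedule(scenario, duration, seed=rng)
        trans = simulate_embryo("transmitted", schedule, flags, seed=rng,
                                stochastic=stochastic)
        lum = simulate_embryo(indicator, schedule, flags, seed=rng,
                              frame_rate=frame_rate, stochastic=stochastic)
        c_freq, _, _ = contraction_frequency(trans.movie, trans.phantom)
        t_freq, _, _, _ = transient_frequency(lum.movie, lum.phantom)
        rows.append({"embryo": i, "scheduled_events": schedule.n_events,
                     "contraction_freq_hz": c_freq,
                     "transient_freq_hz": t_freq})
    frame = pd.DataFrame(rows)
    diffs = frame.contraction_freq_hz - frame.transient_freq_hz
    summary = {
        "n_embryos": n_embryos,
        "mean_contraction_hz": float(frame.contraction_freq_hz.mean()),
        "mean_transient_hz": float(frame.transient_freq_hz.mean()),
        "mean_paired_difference_hz": float(diffs.mean()),
        "sem_paired_difference_hz":
            float(diffs.std(ddof=1) / np.sqrt(n_embryos)) if n_embryos > 1
            else float("nan"),
        "config_hash": config_hash({"n": n_embryos, "duration": duration,
                                    "seed": seed, "scenario": scenario,
                                    "indicator": indicator}),
    }
    return frame, summary


def run_drug_experiment(
    n_embryos: int = 8,
    segment_duration: float = 900.0,
    seed: int = 0,
    drug: str = "fccp",
    include_mito: bool = False,
    mito_duration: float | None = None,
    stochastic: bool = True,
):
    """Paired pre-drug / post-drug segments per embryo.

    Pre segments use the baseline short-recording scenario; post segments
    use the drug preset (event rate ×1.5, mitochondrial uptake disabled).
    Contraction frequencies come from transmitted-light movies; optionally
    mitochondrial transient frequencies from mitoGA movies rendered from the
    same schedules.  Returns ``(frame, summary)``.
    """
    streams = np.random.SeedSequence(seed).spawn(n_embryos)
    mito_duration = mito_duration or segment_duration
    rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pre_s, pre_f = scenario_schedule("sp2-short", segment_duration, seed=rng)
        post_s, post_f = scenario_schedule(drug, segment_duration, seed=rng)
        row: dict = {"embryo": i}
        pre_m = simulate_embryo("transmitted", pre_s, pre_f, seed=rng,
                                stochastic=stochastic)
        post_m = simulate_embryo("transmitted", post_s, post_f, seed=rng,
                                 stochastic=stochastic)
        row["pre_contraction_hz"], _, _ = contraction_frequency(
            pre_m.movie, pre_m.phantom)
        row["post_contraction_hz"], _, _ = contraction_frequency(
            post_m.movie, post_m.phantom)
        if include_mito:
            pre_sm, _ = scenario_schedule("sp2-short", mito_duration, seed=rng)
            post_sm, post_fm = scenario_schedule(drug, mito_duration, seed=rng)
            mito_pre = simulate_embryo("mitoGA", pre_sm, ScenarioFlags(),
                                       seed=rng, stochastic=stochastic)
            mito_post = simulate_embryo("mitoGA", post_sm, post_fm, seed=rng,
                                        stochastic=stochastic)
            row["pre_mito_hz"], _, _, _ = transient_frequency(
                mito_pre.movie, mito_pre.phantom)
            row["post_mito_hz"], _, _, _ = transient_frequency(
                mito_post.movie, mito_post.phantom)
        rows.append(row)
    frame = pd.DataFrame(rows)
    change = contractions.paired_frequency_change(
        frame.pre_contraction_hz.to_numpy(),
        frame.post_contraction_hz.to_numpy())
    summary = {
        "n_embryos": n_embryos,
        "drug": drug,
        "mean_contraction_change_percent": change["mean"],
        "sem_contraction_change_percent": change["sem"],
        "config_hash": config_hash({"n": n_embryos, "seed": seed,
                                    "segment_duration": segment_duration,
                                    "drug": drug}),
    }
    if include_mito:
        summary["mean_pre_mito_hz"] = float(frame.pre_mito_hz.mean())
        summary["mean_post_mito_hz"] = float(frame.post_mito_hz.mean())
    return frame, summary


def _trace_events(values, merge_gap=2, event_fraction=0.25):
    base = float(np.median(values))
    thr = base + event_fraction * (values.max() - base)
    return segment_events(values, merge_gap=merge_gap, threshold=thr)


def run_indicator_comparison(
    duration: float = 120.0,
    seed: int = 0,
    n_embryos: int = 3,
    stochastic: bool = True,
    lum_rate: float = RATE_LUM_STANDARD,
    fluo_rate: float = RATE_FLUORESCENCE,
):
    """Kinetic parameters from luminescence (11.9 Hz) vs. FRET ratio (33 Hz).

    Matched schedules drive both indicators; events are detected and the
    seven kinetic parameters extracted independently per pipeline.  Returns
    a dict with per-indicator summaries.
    """
    streams = np.random.SeedSequence(seed).spawn(n_embryos)
    lum_params, ratio_params = [], []
    lum_n = ratio_n = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        schedule, flags = scenario_schedule("sp2-short", duration, seed=rng)
        lum = simulate_embryo("GA", schedule, flags, seed=rng,
                              frame_rate=lum_rate, stochastic=stochastic)
        roi = central_somite_mask(lum.phantom)
        params = DetectionParams(restrict_mask=roi)
        _, events, trace, _est = transient_frequency(lum.movie, lum.phantom,
                                                     detection_params=params)
        for win in events:
            lum_params.append(event_kinetics(trace, win))
        lum_n += len(events)

        fr = simulate_embryo("twitch4", schedule, flags, seed=rng,
                             frame_rate=fluo_rate, stochastic=stochastic)
        donor, acc, _ = fret.split_and_register(fr.movie, search_radius=3)
        rm = fret.ratio_stack(donor, acc, frame_interval=fr.movie.frame_interval,
                              pixel_scale=fr.movie.pixel_scale)
        rtrace = rm.roi_trace(central_somite_mask(fr.phantom))
        for win in _trace_events(rtrace):
            ratio_params.append(event_kinetics(rtrace, win,
                                               frame_interval=1.0 / fluo_rate))
        ratio_n += 1
    total = n_embryos * duration
    return {
        "GA": summarize_kinetics(lum_params, total),
        "twitch4": summarize_kinetics(ratio_params, total),
        "config_hash": config_hash({"duration": duration, "seed": seed,
                                    "n_embryos": n_embryos}),
    }
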