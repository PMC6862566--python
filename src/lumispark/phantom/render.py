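"""Render ground-truthed movies: bioluminescence, split-field FRET, transmitted light."""

from __future__ import annotations

import numpy as np

from .camera import CameraModel, Movie, apply_camera_noise
from .events import SpikeSchedule
from .geometry import EmbryoPhantom
from .photophysics import BleachingModel, TwitchModel, release_filter


def _check_shapes(phantom: EmbryoPhantom, camera: CameraModel,
                  width_factor: int = 1) -> None:
    h, w = phantom.image_shape
    if camera.binned_shape != (h, w * width_factor):
        raise ValueError(
            f"camera binned shape {camera.binned_shape} does not match "
            f"required frame shape {(h, w * width_factor)}"
        )


def render_luminescence_movie(
    phantom: EmbryoPhantom,
    somite_rates: np.ndarray,
    camera: CameraModel,
    seed=None,
    stochastic: bool = True,
) -> Movie:
    """Render a single-channel bioluminescence movie.

    Parameters
    ----------
    somite_rates : (S, T) array
        Expected photon emission rate (photons/s/pixel) for each somite.
    stochastic : bool
        When False, frames hold the noiseless expected output
        (gain × expected counts) instead of sampled counts.
    """
    _check_shapes(phantom, camera)
    somite_rates = np.asarray(somite_rates, dtype=float)
    s, t = somite_rates.shape
    if s != phantom.n_somites:
        raise ValueError("somite_rates first axis must match n_somites")
    rng = np.random.default_rng(seed)
    dt = camera.integration_time
    h, w = phantom.image_shape

    base = np.full((h, w), camera.dark_rate, dtype=float)
    base[phantom.trunk_mask] += camera.substrate_glow_rate
    masks = phantom.somite_masks

    frames = np.empty((t, h, w), dtype=np.float32)
    for i in range(t):
        lam = base + np.einsum("s,shw->hw", somite_rates[:, i], masks)
        lam = lam * dt
        if stochastic:
            frames[i] = apply_camera_noise(lam, camera, rng)
        else:
            frames[i] = lam * camera.gain
    return Movie(frames, frame_interval=dt, pixel_scale=phantom.pixel_scale,
                 channel_label="luminescence")


def render_fret_movie(
    phantom: EmbryoPhantom,
    ca_traces: np.ndarray,
    twitch: TwitchModel,
    bleach: BleachingModel | None,
    camera: CameraModel,
    seed=None,
    motion_amplitude: float = 0.08,
    channel_offset: tuple[int, int] = (0, 0),
    stochastic: bool = True,
    base_brightness: float = 1000.0,  # photons/s/pixel over the embryo
    background_brightness: float = 20.0,  # photons/s/pixel elsewhere
    donor_ca_dim: float = 0.25,  # fractional donor loss at full occupancy
) -> Movie:
    """Render a split-field two-channel FRET movie (donor left, FRET right).

    The pixel-wise FRET/donor ratio follows the indicator's Hill response to
    the per-somite Ca²⁺ traces (release-filtered by the off half-time).  The
    donor dims and the FRET channel brightens with Ca²⁺; both channels share
    a common multiplicative motion artifact during events and bleach
    mono-exponentially with their channel time constants.  ``channel_offset``
    shifts the FRET half-field content by whole pixels (image-splitter
    misalignment).
    """
    _check_shapes(phantom, camera, width_factor=2)
    ca_traces = np.asarray(ca_traces, dtype=float)
    s, t = ca_traces.shape
    if s != phantom.n_somites:
        raise ValueError("ca_traces first axis must match n_somites")
    rng = np.random.default_rng(seed)
    dt = camera.integration_time
    h, w = phantom.image_shape
    times = (np.arange(t) + 0.5) * dt

    occ = release_filter(twitch.occupancy(ca_traces), dt, twitch.off_half_time)
    # Trunk pixels outside any somite sit at the resting occupancy.
    occ_rest = float(twitch.occupancy(ca_traces.min(initial=0.0)))
    motion = 1.0 - motion_amplitude * occ.mean(axis=0)
    if bleach is None:
        b_d = np.ones(t)
        b_a = np.ones(t)
    else:
        b_d = bleach.donor_remaining(times)
        b_a = bleach.acceptor_remaining(times)

    masks = phantom.somite_masks
    trunk = phantom.trunk_mask
    rest_trunk = trunk & ~masks.any(axis=0)

    frames = np.empty((t, h, 2 * w), dtype=np.float32)
    for i in range(t):
        occ_map = np.einsum("s,shw->hw", occ[:, i], masks)
        occ_map[rest_trunk] = occ_rest
        bright = np.full((h, w), background_brightness, dtype=float)
        bright[trunk] = base_brightness
        dim = np.where(trunk, 1.0 - donor_ca_dim * occ_map, 1.0)
        donor = bright * dim * b_d[i] * motion[i]
        fret = bright * dim * twitch.ratio(occ_map) * b_a[i] * motion[i]
        if channel_offset != (0, 0):
            fret = np.roll(fret, shift=channel_offset, axis=(0, 1))
        lam = np.concatenate([donor, fret], axis=1) * dt
        if stochastic:
            frames[i] = apply_camera_noise(lam, camera, rng)
        else:
            frames[i] = lam * camera.gain
    return Movie(frames, frame_interval=dt, pixel_scale=phantom.pixel_scale,
                 channel_label="splitfield")


def render_transmitted_movie(
    phantom: EmbryoPhantom,
    schedule: SpikeSchedule,
    camera: CameraModel,
    seed=None,
    displacement: float = 40.0,  # µm
    contraction_duration: float = 0.5,  # s
    stochastic: bool = True,
    embryo_rate: float = 2000.0,  # photons/s/pixel inside the embryo
    background_rate: float = 200.0,  # photons/s/pixel outside
) -> Movie:
    """Render a transmitted-light contraction movie.

    During each scheduled event the embryo texture is displaced laterally
    (perpendicular to the body axis) by ``displacement`` µm for
    ``contraction_duration`` s; the background outside the embryo is
    unaffected by the displacement.
    """
    _check_shapes(phantom, camera)
    rng = np.random.default_rng(seed)
    dt = camera.integration_time
    h, w = phantom.image_shape
    n = int(round(schedule.duration / dt)) if schedule.duration else 1

    texture = np.zeros((h, w), dtype=float)
    # Alternating somite shading gives the embryo visible internal contrast.
    for i, m in enumerate(phantom.somite_masks):
        texture[m] = embryo_rate * (1.1 if i % 2 else 0.9)
    texture[phantom.trunk_mask & (texture == 0)] = embryo_rate

    disp_px = int(round(displacement / phantom.pixel_scale))
    shifted = np.roll(texture, -disp_px, axis=0) if disp_px else texture

    base = np.full((h, w), background_rate, dtype=float)
    rest_frame = base + texture
    move_frame = base + shifted

    onsets = schedule.event_onsets
    frames = np.empty((n, h, w), dtype=np.float32)
    for i in range(n):
        t_mid = (i + 0.5) * dt
        active = np.any((onsets <= t_mid) & (t_mid < onsets + contraction_duration))
        lam = (move_frame if active else rest_frame) * dt
        if stochastic:
            frames[i] = apply_camera_noise(lam, camera, rng)
        else:
            frames[i] = lam * camera.gain
    return Movie(frames, frame_interval=dt, pixel_scale=phantom.pixel_scale,
                 channel_label="transmitted")
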