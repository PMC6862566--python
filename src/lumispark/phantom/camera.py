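"""Camera/acquisition model and calibration arithmetic.

Pixel counts are Poisson in the expected photon number per frame (signal +
substrate glow over the embryo + dark rate), scaled by the camera gain, with
additive Gaussian read noise, clipped to the 16-bit range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

UINT16_MAX = 65535.0


@dataclass
class CameraModel:
    """Acquisition geometry and noise of the imaging camera."""

    sensor_pixels: tuple[int, int] = (512, 512)
    binning: int = 4
    integration_time: float = 0.213  # s  (≈ 4.7 Hz)
    gain: float = 1.0  # output units per photon
    read_noise_sd: float = 0.1  # output units
    substrate_glow_rate: float = 0.02  # photons/s/pixel over the embryo
    dark_rate: float = 0.02  # photons/s/pixel everywhere

    def __post_init__(self) -> None:
        h, w = self.sensor_pixels
        if self.binning <= 0 or h % self.binning or w % self.binning:
            raise ValueError("binning must be positive and divide sensor dimensions")
        if self.integration_time <= 0:
            raise ValueError("integration time must be positive")
        for name in ("gain", "read_noise_sd", "substrate_glow_rate", "dark_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def binned_shape(self) -> tuple[int, int]:
        h, w = self.sensor_pixels
        return (h // self.binning, w // self.binning)

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.integration_time

    @classmethod
    def for_binned_shape(cls, shape: tuple[int, int], binning: int = 4, **kw) -> "CameraModel":
        """Camera whose binned frame matches ``shape``."""
        return cls(sensor_pixels=(shape[0] * binning, shape[1] * binning),
                   binning=binning, **kw)


@dataclass
class Movie:
    """Calibrated frame stack."""

    frames: np.ndarray  # (T, H, W), arbitrary units, >= 0
    frame_interval: float  # s
    pixel_scale: float  # µm / pixel
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if np.any(self.frames < 0):
            raise ValueError("pixel values must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    def times(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 0.5) * self.frame_interval


def apply_camera_noise(expected_counts: np.ndarray, camera: CameraModel,
                       rng: np.random.Generator) -> np.ndarray:
    """Poisson photon statistics + gain + Gaussian read noise, 16-bit clipped."""
    counts = rng.poisson(expected_counts).astype(np.float64)
    out = counts * camera.gain
    if camera.read_noise_sd > 0:
        out = out + rng.normal(0.0, camera.read_noise_sd, size=out.shape)
    return np.clip(out, 0.0, UINT16_MAX)


def field_of_view(sensor_pixels: int, binning: int,
                  scale_per_binned_pixel: float, split_halves: int = 1) -> float:
    """Field-of-view side length in µm.

    FOV = (sensor / binning / split_halves) × µm-per-binned-pixel; e.g.
    512 px at 4×4 binning and 12.8 µm/px → 1638.4 µm, and a 2048 px sensor at
    4×4 binning split in two half-fields at 2.9 µm/px → 742.4 µm.
    """
    if binning <= 0:
        raise ValueError("binning must be positive")
    if split_halves <= 0:
        raise ValueError("split_halves must be positive")
    return (sensor_pixels // binning // split_halves) * scale_per_binned_pixel


def acquisition_frequency(integration_time: float) -> float:
    """Frame rate in Hz from the integration time, rounded to one decimal.

    84 ms → 11.9 Hz; 213 ms → 4.7 Hz; 1000 ms → 1.0 Hz.
    """
    if integration_time <= 0:
        raise ValueError("integration time must be positive")
    return round(1.0 / integration_time, 1)
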