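"""Split-field FRET processing: registration, pixel-wise ratio, photobleaching.

The camera field holds the donor image in one half and the FRET (acceptor)
image in the other, acquired truly simultaneously through an image splitter.
The FRET half is registered onto the donor half by the integer translation
maximizing the normalized cross-correlation on a reference frame, the
FRET/donor ratio is computed pixel by pixel wherever the donor is above a
floor, and channel photobleaching is quantified by a mono-exponential fit to
event-free channel means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom.camera import Movie


@dataclass
class RatioMovie:
    """Co-registered donor/FRET stacks and their pixel-wise ratio."""

    donor_stack: np.ndarray
    fret_stack: np.ndarray
    ratio_stack: np.ndarray  # NaN where invalid
    validity_mask: np.ndarray  # (T, H, W) bool
    frame_interval: float
    pixel_scale: float

    def roi_trace(self, roi: np.ndarray) -> np.ndarray:
        """Per-frame mean ratio over the valid pixels of ``roi``."""
        roi = np.asarray(roi, dtype=bool)
        out = np.empty(self.ratio_stack.shape[0])
        for i, (r, v) in enumerate(zip(self.ratio_stack, self.validity_mask)):
            sel = roi & v
            out[i] = r[sel].mean() if sel.any() else np.nan
        return out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def register_offset(reference: np.ndarray, moving: np.ndarray,
                    search_radius: int = 10) -> tuple[int, int]:
    """Integer translation (dy, dx) of ``moving`` relative to ``reference``.

    Exhaustive search over ±``search_radius`` maximizing the normalized
    cross-correlation of the overlapping region; warns when the optimum lies
    on the search-window edge (possible misregistration).
    """
    best, best_shift = -np.inf, (0, 0)
    r = search_radius
    h, w = reference.shape
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            # hypothesis: moving(x) = reference(x - (dy, dx))
            y0, y1 = max(0, dy), min(h, h + dy)
            x0, x1 = max(0, dx), min(w, w + dx)
            mov_part = moving[y0:y1, x0:x1]
            ref_part = reference[y0 - dy : y1 - dy, x0 - dx : x1 - dx]
            c = _ncc(ref_part, mov_part)
            if c > best:
                best, best_shift = c, (dy, dx)
    if max(abs(best_shift[0]), abs(best_shift[1])) == r and r > 0:
        warnings.warn("correlation peak on search-window edge; "
                      "possible misregistration", stacklevel=2)
    return best_shift


def split_and_register(
    movie: Movie,
    layout: str = "horizontal",
    search_radius: int = 10,
    reference_frame: int = 0,
):
    """Split a side-by-side field into donor and FRET stacks and co-register.

    Returns ``(donor_stack, fret_stack, offset)``; the recovered integer
    offset is removed from every FRET frame (circular shift — adequate for
    the small splitter misalignments this handles).
    """
    frames = movie.frames
    if layout != "horizontal":
        raise ValueError("only the horizontal side-by-side layout is supported")
    w = frames.shape[2]
    if w % 2:
        raise ValueError("field width must be even for a half-field split")
    donor = np.asarray(frames[:, :, : w // 2], dtype=float)
    fret = np.asarray(frames[:, :, w // 2 :], dtype=float)
    offset = register_offset(donor[reference_frame], fret[reference_frame],
                             search_radius)
    if offset != (0, 0):
        fret = np.roll(fret, shift=(-offset[0], -offset[1]), axis=(1, 2))
    return donor, fret, offset


def ratio_stack(donor: np.ndarray, fret: np.ndarray,
                donor_floor_pct: float = 1.0,
                frame_interval: float = 1.0,
                pixel_scale: float = 1.0) -> RatioMovie:
    """Pixel-wise FRET/donor ratio wherever the donor is above a floor.

    The floor is the ``donor_floor_pct`` percentile of nonzero donor pixels
    (guards against near-zero division).  Pixels at or below the floor are
    NaN in the ratio stack and False in the validity mask.
    """
    donor = np.asarray(donor, dtype=float)
    fret = np.asarray(fret, dtype=float)
    if donor.shape != fret.shape:
        raise ValueError("donor and FRET stacks must share one shape")
    nonzero = donor[donor > 0]
    if nonzero.size == 0:
        raise ValueError("donor stack has no positive pixels")
    floor = float(np.percentile(nonzero, donor_floor_pct))
    validity = donor >= floor
    if not validity.any():
        raise ValueError("empty validity mask: donor never exceeds the floor")
    ratio = np.full_like(donor, np.nan)
    np.divide(fret, donor, out=ratio, where=validity)
    return RatioMovie(donor, fret, ratio, validity, frame_interval, pixel_scale)


def bleaching_summary(channel_means, times, horizon: float = 900.0) -> dict:
    """Quantify photobleaching from event-free channel means.

    Fits I(t) = I0·exp(−t/τ) by least squares on log intensities and reports
    the percent decline 100 × (1 − exp(−horizon/τ)) at the requested horizon
    (s).  A non-decaying trace reports τ = inf and 0% decline.
    """
    y = np.asarray(channel_means, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least two event-free time points")
    if np.any(y <= 0):
        raise ValueError("channel means must be positive for an exponential fit")
    slope, intercept = np.polyfit(t, np.log(y), 1)
    if slope >= -1e-12:  # non-decaying up to fit round-off
        return {"tau": float("inf"), "decline_percent": 0.0,
                "i0": float(np.exp(intercept))}
    tau = -1.0 / slope
    return {
        "tau": float(tau),
        "decline_percent": 100.0 * (1.0 - float(np.exp(-horizon / tau))),
        "i0": float(np.exp(intercept)),
    }
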