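"""Phase extraction from optical-mapping movies and input conditioning.

Cardiac optical mapping yields a per-pixel time series of fractional
fluorescence.  Wavefront analysis is done in the *phase domain*: for each
pixel the temporal mean is removed, the analytic signal ``x + i H[x]`` is
formed with the discrete (FFT-based) Hilbert transform over the full
recording, and its angle gives the instantaneous phase in [-pi, pi].
Wavefronts live at the pi -> -pi phase wrap.

Also here: Gaussian contact/sensor noise injection on the raw signal
(applied *before* the Hilbert step, as an electrode-contact noise model),
spatial cropping (e.g. trimming pacing-electrode artifacts), and the
linear [-pi, pi] -> [-1, 1] rescaling that turns a phase frame into a
network input map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "RawRecording",
    "PhaseMovie",
    "CropRegion",
    "hilbert_phase",
    "add_input_noise",
    "crop",
    "phase_to_input",
    "input_to_phase",
]

#: minimum frames for a meaningful analytic-signal estimate
MIN_FRAMES = 8


@dataclass
class RawRecording:
    """Time-series movie: frames (T, H, W), nominal sampling rate in Hz."""

    frames: np.ndarray
    frame_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.shape[0] < MIN_FRAMES:
            raise ValueError(f"need at least {MIN_FRAMES} frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("recording contains non-finite samples")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.frames.shape


@dataclass
class PhaseMovie:
    """Instantaneous phase in [-pi, pi] per frame and pixel (T, H, W).

    NaN entries mark degenerate pixels (constant-in-time signal, artifact
    regions) whose phase is undefined.
    """

    phase: np.ndarray
    frame_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 3:
            raise ValueError("phase must be a (T, H, W) array")
        finite = self.phase[np.isfinite(self.phase)]
        if finite.size and (finite.min() < -np.pi - 1e-9 or finite.max() > np.pi + 1e-9):
            raise ValueError("phase values outside [-pi, pi]")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.phase.shape


@dataclass(frozen=True)
class CropRegion:
    """0-based, half-open spatial window (row0:row0+height, col0:col0+width)."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if min(self.row0, self.col0) < 0 or min(self.height, self.width) < 1:
            raise ValueError("invalid crop region")

    def slices(self) -> Tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )


def hilbert_phase(rec: RawRecording) -> PhaseMovie:
    """Per-pixel instantaneous phase of a recording via the analytic signal.

    The temporal mean is removed per pixel before the FFT-based Hilbert
    transform.  Pixels with zero temporal variance have no defined phase:
    they are returned as NaN and a warning names how many were flagged.
    """
    x = rec.frames
    centered = x - x.mean(axis=0, keepdims=True)
    degenerate = (x.max(axis=0) - x.min(axis=0)) == 0.0
    analytic = hilbert(centered, axis=0)
    phase = np.angle(analytic)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant-in-time pixel(s) have undefined "
            "instantaneous phase; flagged as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        phase[:, degenerate] = np.nan
    return PhaseMovie(phase, rec.frame_rate_hz)


def add_input_noise(
    rec: RawRecording, sigma: float, rng: np.random.Generator
) -> RawRecording:
    """Add i.i.d. N(0, sigma^2) to every sample of the raw recording."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        return RawRecording(rec.frames.copy(), rec.frame_rate_hz)
    noisy = rec.frames + rng.normal(0.0, sigma, size=rec.frames.shape)
    return RawRecording(noisy, rec.frame_rate_hz)


def crop(movie, region: CropRegion):
    """Spatial crop of a RawRecording or PhaseMovie (frames untouched)."""
    rs, cs = region.slices()
    if isinstance(movie, RawRecording):
        data = movie.frames
    elif isinstance(movie, PhaseMovie):
        data = movie.phase
    else:
        raise TypeError("crop expects a RawRecording or PhaseMovie")
    h, w = data.shape[1], data.shape[2]
    if region.row0 + region.height > h or region.col0 + region.width > w:
        raise ValueError(
            f"crop region {region} exceeds grid {h}x{w}"
        )
    out = data[:, rs, cs].copy()
    if isinstance(movie, RawRecording):
        return RawRecording(out, movie.frame_rate_hz)
    return PhaseMovie(out, movie.frame_rate_hz)


def phase_to_input(phase_frame: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Rescale one phase frame from [-pi, pi] to the network input range
    [-1, 1].  NaN (degenerate) pixels map to 0; the returned boolean mask
    is True where the input was NaN."""
    phase_frame = np.asarray(phase_frame, dtype=float)
    mask = ~np.isfinite(phase_frame)
    u = np.where(mask, 0.0, phase_frame / np.pi)
    return u, mask


def input_to_phase(u: np.ndarray) -> np.ndarray:
    """Inverse of :func:`phase_to_input` on unmasked pixels."""
    return np.asarray(u, dtype=float) * np.pi
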