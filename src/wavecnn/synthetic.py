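"""Synthetic optical-mapping generator with analytic ground truth.

Emulates the statistical structure of fibrillating-heart optical-mapping
data: per-pixel quasi-periodic activation signals whose instantaneous
phase forms planar travelling waves or spiral (rotor) waves, with the
wavefront at the pi -> -pi phase wrap.  The generator provides the exact
(analytic) phase field, a rendered raw movie, an algorithmic wavefront
labeler, and a reproducible train/test dataset builder with optional
sensor noise and a constant-valued artifact patch standing in for a
pacing electrode.

Default study conditions
------------------------
* grid 70 x 35 pixels (the cropped field of view), 256 frames at 1 kHz;
* temporal frequency 4-8 Hz, the dominant-frequency band of human
  ventricular fibrillation;
* wavelength 10-24 px, so each frame carries a few well-resolved fronts;
* fractional-fluorescence amplitude 0.05 on a baseline of 1, typical of
  voltage-sensitive dye signals (so raw-signal noise sigma is measured
  against a 0.05 signal amplitude);
* planar and spiral specimens drawn with equal probability.

The wavefront labeler is an algorithmic surrogate for the study's manual
labels: a pixel is a wavefront pixel iff its phase is negative (the
"blue" side) and at least one 4-adjacent neighbor lies across the phase
branch cut (absolute phase difference > pi).  Labels are one pixel thick
by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Tuple

import numpy as np

from .preprocessing import (
    CropRegion,
    PhaseMovie,
    RawRecording,
    add_input_noise,
    hilbert_phase,
    phase_to_input,
)

__all__ = [
    "WaveSpec",
    "DatasetManifest",
    "sample_wave_spec",
    "true_phase",
    "render_raw",
    "label_wavefront",
    "generate_pairs",
    "make_dataset",
]

DEFAULT_GRID = (70, 35)
DEFAULT_FRAMES = 256
DEFAULT_FRAME_RATE = 1000.0
DEFAULT_AMPLITUDE = 0.05
DEFAULT_BASELINE = 1.0
FREQ_RANGE_HZ = (4.0, 8.0)
WAVELENGTH_RANGE_PX = (10.0, 24.0)
GENERATOR_VERSION = "1.0"


@dataclass(frozen=True)
class WaveSpec:
    """Parameters of one synthetic wave movie."""

    kind: str  # "planar" | "spiral"
    omega: float  # rad/frame temporal frequency
    wavelength_px: float
    direction_deg: float = 0.0  # planar propagation direction
    core_rc: Tuple[float, float] = (0.0, 0.0)  # spiral core (row, col)
    chirality: int = 1  # spiral handedness, +/-1
    amplitude: float = DEFAULT_AMPLITUDE
    baseline: float = DEFAULT_BASELINE
    grid: Tuple[int, int] = DEFAULT_GRID
    frames: int = DEFAULT_FRAMES
    frame_rate_hz: float = DEFAULT_FRAME_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("planar", "spiral"):
            raise ValueError(f"unknown wave kind {self.kind!r}")
        if self.wavelength_px < 4.0:
            raise ValueError("wavelength must be >= 4 px to be resolvable")
        if abs(self.omega) * self.frames < 2 * np.pi:
            raise ValueError("recording must cover at least one full cycle")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.chirality not in (-1, 1):
            raise ValueError("chirality must be +/-1")


def sample_wave_spec(
    rng: np.random.Generator,
    grid: Tuple[int, int] = DEFAULT_GRID,
    frames: int = DEFAULT_FRAMES,
) -> WaveSpec:
    """Draw a random planar or spiral wave spec (equal mixture)."""
    h, w = grid
    kind = "planar" if rng.random() < 0.5 else "spiral"
    freq = rng.uniform(*FREQ_RANGE_HZ)
    # negative temporal frequency so the wrapped phase *advances* in time,
    # matching the positive-frequency convention of the analytic signal
    # (the rendered cosine is identical either way; only labels care)
    omega = -2 * np.pi * freq / DEFAULT_FRAME_RATE
    wavelength = rng.uniform(*WAVELENGTH_RANGE_PX)
    return WaveSpec(
        kind=kind,
        omega=omega,
        wavelength_px=wavelength,
        direction_deg=float(rng.uniform(0.0, 360.0)),
        core_rc=(
            float(rng.uniform(h / 4, 3 * h / 4)),
            float(rng.uniform(w / 4, 3 * w / 4)),
        ),
        chirality=int(rng.choice((-1, 1))),
        grid=grid,
        frames=frames,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _wrap(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi] (pi maps to -pi... strictly (-pi, pi])."""
    return np.angle(np.exp(1j * phi))


def _spatial_phase(spec: WaveSpec) -> np.ndarray:
    """Time-independent part of the phase field (unwrapped)."""
    h, w = spec.grid
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    if spec.kind == "planar":
        theta = np.deg2rad(spec.direction_deg)
        return 2 * np.pi * (cols * np.cos(theta) + rows * np.sin(theta)) / spec.wavelength_px
    r0, c0 = spec.core_rc
    dr = rows - r0
    dc = cols - c0
    rho = np.hypot(dr, dc)
    return spec.chirality * np.arctan2(dr, dc) + 2 * np.pi * rho / spec.wavelength_px


def true_phase(spec: WaveSpec, frame_index: int) -> np.ndarray:
    """Analytic phase field of the wave at one frame, wrapped to [-pi, pi]."""
    return _wrap(_spatial_phase(spec) - spec.omega * float(frame_index))


def render_raw(spec: WaveSpec) -> RawRecording:
    """Render the raw movie: amplitude * cos(phase) + baseline per frame."""
    spatial = _spatial_phase(spec)
    t = np.arange(spec.frames, dtype=float)[:, None, None]
    frames = spec.amplitude * np.cos(spatial[None] - spec.omega * t) + spec.baseline
    return RawRecording(frames, spec.frame_rate_hz)


def label_wavefront(phase: np.ndarray) -> np.ndarray:
    """Binary wavefront label map from one phase frame.

    A pixel is wavefront (-1) iff its phase is negative and at least one
    4-adjacent neighbor lies across the pi -> -pi branch cut (absolute
    phase difference > pi); all other pixels, including NaN-phase pixels,
    are nonwavefront (+1).
    """
    phi = np.asarray(phase, dtype=float)
    if phi.ndim != 2:
        raise ValueError("label_wavefront expects a single 2-D phase frame")
    crossing = np.zeros(phi.shape, dtype=bool)
    for shift_axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb = np.full_like(phi, np.nan)
        src = [slice(None), slice(None)]
        dst = [slice(None), slice(None)]
        if shift == 1:
            src[shift_axis] = slice(1, None)
            dst[shift_axis] = slice(None, -1)
        else:
            src[shift_axis] = slice(None, -1)
            dst[shift_axis] = slice(1, None)
        nb[tuple(dst)] = phi[tuple(src)]
        with np.errstate(invalid="ignore"):
            crossing |= np.abs(nb - phi) > np.pi
    with np.errstate(invalid="ignore"):
        wavefront = crossing & (phi < 0)
    return np.where(wavefront, -1.0, 1.0)


@dataclass
class DatasetManifest:
    """Provenance record of a generated dataset."""

    entries: List[dict] = field(default_factory=list)
    global_seed: int = 0
    generator_version: str = GENERATOR_VERSION

    def as_dict(self) -> dict:
        return {
            "generator_version": self.generator_version,
            "global_seed": self.global_seed,
            "entries": self.entries,
        }


def _make_pair(
    spec: WaveSpec,
    noise_sigma: float,
    artifact_region: Optional[CropRegion],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One (input u, label d, exclude mask, phase frame) training pair.

    The movie is rendered, optionally noised and given a constant-valued
    artifact patch, Hilbert-transformed, and the center frame extracted
    (away from analytic-signal edge effects).  The label is derived from
    the same recovered phase frame the network sees.
    """
    rec = render_raw(spec)
    if artifact_region is not None:
        rs, cs = artifact_region.slices()
        rec.frames[:, rs, cs] = spec.baseline
    if noise_sigma > 0:
        rec = add_input_noise(rec, noise_sigma, rng)
        if artifact_region is not None:
            # electrode patch stays saturated/constant even under noise
            rs, cs = artifact_region.slices()
            rec.frames[:, rs, cs] = spec.baseline
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        movie = hilbert_phase(rec)
    frame = movie.phase[spec.frames // 2]
    u, mask = phase_to_input(frame)
    d = label_wavefront(frame)
    return u, d, mask, frame


def generate_pairs(
    n: int,
    rng: np.random.Generator,
    grid: Tuple[int, int] = DEFAULT_GRID,
    frames: int = DEFAULT_FRAMES,
    noise_sigma: float = 0.0,
    artifact_region: Optional[CropRegion] = None,
    spec_sampler: Optional[Callable[[np.random.Generator], WaveSpec]] = None,
) -> Tuple[List[Tuple[np.ndarray, np.ndarray, np.ndarray]], List[WaveSpec]]:
    """Generate ``n`` in-memory (input, label, mask) pairs plus their specs."""
    if n < 1:
        raise ValueError("need at least one sample")
    sampler = spec_sampler or (lambda r: sample_wave_spec(r, grid, frames))
    pairs = []
    specs = []
    for _ in range(n):
        spec = sampler(rng)
        u, d, mask, _ = _make_pair(spec, noise_sigma, artifact_region, rng)
        pairs.append((u, d, mask))
        specs.append(spec)
    return pairs, specs


def make_dataset(
    root,
    n_train: int,
    n_test: int,
    seed: int = 0,
    grid: Tuple[int, int] = DEFAULT_GRID,
    frames: int = DEFAULT_FRAMES,
    noise_sigma: float = 0.0,
    artifact_region: Optional[CropRegion] = None,
    spec_sampler: Optional[Callable[[np.random.Generator], WaveSpec]] = None,
) -> DatasetManifest:
    """Write a train/test dataset of phase/label image pairs to disk.

    Layout: ``<root>/{train,test}/<id>_phase.png`` and ``..._label.png``
    (16-bit grayscale; phase mapped linearly from [-pi, pi]) plus
    ``<root>/manifest.json``.  Fully reproducible from ``seed``.
    """
    from .io import save_label_png16, save_phase_png16

    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must be >= 1")
    root = Path(root)
    rng = np.random.default_rng(seed)
    sampler = spec_sampler or (lambda r: sample_wave_spec(r, grid, frames))
    manifest = DatasetManifest(global_seed=seed)
    for split, count in (("train", n_train), ("test", n_test)):
        split_dir = root / split
        split_dir.mkdir(parents=True, exist_ok=True)
        for i in range(count):
            spec = sampler(rng)
            u, d, mask, frame = _make_pair(spec, noise_sigma, artifact_region, rng)
            phase_file = split_dir / f"{i:04d}_phase.png"
            label_file = split_dir / f"{i:04d}_label.png"
            save_phase_png16(frame, phase_file)
            save_label_png16(d, label_file)
            entry = {
                "split": split,
                "phase": str(phase_file.relative_to(root)),
                "label": str(label_file.relative_to(root)),
                "spec": asdict(spec),
            }
            manifest.entries.append(entry)
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest.as_dict(), fh, indent=1)
    return manifest
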