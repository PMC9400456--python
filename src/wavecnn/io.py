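"""Serialization: HDF5 movie/phase containers, 16-bit PNG export, and
template JSON/CSV files.

Conventions
-----------
* Templates as JSON: ``{"A": 3x3, "B": 3x3, "I": scalar,
  "neighborhood": 4|8, "bits": int|null}``; CSV export writes rows
  A1..A3, B1..B3, I.
* Movies as HDF5: dataset ``frames`` (raw) or ``phase``, attribute
  ``frame_rate_hz``.  Single phase/label frames as HDF5 datasets
  ``phase``/``label`` with ``height``/``width``/``frame_rate_hz``
  attributes.
* PNG16: phase mapped linearly [-pi, pi] -> [0, 65535] (NaN -> 0);
  labels: wavefront (-1) -> 0, nonwavefront (+1) -> 65535.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Tuple

import h5py
import numpy as np
from PIL import Image

from .core import Neighborhood, TemplateSet
from .preprocessing import PhaseMovie, RawRecording

__all__ = [
    "save_templates_json",
    "load_templates_json",
    "save_templates_csv",
    "save_recording_h5",
    "load_recording_h5",
    "save_phase_movie_h5",
    "load_phase_movie_h5",
    "save_frame_pair_h5",
    "load_frame_pair_h5",
    "save_phase_png16",
    "load_phase_png16",
    "save_label_png16",
    "load_label_png16",
]


# ---------------------------------------------------------------- templates

def save_templates_json(
    theta: TemplateSet,
    path,
    neighborhood: Neighborhood = Neighborhood.EIGHT,
    bits: Optional[int] = None,
) -> None:
    doc = {
        "A": theta.A.tolist(),
        "B": theta.B.tolist(),
        "I": theta.I,
        "neighborhood": neighborhood.value,
        "bits": bits,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_templates_json(path) -> Tuple[TemplateSet, Neighborhood, Optional[int]]:
    with open(path) as fh:
        doc = json.load(fh)
    theta = TemplateSet(np.array(doc["A"]), np.array(doc["B"]), float(doc["I"]))
    nb = Neighborhood(int(doc.get("neighborhood", 8)))
    bits = doc.get("bits")
    return theta, nb, None if bits is None else int(bits)


def save_templates_csv(theta: TemplateSet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for label, row in zip(("A1", "A2", "A3"), theta.A):
            w.writerow([label, *row])
        for label, row in zip(("B1", "B2", "B3"), theta.B):
            w.writerow([label, *row])
        w.writerow(["I", theta.I])


# ------------------------------------------------------------------- movies

def save_recording_h5(rec: RawRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=rec.frames)
        f.attrs["frame_rate_hz"] = rec.frame_rate_hz


def load_recording_h5(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        return RawRecording(f["frames"][()], float(f.attrs["frame_rate_hz"]))


def save_phase_movie_h5(movie: PhaseMovie, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("phase", data=movie.phase)
        f.attrs["frame_rate_hz"] = movie.frame_rate_hz


def load_phase_movie_h5(path) -> PhaseMovie:
    with h5py.File(path, "r") as f:
        return PhaseMovie(f["phase"][()], float(f.attrs["frame_rate_hz"]))


def save_frame_pair_h5(
    phase: np.ndarray, label: np.ndarray, path, frame_rate_hz: float = 1000.0
) -> None:
    """One phase frame plus its binary wavefront label in a single file."""
    phase = np.asarray(phase, dtype=float)
    label = np.asarray(label, dtype=float)
    with h5py.File(path, "w") as f:
        f.create_dataset("phase", data=phase)
        f.create_dataset("label", data=label)
        f.attrs["height"] = phase.shape[0]
        f.attrs["width"] = phase.shape[1]
        f.attrs["frame_rate_hz"] = frame_rate_hz


def load_frame_pair_h5(path) -> Tuple[np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        return f["phase"][()], f["label"][()]


# -------------------------------------------------------------------- PNG16

def save_phase_png16(phase_frame: np.ndarray, path) -> None:
    """Phase frame to 16-bit grayscale PNG, [-pi, pi] -> [0, 65535]."""
    phi = np.asarray(phase_frame, dtype=float)
    scaled = (phi + np.pi) / (2 * np.pi) * 65535.0
    scaled = np.where(np.isfinite(scaled), scaled, 0.0)
    img = np.clip(np.round(scaled), 0, 65535).astype(np.uint16)
    Image.fromarray(img).save(Path(path))


def load_phase_png16(path) -> np.ndarray:
    img = np.asarray(Image.open(Path(path)), dtype=float)
    return img / 65535.0 * 2 * np.pi - np.pi


def save_label_png16(label: np.ndarray, path) -> None:
    """Binary label to PNG16: wavefront (-1) black, nonwavefront (+1) white."""
    lab = np.asarray(label)
    img = np.where(lab == -1, 0, 65535).astype(np.uint16)
    Image.fromarray(img).save(Path(path))


def load_label_png16(path) -> np.ndarray:
    img = np.asarray(Image.open(Path(path)))
    return np.where(img < 32768, -1.0, 1.0)
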