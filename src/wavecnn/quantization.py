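"""Limited-bit-precision template arithmetic and device nonidealities.

Memristive template storage cannot hold float64 weights.  This module
models three hardware effects on the 19 template parameters (A, B, I):

* **Quantization** onto a uniform grid of ``2**bits`` conductance levels
  spanning a normalized range (default [-1, +1]), with either
  round-to-nearest (ties to even) or *stochastic rounding*: a value ``v``
  bracketed by levels ``A1 <= v <= A2`` rounds up to ``A2`` with
  probability ``(v - A1)/(A2 - A1)``, so the rounded value is unbiased.
* **Read noise**: i.i.d. Gaussian perturbation (mean 0, level-independent
  sigma) of every parameter, redrawn at each read/inference.
* **Stuck devices** (yield loss): a fraction of the 19 parameter positions
  frozen at the grid maximum (ON), minimum (OFF), or a fair mix.

Values outside the grid range are clipped before rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import TemplateSet

__all__ = [
    "QuantizationGrid",
    "RoundingMode",
    "StuckMode",
    "NoiseConfig",
    "build_grid",
    "round_nearest",
    "round_stochastic",
    "quantize_templates",
    "apply_read_noise",
    "apply_stuck",
]

N_PARAMS = 19  # 9 feedback + 9 control weights + bias


class RoundingMode(Enum):
    NEAREST = "nearest"
    STOCHASTIC = "stochastic"


class StuckMode(Enum):
    ON = "on"
    OFF = "off"
    MIXED = "mixed"


@dataclass(frozen=True)
class QuantizationGrid:
    """Uniform conductance-level grid: 2**bits levels spanning [lo, hi]."""

    bits: int
    lo: float = -1.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.bits <= 16:
            raise ValueError(f"bits must be in [1, 16], got {self.bits}")
        if not self.lo < self.hi:
            raise ValueError("grid range is empty")

    @property
    def n_levels(self) -> int:
        return 2 ** self.bits

    @property
    def spacing(self) -> float:
        return (self.hi - self.lo) / (self.n_levels - 1)

    @property
    def levels(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_levels)


@dataclass(frozen=True)
class NoiseConfig:
    """Inference-time nonideality settings."""

    read_sigma: float = 0.0
    stuck_fraction: float = 0.0
    stuck_mode: StuckMode = StuckMode.MIXED
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")
        if not 0.0 <= self.stuck_fraction <= 1.0:
            raise ValueError("stuck_fraction must be in [0, 1]")


def build_grid(bits: int, lo: float = -1.0, hi: float = 1.0) -> QuantizationGrid:
    return QuantizationGrid(bits=bits, lo=lo, hi=hi)


def _positions(v: np.ndarray, grid: QuantizationGrid) -> np.ndarray:
    """Clip into range and express as fractional level index."""
    v = np.clip(np.asarray(v, dtype=float), grid.lo, grid.hi)
    return (v - grid.lo) / grid.spacing


def round_nearest(v, grid: QuantizationGrid):
    """Round (scalar or array) to the nearest grid level, ties to the level
    with even 0-based index — the IEEE-style default rounding."""
    p = _positions(v, grid)
    # np.round implements round-half-to-even on the index scale
    idx = np.round(p)
    out = grid.lo + idx * grid.spacing
    return float(out) if np.isscalar(v) or np.ndim(v) == 0 else out


def round_stochastic(v, grid: QuantizationGrid, rng: np.random.Generator):
    """Round probabilistically to a bracketing level; unbiased in expectation.

    For v between levels A1 < A2: up to A2 with probability (v-A1)/(A2-A1),
    else down to A1.  A value already on a level is returned unchanged.
    """
    p = _positions(v, grid)
    lower = np.floor(p)
    frac = p - lower
    up = rng.random(np.shape(p)) < frac
    idx = lower + up
    out = grid.lo + idx * grid.spacing
    return float(out) if np.isscalar(v) or np.ndim(v) == 0 else out


def quantize_templates(
    theta: TemplateSet,
    grid: QuantizationGrid,
    mode: RoundingMode = RoundingMode.NEAREST,
    rng: np.random.Generator | None = None,
) -> TemplateSet:
    """Map every template entry and the bias through the chosen rounding.

    Quantization-aware training calls this after every weight update;
    post-training quantization calls it once on the final templates.
    """
    if mode is RoundingMode.NEAREST:
        f = lambda v: round_nearest(v, grid)
    else:
        if rng is None:
            raise ValueError("stochastic rounding needs an rng")
        f = lambda v: round_stochastic(v, grid, rng)
    return TemplateSet(f(theta.A), f(theta.B), float(f(theta.I)))


def apply_read_noise(
    theta: TemplateSet, sigma: float, rng: np.random.Generator
) -> TemplateSet:
    """Add i.i.d. N(0, sigma^2) to all 19 parameters (fresh draw per call,
    modelling read-time noise rather than a programming error)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        return theta.copy()
    v = theta.flat() + rng.normal(0.0, sigma, size=N_PARAMS)
    return TemplateSet.from_flat(v)


def apply_stuck(
    theta: TemplateSet,
    fraction: float,
    mode: StuckMode,
    grid: QuantizationGrid,
    rng: np.random.Generator,
) -> TemplateSet:
    """Freeze ceil(fraction * 19) parameter positions at a grid extreme.

    Positions are drawn uniformly without replacement over all 19
    parameters (bias included).  ON -> grid maximum, OFF -> grid minimum,
    MIXED -> independent fair coin per stuck position.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n_stuck = int(np.ceil(fraction * N_PARAMS))
    if n_stuck == 0:
        return theta.copy()
    v = theta.flat()
    pos = rng.choice(N_PARAMS, size=n_stuck, replace=False)
    if mode is StuckMode.ON:
        v[pos] = grid.hi
    elif mode is StuckMode.OFF:
        v[pos] = grid.lo
    else:
        v[pos] = np.where(rng.random(n_stuck) < 0.5, grid.hi, grid.lo)
    return TemplateSet.from_flat(v)
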