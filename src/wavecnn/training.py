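"""Template training: adapted stochastic-gradient backpropagation with
batch updates, plus the binarization schemes used during or after training.

For desired label map ``d`` (wavefront -1, nonwavefront +1) and network
output ``y*`` the per-cell loss is the half squared error
``e_ij = 1/2 (d_ij - y*_ij)^2`` and the gradient signal is the residual
``d_ij - y*_ij``.  Template updates (learning rate eta) average the
per-cell contributions over the grid,

    da_mn = 1/(H W) sum_ij err_ij * y*_{i+m-2, j+n-2}
    db_mn = 1/(H W) sum_ij err_ij * u_{i+m-2, j+n-2}
    dI    = 1/(H W) sum_ij err_ij

and batch training averages these per-sample updates over the batch
before applying ``theta <- theta + eta * delta``.

Binarization thresholds are quoted as a percentage of the [-1, 1] output
range: p% maps to the output value -1 + 2p/100, so 50% is 0 (the range
midpoint).  In "during" mode the output is thresholded before it enters
the error and the gradients; in "after" (or "none") mode the grayscale
output is used throughout and thresholding happens only at evaluation.
Training history always records metrics binarized at 50% so convergence
curves are comparable across modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    DivergenceError,
    IntegrationConfig,
    Neighborhood,
    TemplateSet,
    infer_batch,
)
from .metrics import ConfusionCounts, MetricsRecord, aggregate, confusion
from .quantization import QuantizationGrid, RoundingMode, quantize_templates

__all__ = [
    "InitScheme",
    "BinarizationMode",
    "TemplateGradient",
    "TrainingConfig",
    "EpochRecord",
    "TrainingHistory",
    "initialize_templates",
    "cell_error",
    "template_gradient",
    "batch_gradient",
    "apply_update",
    "binarize",
    "threshold_pct_to_value",
    "train",
    "evaluate_dataset",
]

#: predefined edge-detection control template (classical CNN cloning template)
EDGE_DETECTION_B = np.array(
    [[-1.0, -1.0, -1.0], [-1.0, 8.0, -1.0], [-1.0, -1.0, -1.0]]
)
EDGE_DETECTION_I = 1.0

#: stop when the epoch mean error has varied by less than this over the
#: trailing window of epochs
CONVERGENCE_TOL = 1e-6
CONVERGENCE_WINDOW = 10


class InitScheme(Enum):
    ZERO = "zero"
    RANDOM_UNIFORM = "random_uniform"
    EDGE_DETECTION = "edge_detection"


class BinarizationMode(Enum):
    NONE = "none"
    DURING = "during"
    AFTER = "after"


@dataclass(frozen=True)
class TemplateGradient:
    dA: np.ndarray
    dB: np.ndarray
    dI: float

    def flat(self) -> np.ndarray:
        return np.concatenate([self.dA.ravel(), self.dB.ravel(), [self.dI]])


@dataclass
class TrainingConfig:
    eta: float = 0.1
    batch_size: int = 20
    epochs: int = 500
    init: InitScheme = InitScheme.RANDOM_UNIFORM
    binarization: BinarizationMode = BinarizationMode.AFTER
    threshold_pct: float = 50.0
    clip_range: Optional[Tuple[float, float]] = None
    seed: int = 0
    shuffle: bool = True
    # quantization-aware training hooks
    quant_grid: Optional[QuantizationGrid] = None
    quant_mode: RoundingMode = RoundingMode.NEAREST
    quant_when: Optional[str] = None  # "during" | "after" | None

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if not 0.0 < self.threshold_pct < 100.0:
            raise ValueError("threshold_pct must lie in (0, 100)")
        if self.quant_when not in (None, "during", "after"):
            raise ValueError("quant_when must be None, 'during' or 'after'")
        if self.quant_when is not None and self.quant_grid is None:
            raise ValueError("quant_when set but no quantization grid given")


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    iteration: int  # cumulative weight-update count k
    mean_error: float
    metrics: MetricsRecord
    templates: TemplateSet


@dataclass
class TrainingHistory:
    records: List[EpochRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def mean_errors(self) -> np.ndarray:
        return np.array([r.mean_error for r in self.records])

    def metric_series(self, name: str) -> np.ndarray:
        return np.array(
            [np.nan if getattr(r.metrics, name) is None else getattr(r.metrics, name)
             for r in self.records]
        )


def initialize_templates(
    scheme: InitScheme, rng: Optional[np.random.Generator] = None
) -> TemplateSet:
    """Build starting templates: all-zero, i.i.d. uniform on [-1, 1], or the
    predefined edge-detection cloning template (A=0, Laplacian-style B, I=1)."""
    if scheme is InitScheme.ZERO:
        return TemplateSet()
    if scheme is InitScheme.EDGE_DETECTION:
        return TemplateSet(np.zeros((3, 3)), EDGE_DETECTION_B.copy(), EDGE_DETECTION_I)
    if scheme is InitScheme.RANDOM_UNIFORM:
        if rng is None:
            raise ValueError("random initialization needs an rng")
        return TemplateSet(
            rng.uniform(-1, 1, (3, 3)), rng.uniform(-1, 1, (3, 3)),
            float(rng.uniform(-1, 1)),
        )
    raise ValueError(f"unknown initialization scheme {scheme!r}")


def cell_error(d: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-cell half squared error 1/2 (d - y)^2."""
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    if d.shape != y.shape:
        raise ValueError(f"label shape {d.shape} != output shape {y.shape}")
    return 0.5 * (d - y) ** 2


def _shift_windows(grid: np.ndarray) -> np.ndarray:
    """Stack of the 9 neighborhood shifts of ``grid`` (zero boundary).

    Returns shape (3, 3, ...) where entry (m, n) holds
    grid[..., i+m-1, j+n-1] (0-based offsets -1..+1).
    """
    pad = [(0, 0)] * (grid.ndim - 2) + [(1, 1), (1, 1)]
    g = np.pad(grid, pad)
    h, w = grid.shape[-2], grid.shape[-1]
    return np.stack(
        [np.stack([g[..., m : m + h, n : n + w] for n in range(3)]) for m in range(3)]
    )


def template_gradient(
    err_signal: np.ndarray,
    y: np.ndarray,
    u: np.ndarray,
    nb: Neighborhood = Neighborhood.EIGHT,
) -> TemplateGradient:
    """Grid-averaged template update direction from a residual map.

    Accepts leading batch axes on all three arrays, in which case the
    result is already the batch mean (identical to averaging per-sample
    gradients).  Corner entries are forced to zero under a four-neighbor
    spec.
    """
    err = np.asarray(err_signal, dtype=float)
    y = np.asarray(y, dtype=float)
    u = np.asarray(u, dtype=float)
    if not (err.shape == y.shape == u.shape):
        raise ValueError("error/output/input shapes disagree")
    norm = err.shape[-2] * err.shape[-1]
    n_batch = int(np.prod(err.shape[:-2])) if err.ndim > 2 else 1
    scale = 1.0 / (norm * n_batch)
    dA = np.tensordot(_shift_windows(y), err, axes=(range(2, err.ndim + 2),
                                                    range(err.ndim))) * scale
    dB = np.tensordot(_shift_windows(u), err, axes=(range(2, err.ndim + 2),
                                                    range(err.ndim))) * scale
    dI = float(err.sum() * scale)
    mask = nb.mask
    return TemplateGradient(np.where(mask, dA, 0.0), np.where(mask, dB, 0.0), dI)


def batch_gradient(gs: Sequence[TemplateGradient]) -> TemplateGradient:
    """Elementwise mean of per-sample gradients."""
    if not gs:
        raise ValueError("empty gradient list")
    n = len(gs)
    dA = sum(g.dA for g in gs) / n
    dB = sum(g.dB for g in gs) / n
    dI = sum(g.dI for g in gs) / n
    return TemplateGradient(dA, dB, float(dI))


def apply_update(
    theta: TemplateSet,
    g: TemplateGradient,
    eta: float,
    clip: Optional[Tuple[float, float]] = None,
) -> TemplateSet:
    """theta <- theta + eta * delta, with optional clipping to a range."""
    out = TemplateSet(
        theta.A + eta * g.dA, theta.B + eta * g.dB, theta.I + eta * g.dI
    )
    if clip is not None:
        out = out.clipped(*clip)
    return out


def binarize(y: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold a grayscale output map: +1 where y >= threshold, else -1."""
    y = np.asarray(y, dtype=float)
    return np.where(y >= threshold, 1.0, -1.0)


def threshold_pct_to_value(pct: float) -> float:
    """Map a percentage of the [-1, 1] output range to a threshold value."""
    return -1.0 + 2.0 * pct / 100.0


def _quantize(theta: TemplateSet, cfg: TrainingConfig,
              rng: np.random.Generator) -> TemplateSet:
    return quantize_templates(theta, cfg.quant_grid, cfg.quant_mode, rng)


def _prepare_dataset(dataset):
    """Normalize dataset items to (u, d, mask-or-None) triples."""
    out = []
    for item in dataset:
        if len(item) == 2:
            u, d = item
            mask = None
        else:
            u, d, mask = item
        u = np.asarray(u, dtype=float)
        d = np.asarray(d, dtype=float)
        if u.shape != d.shape:
            raise ValueError("input/label shapes disagree")
        if not np.all(np.isin(d, (-1, 1))):
            raise ValueError("label map is not binary (+/-1)")
        out.append((u, d, None if mask is None else np.asarray(mask, bool)))
    return out


def train(
    dataset,
    cfg: TrainingConfig,
    nb: Neighborhood = Neighborhood.EIGHT,
    icfg: Optional[IntegrationConfig] = None,
) -> Tuple[TemplateSet, TrainingHistory]:
    """Run batch-gradient template training over a labeled dataset.

    ``dataset`` is a sequence of (input_map, label_map) or
    (input_map, label_map, exclude_mask) items; masked pixels contribute
    neither to the loss/gradients nor to the history metrics.

    Deterministic given ``cfg.seed``: the same configuration reproduces
    the returned templates bit-exactly.
    """
    if icfg is None:
        icfg = IntegrationConfig()
    data = _prepare_dataset(dataset)
    if not data:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    theta = initialize_templates(cfg.init, rng).masked(nb)
    if cfg.quant_when == "during":
        theta = _quantize(theta, cfg, rng)

    thr = threshold_pct_to_value(cfg.threshold_pct)
    thr50 = 0.0
    history = TrainingHistory()
    iteration = 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(data)) if cfg.shuffle else np.arange(len(data))
        epoch_err_sum = 0.0
        epoch_px = 0
        epoch_counts: List[ConfusionCounts] = []
        for start in range(0, len(data), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            U = np.stack([data[i][0] for i in idx])
            D = np.stack([data[i][1] for i in idx])
            keep = np.stack(
                [np.ones(data[i][0].shape, bool) if data[i][2] is None
                 else ~data[i][2] for i in idx]
            )
            try:
                Y = infer_batch(U, theta, nb, icfg)
            except DivergenceError as exc:
                raise DivergenceError(
                    f"divergence at epoch {epoch}, batch starting at sample "
                    f"{start}: {exc}"
                ) from exc
            y_star = binarize(Y, thr) if cfg.binarization is BinarizationMode.DURING else Y
            err = (D - y_star) * keep
            epoch_err_sum += float(np.sum(0.5 * err ** 2))
            epoch_px += int(np.sum(keep))
            g = template_gradient(err, y_star, U, nb)
            theta = apply_update(theta, g, cfg.eta, cfg.clip_range).masked(nb)
            if cfg.quant_when == "during":
                theta = _quantize(theta, cfg, rng)
            iteration += 1
            # convergence tracking: 50%-binarized metrics of this pass
            pred50 = binarize(Y, thr50)
            for b, i in enumerate(idx):
                epoch_counts.append(
                    confusion(pred50[b], D[b],
                              None if data[i][2] is None else data[i][2])
                )
        mean_error = epoch_err_sum / max(epoch_px, 1)
        history.records.append(
            EpochRecord(
                epoch=epoch,
                iteration=iteration,
                mean_error=mean_error,
                metrics=aggregate(epoch_counts, "micro"),
                templates=theta.copy(),
            )
        )
        if len(history) > CONVERGENCE_WINDOW:
            window = history.mean_errors[-(CONVERGENCE_WINDOW + 1):]
            if window.max() - window.min() < CONVERGENCE_TOL:
                break

    if cfg.quant_when == "after":
        theta = _quantize(theta, cfg, rng)
    return theta, history


def evaluate_dataset(
    dataset,
    theta: TemplateSet,
    nb: Neighborhood = Neighborhood.EIGHT,
    icfg: Optional[IntegrationConfig] = None,
    threshold_pct: float = 50.0,
    how: str = "micro",
    batch_size: int = 50,
) -> Tuple[MetricsRecord, List[ConfusionCounts]]:
    """Binarized metrics of a frozen template set over a labeled dataset."""
    if icfg is None:
        icfg = IntegrationConfig()
    data = _prepare_dataset(dataset)
    thr = threshold_pct_to_value(threshold_pct)
    counts: List[ConfusionCounts] = []
    for start in range(0, len(data), batch_size):
        chunk = data[start : start + batch_size]
        U = np.stack([c[0] for c in chunk])
        Y = infer_batch(U, theta, nb, icfg)
        pred = binarize(Y, thr)
        for b, (_, d, mask) in enumerate(chunk):
            counts.append(confusion(pred[b], d, mask))
    return aggregate(counts, how), counts
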