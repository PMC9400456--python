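"""Experiment orchestration: reproducible parameter sweeps on the
synthetic benchmark.

Seven named studies mirror the standard robustness questions for this
detector: learning rate, binarization scheme, training-set size,
template bit precision (rounding method x when applied), template read
noise, device yield (stuck fraction), input noise before the Hilbert
step, and neighborhood size.

Every run gets its own seed derived by hashing (root seed, sweep name,
run index), so any results row can be re-run in isolation.  Rows are
appended to CSV as they finish (crash-safe) with a JSON sidecar of the
full configuration; failed runs are recorded and the sweep continues,
signalled by a nonzero exit status at the end.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from .core import IntegrationConfig, Neighborhood
from .quantization import QuantizationGrid, RoundingMode, StuckMode, apply_read_noise, apply_stuck
from .synthetic import generate_pairs
from .training import (
    BinarizationMode,
    InitScheme,
    TrainingConfig,
    evaluate_dataset,
    train,
)

__all__ = ["ExperimentConfig", "run_sweep", "SWEEPS", "derive_seed"]

log = logging.getLogger("wavecnn.sweep")

SWEEPS = (
    "learning_rate",
    "binarization",
    "dataset_size",
    "bit_precision",
    "read_noise",
    "yield",
    "input_noise",
    "neighborhood",
)

DEFAULT_POINTS = {
    "learning_rate": [1e-4, 1e-2, 0.1, 1.0, 100.0, 1e4],
    "binarization": ["none", "during", "after"],
    "dataset_size": [1, 10, 50, 100, 200],
    "bit_precision": [2, 4, 6, 8, 12, 16],
    "read_noise": [0.0, 0.05, 0.1, 0.2],
    "yield": [0.0, 0.01, 0.05, 0.1],
    "input_noise": [0.0, 0.002, 0.01, 0.02],
    "neighborhood": [8, 4],
}


@dataclass
class ExperimentConfig:
    """One sweep definition; round-trips losslessly through JSON/YAML."""

    sweep: str
    points: Optional[List] = None  # parameter values; None -> study default
    n_train: int = 200
    n_test: int = 50
    epochs: int = 150
    eta: float = 0.1
    batch_size: int = 20
    repeats: int = 1
    root_seed: int = 0
    out_dir: str = "results"
    # inference-robustness sweeps evaluate a fixed hardware-aware model:
    # 6-bit stochastic-rounding-during training (the deployment setting)
    eval_bits: int = 6

    def __post_init__(self) -> None:
        if self.sweep not in SWEEPS:
            raise ValueError(f"unknown sweep {self.sweep!r}; expected one of {SWEEPS}")
        if self.points is None:
            self.points = list(DEFAULT_POINTS[self.sweep])
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    def as_dict(self) -> dict:
        return asdict(self)


def derive_seed(root_seed: int, sweep: str, run_index: int) -> int:
    """Deterministic per-run seed below 2**31."""
    digest = hashlib.sha256(f"{root_seed}:{sweep}:{run_index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


CSV_FIELDS = [
    "sweep", "run_index", "repeat", "seed", "params",
    "train_accuracy", "train_precision", "train_sensitivity", "train_specificity",
    "test_accuracy", "test_precision", "test_sensitivity", "test_specificity",
    "runtime_s", "error",
]


def _metrics_cols(prefix: str, m) -> dict:
    d = m.as_dict()
    return {f"{prefix}_{k}": ("" if v is None else v) for k, v in d.items()}


def _base_training_cfg(cfg: ExperimentConfig, seed: int, **overrides) -> TrainingConfig:
    kw = dict(
        eta=cfg.eta,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        init=InitScheme.RANDOM_UNIFORM,
        binarization=BinarizationMode.AFTER,
        seed=seed,
    )
    kw.update(overrides)
    return TrainingConfig(**kw)


def _quant_cfg(cfg: ExperimentConfig, seed: int, bits: int, mode: str, when: str,
               **overrides) -> TrainingConfig:
    return _base_training_cfg(
        cfg, seed,
        clip_range=(-1.0, 1.0),
        quant_grid=QuantizationGrid(bits),
        quant_mode=RoundingMode(mode),
        quant_when=when,
        **overrides,
    )


def _enumerate_runs(cfg: ExperimentConfig) -> List[dict]:
    """Cross-product of sweep points (and sub-factors) with repeats."""
    runs = []
    for value in cfg.points:
        if cfg.sweep == "bit_precision":
            for mode in ("nearest", "stochastic"):
                for when in ("during", "after"):
                    runs.append({"bits": value, "mode": mode, "when": when})
        elif cfg.sweep == "yield":
            runs.append({"stuck_fraction": value, "stuck_mode": "mixed"})
        elif cfg.sweep == "read_noise":
            runs.append({"read_sigma": value})
        elif cfg.sweep == "input_noise":
            runs.append({"input_sigma": value})
        elif cfg.sweep == "learning_rate":
            runs.append({"eta": value})
        elif cfg.sweep == "binarization":
            runs.append({"binarization": value})
        elif cfg.sweep == "dataset_size":
            runs.append({"n_train": value})
        elif cfg.sweep == "neighborhood":
            runs.append({"neighbors": value})
    expanded = []
    for params in runs:
        for rep in range(cfg.repeats):
            expanded.append({"params": params, "repeat": rep})
    return expanded


def _execute_run(
    cfg: ExperimentConfig,
    params: dict,
    seed: int,
    repeat: int,
    datasets: dict,
    trained_cache: dict,
) -> dict:
    """Run one parameter point; returns train/test metric columns."""
    icfg = IntegrationConfig()
    train_pairs, test_pairs = datasets["train"], datasets["test"]
    nb = Neighborhood.EIGHT
    sweep = cfg.sweep

    if sweep in ("read_noise", "yield", "input_noise"):
        # evaluate one frozen hardware-aware model (per repeat) under the
        # nonideality, as in deployment: train once, perturb at read time
        deploy_seed = derive_seed(cfg.root_seed, "deploy", repeat)
        key = ("deploy", deploy_seed)
        if key not in trained_cache:
            tc = _quant_cfg(cfg, deploy_seed, cfg.eval_bits, "stochastic", "during")
            trained_cache[key] = train(train_pairs, tc, nb, icfg)[0]
        theta = trained_cache[key]
        rng = np.random.default_rng(seed + 1)
        if sweep == "read_noise":
            theta = apply_read_noise(theta, params["read_sigma"], rng)
        elif sweep == "yield":
            theta = apply_stuck(
                theta, params["stuck_fraction"], StuckMode(params["stuck_mode"]),
                QuantizationGrid(cfg.eval_bits), rng,
            )
        else:
            noisy, _ = generate_pairs(
                cfg.n_test, np.random.default_rng(derive_seed(cfg.root_seed, "noisy-test", seed)),
                noise_sigma=params["input_sigma"],
            )
            test_pairs = noisy
        m_train, _ = evaluate_dataset(train_pairs, theta, nb, icfg)
        m_test, _ = evaluate_dataset(test_pairs, theta, nb, icfg)
        return {**_metrics_cols("train", m_train), **_metrics_cols("test", m_test)}

    if sweep == "bit_precision":
        tc = _quant_cfg(cfg, seed, params["bits"], params["mode"], params["when"])
    elif sweep == "learning_rate":
        tc = _base_training_cfg(cfg, seed, eta=params["eta"])
    elif sweep == "binarization":
        tc = _base_training_cfg(cfg, seed, binarization=BinarizationMode(params["binarization"]))
    elif sweep == "dataset_size":
        tc = _base_training_cfg(cfg, seed)
        train_pairs = train_pairs[: params["n_train"]]
    elif sweep == "neighborhood":
        tc = _base_training_cfg(cfg, seed)
        nb = Neighborhood(params["neighbors"])
    else:  # pragma: no cover
        raise ValueError(sweep)

    theta, _ = train(train_pairs, tc, nb, icfg)
    m_train, _ = evaluate_dataset(train_pairs, theta, nb, icfg)
    m_test, _ = evaluate_dataset(test_pairs, theta, nb, icfg)
    return {**_metrics_cols("train", m_train), **_metrics_cols("test", m_test)}


def run_sweep(cfg: ExperimentConfig) -> int:
    """Execute a sweep; returns the number of failed runs (0 = all ok).

    Writes ``<out_dir>/<sweep>.csv`` (one row per run, appended as runs
    finish) and ``<out_dir>/<sweep>_config.json``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"{cfg.sweep}_config.json", "w") as fh:
        json.dump(cfg.as_dict(), fh, indent=1)

    data_rng = np.random.default_rng(derive_seed(cfg.root_seed, "dataset", 0))
    train_pairs, _ = generate_pairs(cfg.n_train, data_rng)
    test_pairs, _ = generate_pairs(cfg.n_test, data_rng)
    datasets = {"train": train_pairs, "test": test_pairs}

    runs = _enumerate_runs(cfg)
    csv_path = out_dir / f"{cfg.sweep}.csv"
    failures = 0
    trained_cache: dict = {}
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_FIELDS)
        writer.writeheader()
        fh.flush()
        for idx, run in enumerate(runs):
            seed = derive_seed(cfg.root_seed, cfg.sweep, idx)
            row = {
                "sweep": cfg.sweep,
                "run_index": idx,
                "repeat": run["repeat"],
                "seed": seed,
                "params": json.dumps(run["params"], sort_keys=True),
                "error": "",
            }
            t0 = time.perf_counter()
            try:
                log.info("run %d/%d: %s", idx + 1, len(runs), row["params"])
                row.update(
                    _execute_run(cfg, run["params"], seed, run["repeat"],
                                 datasets, trained_cache)
                )
            except Exception as exc:  # noqa: BLE001 - record and continue
                log.error("run %d failed: %s", idx, exc)
                row["error"] = str(exc)
                failures += 1
            row["runtime_s"] = round(time.perf_counter() - t0, 3)
            writer.writerow(row)
            fh.flush()
    return failures
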