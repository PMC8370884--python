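"""Factorial in-silico benchmark: simulate -> reconstruct -> Dice table.

Mirrors the reference in-silico study design: phantoms x detector counts x data SNRs x
methods, with the forward data generated on a fine grid and every inversion
performed on a coarser grid. Comparator reconstructions are segmented by the
clip-at-zero + mean-threshold protocol; the binary solver's output is scored
directly on its upper level set.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .baselines import Backprojection, LassoMM, Tikhonov, sweep_lambda
from .binary import BinaryLevels, BinaryTomography
from .evaluation import as_mask, dice, segment_threshold_mean
from .forward import (
    NoiseSpec,
    SystemMatrix,
    TransducerModel,
    add_awgn,
    build_system_matrix,
)
from .geometry import AcquisitionSettings, ImageGrid, make_detector_ring, make_grid
from .phantoms import PhantomSpec, generate_phantom

__all__ = ["BenchmarkConfig", "benchmark_table", "reconstruct_and_score", "write_table_csv"]

log = logging.getLogger("binpat.benchmark")

#: default relative lambda grid for the Tikhonov sweep (times ||A||^2)
TIKHONOV_LAMBDA_REL = (2e-4, 5e-4, 1e-3, 2e-3, 5e-3)
#: default L1 threshold fractions of the absorber amplitude
L1_THRESHOLD_FRACTIONS = (0.003, 0.01, 0.03, 0.1)


@dataclass
class BenchmarkConfig:
    """Study-design parameters; defaults follow the in-silico protocol
    (22 mm ring, 512 samples at 50 ns, 1500 m/s, 2.25 MHz / 70% transducer,
    20.1 mm field of view) at desk scale (201 forward / 101 inversion pixels)."""

    fine_grid: ImageGrid = field(default_factory=lambda: make_grid(201, 201, 0.1))
    recon_grid: ImageGrid = field(default_factory=lambda: make_grid(101, 101, 20.1 / 101))
    ring_radius: float = 22.0
    acquisition: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    transducer: TransducerModel | None = field(default_factory=TransducerModel)
    tikhonov_lambda_rel: Sequence[float] = TIKHONOV_LAMBDA_REL
    l1_threshold_fractions: Sequence[float] = L1_THRESHOLD_FRACTIONS
    solver_max_iters: int = 300
    solver_tol: float = 1e-6
    binary_kwargs: dict[str, Any] = field(default_factory=dict)
    binary_levels: BinaryLevels | None = None  # None -> estimate from data


def _l1_lambda_grid(c: float, amplitude: float, fractions: Sequence[float]) -> list[float]:
    # ISTA threshold is lam/(2c); express the grid as fractions of the amplitude
    return [2.0 * c * f * amplitude for f in fractions]


def reconstruct_and_score(
    A: SystemMatrix,
    sino,
    truth_mask,
    methods: Sequence[str],
    config: BenchmarkConfig,
    amplitude: float = 1000.0,
) -> dict[str, float]:
    """Reconstruct one sinogram with each method and Dice-score the results."""
    truth_mask = as_mask(truth_mask)
    shape = truth_mask.values.shape
    norm2 = A.norm_squared()
    scores: dict[str, float] = {}
    for method in methods:
        try:
            if method == "bp":
                res = Backprojection(A, sino).fit()
                seg = segment_threshold_mean(res.x.reshape(shape))
            elif method == "tikhonov":
                grid_l = [r * norm2 for r in config.tikhonov_lambda_rel]
                best, _ = sweep_lambda(
                    A, sino, "tikhonov", grid_l, truth_mask,
                    max_iters=config.solver_max_iters, tol=config.solver_tol,
                )
                res = Tikhonov(A, sino).fit(
                    lam=best.lam, max_iters=config.solver_max_iters, tol=config.solver_tol
                )
                seg = segment_threshold_mean(res.x.reshape(shape))
            elif method == "l1":
                c = 1.05 * norm2
                grid_l = _l1_lambda_grid(c, amplitude, config.l1_threshold_fractions)
                best, _ = sweep_lambda(
                    A, sino, "l1", grid_l, truth_mask,
                    max_iters=config.solver_max_iters, tol=config.solver_tol,
                )
                res = LassoMM(A, sino).fit(
                    lam=best.lam, max_iters=config.solver_max_iters, tol=config.solver_tol
                )
                seg = segment_threshold_mean(res.x.reshape(shape))
            elif method == "binary":
                res = BinaryTomography(A, sino).fit(
                    levels=config.binary_levels, **config.binary_kwargs
                )
                seg = as_mask(res.x.reshape(shape), provenance="binary_solver")
            else:
                raise ValueError(f"unknown method {method!r}")
            scores[method] = dice(truth_mask, seg)
        except Exception:  # noqa: BLE001 - record the failure, keep the run going
            log.exception("method %s failed; recording NaN", method)
            scores[method] = float("nan")
    return scores


def benchmark_table(
    phantoms: dict[str, PhantomSpec],
    detector_counts: Sequence[int],
    snr_list: Sequence[float],
    methods: Sequence[str] = ("bp", "tikhonov", "l1", "binary"),
    seeds: Sequence[int] = (0,),
    config: BenchmarkConfig | None = None,
) -> list[dict[str, Any]]:
    """Full factorial run; one row per (phantom, detector count, SNR).

    Per-cell Dice scores are means over ``seeds`` (independent noise
    realizations). The simulation reuses one clean fine-grid sinogram per
    (phantom, detector count) and one coarse operator per detector count.
    """
    cfg = config or BenchmarkConfig()
    rows: list[dict[str, Any]] = []
    for n_det in detector_counts:
        ring = make_detector_ring(n_det, cfg.ring_radius)
        A_coarse = build_system_matrix(cfg.recon_grid, ring, cfg.acquisition, cfg.transducer)
        A_fine = build_system_matrix(cfg.fine_grid, ring, cfg.acquisition, cfg.transducer)
        for name, spec in phantoms.items():
            truth = as_mask(generate_phantom(cfg.recon_grid, spec), provenance="ground_truth")
            clean = A_fine.forward(generate_phantom(cfg.fine_grid, spec))
            for snr in snr_list:
                per_seed: dict[str, list[float]] = {m: [] for m in methods}
                for seed in seeds:
                    sino = add_awgn(clean, NoiseSpec(snr_db=snr, rng_seed=int(seed)))
                    cell = reconstruct_and_score(
                        A_coarse, sino, truth, methods, cfg, amplitude=spec.amplitude
                    )
                    for m in methods:
                        per_seed[m].append(cell[m])
                    log.info(
                        "phantom=%s det=%d snr=%g seed=%d %s",
                        name, n_det, snr, seed,
                        " ".join(f"{m}={cell[m]:.4f}" for m in methods),
                    )
                row: dict[str, Any] = {
                    "phantom": name,
                    "n_detectors": int(n_det),
                    "snr_db": float(snr),
                }
                for m in methods:
                    row[m] = float(np.nanmean(per_seed[m])) if per_seed[m] else float("nan")
                rows.append(row)
    return rows


def write_table_csv(rows: list[dict[str, Any]], path) -> None:
    """Write the benchmark table (rows = phantom x SNR, columns = methods)."""
    if not rows:
        raise ValueError("no benchmark rows to write")
    fieldnames = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
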