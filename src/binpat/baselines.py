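"""Comparator reconstructions: backprojection, Tikhonov (L2) and L1 sparse
recovery via majorization-minimization.

* backprojection: ``x = A^T b`` (a single adjoint pass);
* Tikhonov: minimise ``||Ax-b||^2 + lam ||x||^2``, solved matrix-free by
  damped conjugate-gradient least squares (identical minimiser to the
  normal-equations closed form);
* L1: minimise ``||Ax-b||^2 + lam ||x||_1`` by iterative soft-thresholded
  gradient steps (the majorization-minimization surrogate), with the step
  constant taken above the largest eigenvalue of A^T A.

Negative values are retained in all outputs; clipping happens only during
evaluation/segmentation.
"""

from __future__ import annotations

import warnings
from typing import Any, Sequence

import numpy as np

from ._linalg import cgls
from .base import ReconModel, ReconParams, ReconResult, StepSizeError

__all__ = [
    "Backprojection",
    "Tikhonov",
    "LassoMM",
    "backproject",
    "tikhonov_solve",
    "l1_mm_solve",
    "sweep_lambda",
    "soft_threshold",
]


def soft_threshold(t: np.ndarray, thresh: float) -> np.ndarray:
    """Elementwise soft-thresholding, the proximal operator of the L1 norm."""
    return np.sign(t) * np.maximum(np.abs(t) - thresh, 0.0)


class Backprojection(ReconModel):
    """Adjoint reconstruction ``x = A^T b``: one pass, no iterations."""

    method = "bp"

    def fit(self) -> ReconResult:
        prob = self.problem
        x = prob.rmatvec(prob.b)
        res = float(np.linalg.norm(prob.matvec(x) - prob.b))
        return ReconResult(
            x=x,
            method=self.method,
            params=ReconParams(method=self.method, lam=0.0, max_iters=1),
            grid=prob.grid,
            objective_trace=None,
            residual_norm=res,
            n_iter=1,
            converged=True,
        )


class Tikhonov(ReconModel):
    """Damped least squares: the minimiser of ``||Ax-b||^2 + lam ||x||^2``."""

    method = "tikhonov"

    def fit(self, lam: float, max_iters: int = 200, tol: float = 1e-6) -> ReconResult:
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        prob = self.problem
        x, info = cgls(
            prob.matvec,
            prob.rmatvec,
            prob.b,
            prob.n,
            damp=lam,
            max_iters=max_iters,
            tol=tol,
        )
        if lam == 0.0 and not info.converged:
            warnings.warn(
                "undamped least squares did not converge (possibly rank-deficient "
                f"operator); final gradient norm {info.grad_norm:.3g}",
                RuntimeWarning,
                stacklevel=2,
            )
        res = float(np.linalg.norm(prob.matvec(x) - prob.b))
        return ReconResult(
            x=x,
            method=self.method,
            params=ReconParams(method=self.method, lam=lam, max_iters=max_iters, tol=tol),
            grid=prob.grid,
            objective_trace=info.objective_trace,
            residual_norm=res,
            n_iter=info.iterations,
            converged=info.converged,
        )


class LassoMM(ReconModel):
    """L1-regularized recovery by majorization-minimization (ISTA iterations).

    Iterates ``x <- soft(x + (1/c) A^T (b - A x), lam/(2c))`` with
    ``c >= lambda_max(A^T A)`` (power-iteration estimate times a 1.05 safety
    factor), which keeps the surrogate a true majorizer so the objective is
    non-increasing.
    """

    method = "l1"

    def fit(
        self,
        lam: float,
        max_iters: int = 200,
        tol: float = 1e-6,
        step_constant: float | None = None,
        x0: np.ndarray | None = None,
    ) -> ReconResult:
        if not lam > 0:
            raise ValueError("lambda must be > 0 for the L1 solver")
        prob = self.problem
        c = float(step_constant) if step_constant is not None else 1.05 * prob.operator_norm_squared()
        if not c > 0:
            raise ValueError("step constant must be positive")
        x = np.zeros(prob.n) if x0 is None else np.array(x0, dtype=float).ravel()

        def objective(xv: np.ndarray, r: np.ndarray) -> float:
            return float(r @ r) + lam * float(np.abs(xv).sum())

        r = prob.b - prob.matvec(x)
        trace = [objective(x, r)]
        converged = False
        increases = 0
        k = 0
        for k in range(1, max_iters + 1):
            x_new = soft_threshold(x + prob.rmatvec(r) / c, lam / (2 * c))
            r = prob.b - prob.matvec(x_new)
            obj = objective(x_new, r)
            if obj > trace[-1] * (1 + 1e-12) + 1e-300:
                increases += 1
                if increases >= 3:
                    raise StepSizeError(
                        "L1 objective increased repeatedly: the step constant "
                        f"c={c:.3g} is below ||A||^2; increase it (or leave "
                        "step_constant unset for the power-iteration bound)"
                    )
            else:
                increases = 0
            trace.append(obj)
            dx = np.linalg.norm(x_new - x)
            nx = np.linalg.norm(x_new)
            x = x_new
            if dx <= tol * max(nx, 1e-300):
                converged = True
                break
        return ReconResult(
            x=x,
            method=self.method,
            params=ReconParams(
                method=self.method,
                lam=lam,
                max_iters=max_iters,
                tol=tol,
                extra={"step_constant": c},
            ),
            grid=prob.grid,
            objective_trace=np.array(trace),
            residual_norm=float(np.linalg.norm(r)),
            n_iter=k,
            converged=converged,
        )


# ---------------------------------------------------------------------------
# functional wrappers


def backproject(A: Any, b: Any) -> ReconResult:
    """Backprojection reconstruction ``x = A^T b``."""
    return Backprojection(A, b).fit()


def tikhonov_solve(A: Any, b: Any, params: ReconParams) -> ReconResult:
    """Tikhonov reconstruction at ``params.lam`` (see :class:`Tikhonov`)."""
    return Tikhonov(A, b).fit(lam=params.lam, max_iters=params.max_iters, tol=params.tol)


def l1_mm_solve(A: Any, b: Any, params: ReconParams) -> ReconResult:
    """L1 majorization-minimization reconstruction (see :class:`LassoMM`)."""
    return LassoMM(A, b).fit(
        lam=params.lam,
        max_iters=params.max_iters,
        tol=params.tol,
        step_constant=params.extra.get("step_constant"),
    )


def sweep_lambda(
    A: Any,
    b: Any,
    method: str,
    lambda_grid: Sequence[float],
    truth,
    max_iters: int = 200,
    tol: float = 1e-6,
) -> tuple[ReconParams, list[dict]]:
    """Score a method across a lambda grid by Dice against a known truth.

    For each lambda the method is run, its output segmented by the standard
    clip-at-zero + mean-threshold protocol, and Dice computed against
    ``truth`` (a ground-truth mask or two-level image). Returns the best
    :class:`ReconParams` (arg-max Dice) and the full per-lambda table. Only
    meaningful in simulation mode, where the truth is available.
    """
    from .evaluation import as_mask, dice, segment_threshold_mean

    lambda_grid = list(lambda_grid)
    if not lambda_grid:
        raise ValueError("lambda grid is empty")
    if method not in ("tikhonov", "l1"):
        raise ValueError(f"sweep_lambda supports 'tikhonov' and 'l1', got {method!r}")
    truth_mask = as_mask(truth)
    model_cls = Tikhonov if method == "tikhonov" else LassoMM
    model = model_cls(A, b)
    table: list[dict] = []
    for lam in lambda_grid:
        result = model.fit(lam=float(lam), max_iters=max_iters, tol=tol)
        seg = segment_threshold_mean(result.x.reshape(truth_mask.values.shape))
        score = dice(truth_mask, seg)
        table.append(
            {
                "lambda": float(lam),
                "dice": float(score),
                "residual_norm": result.residual_norm,
                "n_iter": result.n_iter,
            }
        )
    best = max(table, key=lambda row: row["dice"])
    best_params = ReconParams(method=method, lam=best["lambda"], max_iters=max_iters, tol=tol)
    return best_params, table
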