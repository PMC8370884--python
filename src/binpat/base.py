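"""Shared model/results machinery for the reconstruction solvers.

Every reconstruction is exposed in two equivalent ways:

* a model object (``Backprojection``, ``Tikhonov``, ``LassoMM``,
  ``BinaryTomography``) built from an operator and a sinogram, whose
  ``fit()`` returns a :class:`ReconResult`;
* a functional wrapper (``backproject``, ``tikhonov_solve``, ...).

Operators may be :class:`~binpat.forward.SystemMatrix` instances or any
dense/sparse matrix (used heavily by the small-scale oracle tests); data may
be a :class:`~binpat.forward.Sinogram` or a plain vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import scipy.sparse as sp

from .forward import Sinogram, SystemMatrix
from .geometry import ImageGrid, PressureImage

__all__ = ["LinearProblem", "ReconParams", "ReconResult", "ReconModel", "StepSizeError"]


class StepSizeError(RuntimeError):
    """The iterative solver's step size made the objective diverge."""


@dataclass
class LinearProblem:
    """Uniform access to (A, b) regardless of the concrete types passed in."""

    matvec: Callable[[np.ndarray], np.ndarray]
    rmatvec: Callable[[np.ndarray], np.ndarray]
    shape: tuple[int, int]
    b: np.ndarray
    grid: ImageGrid | None = None
    norm_squared: Callable[[], float] | None = None

    @classmethod
    def from_inputs(cls, A: Any, b: Any) -> "LinearProblem":
        if isinstance(b, Sinogram):
            b_vec = b.ravel()
        else:
            b_vec = np.asarray(b, dtype=float).ravel()
        if isinstance(A, SystemMatrix):
            prob = cls(A.matvec, A.rmatvec, A.shape, b_vec, A.grid, A.norm_squared)
        elif sp.issparse(A):
            prob = cls(
                lambda x, _A=A: _A @ x,
                lambda y, _A=A: _A.T @ y,
                A.shape,
                b_vec,
            )
        else:
            A_arr = np.asarray(A, dtype=float)
            if A_arr.ndim != 2:
                raise ValueError("operator must be 2-D")
            prob = cls(
                lambda x, _A=A_arr: _A @ x,
                lambda y, _A=A_arr: _A.T @ y,
                A_arr.shape,
                b_vec,
            )
        if prob.b.size != prob.shape[0]:
            raise ValueError(
                f"data length {prob.b.size} does not match operator rows {prob.shape[0]}"
            )
        return prob

    @property
    def n(self) -> int:
        return self.shape[1]

    def operator_norm_squared(self) -> float:
        from ._linalg import power_iteration

        if self.norm_squared is not None:
            return self.norm_squared()
        return power_iteration(self.matvec, self.rmatvec, self.n, iters=20, seed=0)


@dataclass
class ReconParams:
    """Solver settings shared by the iterative reconstructions."""

    method: str = "tikhonov"
    lam: float = 0.0
    max_iters: int = 200
    tol: float = 1e-6
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("regularization weight must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")


@dataclass
class ReconResult:
    """A fitted reconstruction: the image plus solver diagnostics."""

    x: np.ndarray  # flattened solution vector
    method: str
    params: ReconParams
    grid: ImageGrid | None = None
    objective_trace: np.ndarray | None = None
    residual_norm: float = np.nan
    n_iter: int = 0
    converged: bool = True
    role: str = "reconstruction"

    @property
    def image(self) -> PressureImage | np.ndarray:
        """The solution as a :class:`PressureImage` when a grid is known."""
        if self.grid is None:
            return self.x
        return PressureImage(
            grid=self.grid, values=self.x.reshape(self.grid.shape), role=self.role
        )

    def summary(self) -> str:
        lines = [
            f"{'Reconstruction summary':^58}",
            "=" * 58,
            f"{'method:':<22}{self.method}",
            f"{'unknowns:':<22}{self.x.size}",
            f"{'lambda:':<22}{self.params.lam:g}",
            f"{'iterations:':<22}{self.n_iter}",
            f"{'converged:':<22}{self.converged}",
            f"{'residual ||Ax-b||:':<22}{self.residual_norm:.6g}",
            f"{'min / max value:':<22}{self.x.min():.6g} / {self.x.max():.6g}",
        ]
        if self.objective_trace is not None and len(self.objective_trace):
            lines.append(f"{'final objective:':<22}{self.objective_trace[-1]:.6g}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot(self, ax=None, **imshow_kwargs):
        """Show the reconstructed image with physical (mm) axes."""
        import matplotlib.pyplot as plt

        if self.grid is None:
            raise ValueError("result carries no grid; plot the raw vector yourself")
        if ax is None:
            _, ax = plt.subplots()
        w, h = self.grid.extent
        im = ax.imshow(
            self.x.reshape(self.grid.shape),
            origin="lower",
            extent=(-w / 2, w / 2, -h / 2, h / 2),
            **imshow_kwargs,
        )
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        ax.set_title(self.method)
        plt.colorbar(im, ax=ax, label="Pa")
        return ax

    def plot_objective(self, ax=None):
        """Plot the per-iteration objective trace."""
        import matplotlib.pyplot as plt

        if self.objective_trace is None or not len(self.objective_trace):
            raise ValueError(f"{self.method} has no objective trace")
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.objective_trace)
        ax.set_xlabel("iteration")
        ax.set_ylabel("objective")
        ax.set_title(f"{self.method} convergence")
        return ax


class ReconModel:
    """Base class: an inverse problem ``A x = b`` awaiting a ``fit()``."""

    method: str = "base"

    def __init__(self, A: Any, b: Any) -> None:
        self.problem = LinearProblem.from_inputs(A, b)

    def fit(self, **kwargs) -> ReconResult:  # pragma: no cover - abstract
        raise NotImplementedError
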