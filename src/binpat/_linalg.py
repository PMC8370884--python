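"""Matrix-free least-squares building blocks shared by the solvers.

The damped CGLS routine minimises

    ||A x - b||^2 + damp * ||x||^2 + 2 c^T x

via conjugate gradients on the normal equations, tracking the objective (which
is monotone non-increasing over CG iterations) and the normal-equation
gradient norm. All solvers in the package are deterministic: the only RNG here
is the seeded start vector of the power iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["cgls", "power_iteration", "CGLSInfo"]


@dataclass
class CGLSInfo:
    iterations: int
    converged: bool
    objective_trace: np.ndarray  # per-iteration ||Ax-b||^2 + damp||x||^2 + 2 c^T x
    grad_norm: float  # final ||A^T(b-Ax) - damp x - c||


def cgls(
    matvec,
    rmatvec,
    b: np.ndarray,
    n: int,
    damp: float = 0.0,
    linear: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    max_iters: int = 200,
    tol: float = 1e-8,
) -> tuple[np.ndarray, CGLSInfo]:
    """Solve (A^T A + damp I) x = A^T b - c by conjugate gradients.

    Parameters
    ----------
    matvec, rmatvec : callables
        Forward and adjoint applications of A.
    b : ndarray
        Data vector.
    n : int
        Number of unknowns.
    damp : float
        Tikhonov damping (>= 0).
    linear : ndarray, optional
        Linear-term vector c (the dual tilt); omitted means c = 0.
    x0 : ndarray, optional
        Warm start.
    tol : float
        Stop when the normal-equation gradient norm falls below
        ``tol * max(initial gradient norm, tiny)``.
    """
    b = np.asarray(b, dtype=float).ravel()
    c = None if linear is None else np.asarray(linear, dtype=float).ravel()
    x = np.zeros(n) if x0 is None else np.array(x0, dtype=float).ravel()

    s = b - matvec(x)  # data residual
    r = rmatvec(s) - damp * x  # negative gradient / 2
    if c is not None:
        r = r - c

    def objective() -> float:
        val = float(s @ s) + damp * float(x @ x)
        if c is not None:
            val += 2.0 * float(c @ x)
        return val

    trace = [objective()]
    gamma = float(r @ r)
    g0 = np.sqrt(gamma)
    if g0 == 0.0:
        return x, CGLSInfo(0, True, np.array(trace), 0.0)
    p = r.copy()
    converged = False
    k = 0
    for k in range(1, max_iters + 1):
        q = matvec(p)
        delta = float(q @ q) + damp * float(p @ p)
        if delta <= 0.0:
            break
        alpha = gamma / delta
        x += alpha * p
        s -= alpha * q
        r = rmatvec(s) - damp * x
        if c is not None:
            r = r - c
        gamma_new = float(r @ r)
        trace.append(objective())
        if np.sqrt(gamma_new) <= tol * g0:
            converged = True
            gamma = gamma_new
            break
        p = r + (gamma_new / gamma) * p
        gamma = gamma_new
    return x, CGLSInfo(k, converged, np.array(trace), float(np.sqrt(gamma)))


def power_iteration(matvec, rmatvec, n: int, iters: int = 20, seed: int = 0) -> float:
    """Estimate the largest eigenvalue of A^T A (i.e. ||A||_2^2).

    Deterministic given ``seed``; 20 iterations are ample for a step-size
    bound (a 1.05 safety factor is applied by callers).
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(iters):
        w = rmatvec(matvec(v))
        nw = np.linalg.norm(w)
        if nw == 0.0:
            return 0.0
        lam = float(v @ w)
        v = w / nw
    return abs(lam)
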