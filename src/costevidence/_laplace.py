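"""Shared multi-start optimisation and Laplace (free-energy) model evidence.

Model evidence is approximated as

    log p(y | m) ~ log p(y, theta_hat | m) + (d/2) log(2 pi)
                   - (1/2) log det H(theta_hat)

where theta_hat is the posterior mode, d its dimension and H the Hessian of
the negative log-joint at the mode.  The approximation trades fit accuracy
(the log-joint) against complexity (the determinant term grows with the
number and precision of well-identified parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = ["OptimResult", "numerical_hessian", "laplace_log_evidence", "minimize_multistart"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class OptimResult:
    x: np.ndarray
    fun: float
    log_evidence: float
    hessian: np.ndarray
    converged: bool
    n_starts: int
    messages: list = field(default_factory=list)


def numerical_hessian(
    fun: Callable[[np.ndarray], float], x: np.ndarray, step: float = 1e-4
) -> np.ndarray:
    """Central-difference Hessian; symmetrised."""
    x = np.asarray(x, dtype=float)
    d = x.size
    h = np.empty((d, d))
    steps = step * np.maximum(1.0, np.abs(x))
    f0 = fun(x)
    # diagonal
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = steps[i]
        h[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / steps[i] ** 2
    # off-diagonal
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = steps[i]
            ej[j] = steps[j]
            hij = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
            h[i, j] = h[j, i] = hij
    return 0.5 * (h + h.T)


def laplace_log_evidence(
    neg_log_joint_at_mode: float, hessian: np.ndarray, eig_floor: float = 1e-8
) -> float:
    """Free-energy approximation of the log marginal likelihood, in nats."""
    d = hessian.shape[0]
    if d == 0:
        return -neg_log_joint_at_mode
    eigvals = np.linalg.eigvalsh(hessian)
    eigvals = np.maximum(eigvals, eig_floor)
    log_det = float(np.sum(np.log(eigvals)))
    return -neg_log_joint_at_mode + 0.5 * d * _LOG2PI - 0.5 * log_det


def minimize_multistart(
    fun: Callable[[np.ndarray], float],
    starts: Sequence[np.ndarray],
    bounds: Optional[Sequence[tuple]] = None,
    maxiter: int = 400,
    hessian_step: float = 1e-4,
) -> OptimResult:
    """L-BFGS-B from several starting points; returns the best mode with evidence.

    Ties in the objective (within 1e-9) are broken by the smaller parameter
    norm, for reproducibility.
    """
    best_x: Optional[np.ndarray] = None
    best_f = np.inf
    converged = False
    messages = []
    for x0 in starts:
        res = optimize.minimize(
            fun,
            np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        messages.append(res.message)
        better = res.fun < best_f - 1e-9 or (
            abs(res.fun - best_f) <= 1e-9
            and best_x is not None
            and np.linalg.norm(res.x) < np.linalg.norm(best_x)
        )
        if better or best_x is None:
            best_x = res.x
            best_f = float(res.fun)
            converged = bool(res.success)
    assert best_x is not None
    hess = numerical_hessian(fun, best_x, step=hessian_step)
    log_ev = laplace_log_evidence(best_f, hess)
    if not np.isfinite(log_ev):
        log_ev = -1e10  # flagged worst-case evidence
        converged = False
    return OptimResult(
        x=best_x,
        fun=best_f,
        log_evidence=log_ev,
        hessian=hess,
        converged=converged,
        n_starts=len(starts),
        messages=messages,
    )
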