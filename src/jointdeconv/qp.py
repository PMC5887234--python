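"""Projected Barzilai-Borwein (PBB) solver for bound-constrained convex QPs.

Minimizes ``J(x) = 1/2 x^t Q x + q^t x`` subject to ``l <= x <= u`` where
``Q`` is a symmetric positive semidefinite operator supplied as a callable
(never assembled).  The iteration is projected steepest descent

    ``x <- P(x - alpha * grad J)``,   ``P(x) = min(u, max(l, x))``

with the step length alternating between the two Barzilai-Borwein formulas
(BB1 on odd iterations, BB2 on even ones) and falling back to the exact
Cauchy step on the first iteration or whenever a BB step is degenerate.
No line search is performed: the objective is allowed to oscillate, which is
the method's characteristic non-monotone convergence.  Termination uses the
summed KKT-condition violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "QuadraticProblem",
    "SolverReport",
    "project",
    "cauchy_step",
    "bb_steps",
    "kkt_violation",
    "solve_pbb",
]

#: BB steps outside this range are treated as degenerate
_STEP_MIN, _STEP_MAX = 1e-12, 1e12


@dataclass
class QuadraticProblem:
    """Bound-constrained convex quadratic ``1/2 x^t Q x + q^t x``.

    ``apply_Q`` is an opaque linear operator so that structured Hessians
    (e.g. ``L^t A_mu L + lambda2 I``) are never materialized.
    """

    apply_Q: Callable[[np.ndarray], np.ndarray]
    q: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        n = self.q.size
        self.lower = np.broadcast_to(
            np.asarray(self.lower, dtype=float), (n,)
        ).copy()
        self.upper = np.broadcast_to(
            np.asarray(self.upper, dtype=float), (n,)
        ).copy()
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")

    def objective(self, x: np.ndarray) -> float:
        return float(0.5 * x @ self.apply_Q(x) + self.q @ x)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.apply_Q(x) + self.q


@dataclass
class SolverReport:
    """Outcome of a PBB solve."""

    solution: np.ndarray
    iterations: int
    kkt_residual: float
    objective_trace: list[float] = field(repr=False)
    converged: bool = False


def project(x: np.ndarray, l: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Componentwise clamp ``P(x) = min(u, max(l, x))``; idempotent."""
    x, l, u = np.broadcast_arrays(x, l, u)
    return np.minimum(u, np.maximum(l, x))


def cauchy_step(
    g: np.ndarray, apply_Q: Callable[[np.ndarray], np.ndarray]
) -> float:
    """Exact minimizer of J along ``-g``: ``||g||^2 / (g^t Q g)``.

    Returns 1.0 (unit step) when the curvature ``g^t Q g`` is not strictly
    positive, which on a PSD problem means the direction is flat.
    """
    gg = float(g @ g)
    curvature = float(g @ apply_Q(g))
    if not np.isfinite(curvature) or curvature <= 0.0:
        return 1.0
    return gg / curvature


def bb_steps(
    dx: np.ndarray, dg: np.ndarray
) -> tuple[float | None, float | None]:
    """Barzilai-Borwein step lengths from successive differences.

    ``alpha_BB1 = ||dx||^2 / (dx^t dg)`` and
    ``alpha_BB2 = (dx^t dg) / ||dg||^2``; a step is returned as ``None``
    when its denominator vanishes or the step is nonpositive, non-finite or
    outside the safeguard range.
    """
    if dx.shape != dg.shape:
        raise ValueError("dx and dg must have the same shape")
    dxdg = float(dx @ dg)
    dxdx = float(dx @ dx)
    dgdg = float(dg @ dg)

    def _guard(num: float, den: float) -> float | None:
        if abs(den) <= 1e-300:
            return None
        step = num / den
        if not np.isfinite(step) or not (_STEP_MIN <= step <= _STEP_MAX):
            return None
        return step

    return _guard(dxdx, dxdg), _guard(dxdg, dgdg)


def kkt_violation(
    x: np.ndarray, g: np.ndarray, l: np.ndarray, u: np.ndarray
) -> float:
    """Summed KKT-condition violation ``sum_i |s[i]|`` for bounds ``[l, u]``.

    Case by case: infinity for infeasible components; at an active lower
    (upper) bound only an outward-pointing gradient counts, via
    ``min(0, g)`` (``max(0, g)``); strictly interior components contribute
    the full gradient; pinned components (``l = x = u``) contribute nothing.
    """
    x, g, l, u = np.broadcast_arrays(x, g, l, u)
    if np.any((x < l) | (x > u)):
        return float("inf")
    s = np.where(
        (x == l) & (l < u),
        np.minimum(0.0, g),
        np.where(
            (x == u) & (l < u),
            np.maximum(0.0, g),
            np.where(l == u, 0.0, g),
        ),
    )
    return float(np.sum(np.abs(s)))


def solve_pbb(
    problem: QuadraticProblem,
    x0: np.ndarray | None = None,
    tol: float | None = None,
    max_iter: int = 5000,
    trace: bool = True,
    check_every: int = 1,
) -> SolverReport:
    """Run the projected BB iteration until the KKT violation drops below
    ``tol`` or ``max_iter`` is reached.

    ``tol`` defaults to ``1e-6 * max(1, ||q||_inf)``.  Non-convergence is
    reported through ``SolverReport.converged``, not raised.  ``trace``
    records the per-iteration objective; ``check_every`` tests the stopping
    criterion only every that many iterations (the final residual is always
    evaluated at the returned iterate).
    """
    q = problem.q
    l, u = problem.lower, problem.upper
    if tol is None:
        tol = 1e-6 * max(1.0, float(np.max(np.abs(q))) if q.size else 1.0)
    if check_every < 1:
        raise ValueError("check_every must be >= 1")
    x = np.zeros_like(q) if x0 is None else np.asarray(x0, dtype=float)
    x = project(x, l, u)
    g = problem.gradient(x)
    # J(x) = 1/2 x^t (Qx + q) + 1/2 q^t x = 1/2 x^t (g + q)
    objective_trace = [float(0.5 * x @ (g + q))] if trace else []
    residual = kkt_violation(x, g, l, u)
    iterations = 0
    dx = dg = None
    for k in range(max_iter):
        if residual is not None and residual <= tol:
            break
        alpha = None
        if k > 0:
            bb1, bb2 = bb_steps(dx, dg)
            alpha = bb1 if k % 2 == 1 else bb2
        if alpha is None:  # first iteration or degenerate BB step
            alpha = cauchy_step(g, problem.apply_Q)
        x_new = project(x - alpha * g, l, u)
        g_new = problem.apply_Q(x_new) + q
        dx = x_new - x
        dg = g_new - g
        x, g = x_new, g_new
        iterations = k + 1
        if trace:
            objective_trace.append(float(0.5 * x @ (g + q)))
        residual = (
            kkt_violation(x, g, l, u)
            if (k + 1) % check_every == 0
            else None
        )
    if residual is None:
        residual = kkt_violation(x, g, l, u)
    return SolverReport(
        solution=x,
        iterations=iterations,
        kkt_residual=residual,
        objective_trace=objective_trace,
        converged=residual <= tol,
    )
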