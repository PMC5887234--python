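"""Discrete operators of the additive spectrum model.

The model writes an observed spectrum as ``y = x_b + L x_p + noise`` where
``x_b`` is a smooth baseline and ``L`` convolves a sparse nonnegative peak
list ``x_p`` with a known peak shape.  Baseline smoothness is enforced by the
quadratic penalty ``mu/2 * ||D x_b||^2`` built on the first-order finite
difference matrix ``D``.  Eliminating the baseline in closed form introduces

* ``B_mu = I + mu * D^t D``          (symmetric positive definite, tridiagonal)
* ``A_mu = I - B_mu^{-1}``           (applied matrix-free: one banded solve)

and, with imposed baseline boundary values, their corrected counterparts
``B~_mu`` and the modified data vector ``y~``.  ``A_mu`` interpolates between
a regularized second derivative (small ``mu``) and mean-centering
(``mu -> infinity``); it is only ever applied as an operator, never formed
densely here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve_banded, cholesky_banded

from .spectrum import PeakShape

__all__ = [
    "BaselineOperator",
    "build_DtD",
    "build_baseline_operator",
    "build_boundary_corrected",
    "solve_B",
    "apply_A",
    "convolve_peaks",
    "correlate_peaks",
]


def build_DtD(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Bands of the n x n second-difference matrix ``D^t D``.

    Returns ``(diag, off)`` with ``diag = (1, 2, ..., 2, 1)`` and all
    off-diagonal entries equal to -1 (``off`` has length n-1).
    """
    if n < 2:
        raise ValueError("D^t D needs dimension n >= 2")
    diag = np.full(n, 2.0)
    diag[0] = diag[-1] = 1.0
    off = np.full(n - 1, -1.0)
    return diag, off


@dataclass
class BaselineOperator:
    """Tridiagonal ``B_mu`` (or boundary-corrected ``B~_mu``) with cached
    banded Cholesky factorization.

    ``constrained`` holds the imposed boundary baseline values
    ``(ybar_1, ybar_n)`` when the boundary correction is active, in which case
    ``y_tilde`` is the modified data vector that goes with it.
    """

    mu: float
    n: int
    diag: np.ndarray
    off: np.ndarray  # superdiagonal, length n-1
    constrained: tuple[float, float] | None = None
    y_tilde: np.ndarray | None = None
    _factor: np.ndarray | None = field(
        default=None, repr=False, compare=False
    )

    def _cholesky(self) -> np.ndarray:
        if self._factor is None:
            ab = np.zeros((2, self.n))
            ab[0, 1:] = self.off
            ab[1, :] = self.diag
            self._factor = cholesky_banded(ab, lower=False)
        return self._factor

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return solve_B(self, rhs)

    def apply_A(self, v: np.ndarray) -> np.ndarray:
        return apply_A(self, v)


def build_baseline_operator(mu: float, n: int) -> BaselineOperator:
    """Unconstrained ``B_mu = I + mu * D^t D``."""
    if not np.isfinite(mu) or mu < 0:
        raise ValueError("mu must be finite and nonnegative")
    dtd_diag, dtd_off = build_DtD(n)
    return BaselineOperator(
        mu=float(mu), n=n, diag=1.0 + mu * dtd_diag, off=mu * dtd_off
    )


def build_boundary_corrected(
    mu: float, y: np.ndarray, ybar1: float, ybarn: float
) -> BaselineOperator:
    """Boundary-corrected operator ``B~_mu`` and modified data vector ``y~``.

    Imposing the baseline values ``ybar1`` and ``ybarn`` at the two ends
    decouples the boundary samples: the first/last rows of ``B~_mu`` become
    ``(1+mu, 0, ...)`` / ``(..., 0, 1+mu)`` and ``y~`` absorbs the imposed
    values into its first/last two entries, leaving the interior untouched.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("boundary correction needs a vector of length >= 3")
    if not (np.isfinite(ybar1) and np.isfinite(ybarn)):
        raise ValueError("boundary values must be finite")
    if not np.isfinite(mu) or mu < 0:
        raise ValueError("mu must be finite and nonnegative")
    n = y.size
    diag = np.full(n, 1.0 + 2.0 * mu)
    diag[0] = diag[-1] = 1.0 + mu
    off = np.full(n - 1, -mu)
    off[0] = off[-1] = 0.0
    y_tilde = y.copy()
    y_tilde[0] = (1.0 + mu) * ybar1
    y_tilde[1] = y[1] + mu * ybar1
    y_tilde[-2] = y[-2] + mu * ybarn
    y_tilde[-1] = (1.0 + mu) * ybarn
    return BaselineOperator(
        mu=float(mu),
        n=n,
        diag=diag,
        off=off,
        constrained=(float(ybar1), float(ybarn)),
        y_tilde=y_tilde,
    )


def solve_B(op: BaselineOperator, rhs: np.ndarray) -> np.ndarray:
    """Solve ``B_mu x = rhs`` by banded Cholesky elimination, O(n)."""
    rhs = np.asarray(rhs, dtype=float)
    if rhs.shape[0] != op.n:
        raise ValueError(f"rhs length {rhs.shape[0]} != operator size {op.n}")
    if not np.all(np.isfinite(rhs)):
        raise ValueError("rhs contains non-finite values")
    if op.mu == 0.0:
        return rhs.copy() if rhs.ndim == 1 else rhs.copy()
    return cho_solve_banded((op._cholesky(), False), rhs)


def apply_A(op: BaselineOperator, v: np.ndarray) -> np.ndarray:
    """Apply ``A_mu = I - B_mu^{-1}`` matrix-free (one banded solve)."""
    v = np.asarray(v, dtype=float)
    return v - solve_B(op, v)


def _check_kernel(kernel: np.ndarray, n: int) -> int:
    if kernel.size > 2 * n + 1:
        raise ValueError(
            f"kernel length {kernel.size} exceeds 2n+1 = {2 * n + 1}"
        )
    return kernel.size // 2


def convolve_peaks(x_p: np.ndarray, shape: PeakShape) -> np.ndarray:
    """Zero-padded discrete convolution ``L x_p``, output length n."""
    x_p = np.asarray(x_p, dtype=float)
    n = x_p.size
    r = _check_kernel(shape.kernel, n)
    return np.convolve(x_p, shape.kernel)[r : r + n]


def correlate_peaks(v: np.ndarray, shape: PeakShape) -> np.ndarray:
    """Adjoint convolution ``L^t v`` (correlation with the kernel)."""
    v = np.asarray(v, dtype=float)
    n = v.size
    r = _check_kernel(shape.kernel, n)
    return np.convolve(v, shape.kernel[::-1])[r : r + n]
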