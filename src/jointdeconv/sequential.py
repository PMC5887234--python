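"""Classical sequential pipeline: smooth, clip the baseline, deconvolve.

This is the conventional chain the joint estimator is compared against:

1. Savitzky-Golay smoothing (moving least-squares polynomial fit);
2. SNIP baseline estimation (iterative symmetric peak clipping with an
   increasing window, giving a lower envelope of the smoothed spectrum);
3. sparse nonnegative deconvolution of the baseline-subtracted spectrum
   ``argmin_{x_p>=0} 1/2 ||y - L x_p||^2 + lambda1 ||x_p||_1
   + lambda2/2 ||x_p||^2``, solved with the same projected BB solver and
   the same two-pass (select, then debias with lambda1 = lambda2 = 0)
   procedure as the joint method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .joint import DeconvolutionResult, extract_support
from .operators import convolve_peaks, correlate_peaks
from .qp import QuadraticProblem, SolverReport, solve_pbb
from .spectrum import PeakShape, Spectrum

__all__ = [
    "SequentialConfig",
    "savitzky_golay",
    "snip_baseline",
    "classic_deconvolve",
    "sequential_deconvolve",
]


@dataclass
class SequentialConfig:
    """Parameters of the sequential pipeline.

    ``m_sg`` is the (odd) Savitzky-Golay window, fixed at 39 samples by
    convention; ``sg_degree`` the fitted polynomial degree (cubic default);
    ``m_snip`` the SNIP clipping half-width in samples.
    """

    m_snip: int
    lambda1: float = 1.0
    lambda2: float = 0.1
    m_sg: int = 39
    sg_degree: int = 3
    tol: float | None = None
    max_iter: int = 5000
    min_peak_height: float | None = None

    def __post_init__(self) -> None:
        if self.m_sg % 2 == 0:
            raise ValueError("Savitzky-Golay window must be odd")
        if self.m_sg <= self.sg_degree:
            raise ValueError("window must exceed polynomial degree")
        if self.m_snip < 1:
            raise ValueError("m_snip must be >= 1")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be nonnegative")


def savitzky_golay(y: np.ndarray, window: int, degree: int) -> np.ndarray:
    """Savitzky-Golay moving least-squares smoother.

    Edges are handled by fitting the polynomial on the truncated window
    (``mode='interp'``).  Polynomials of degree <= ``degree`` pass through
    unchanged.
    """
    y = np.asarray(y, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= degree:
        raise ValueError("window must exceed polynomial degree")
    if window > y.size:
        raise ValueError("window exceeds signal length")
    return savgol_filter(y, window_length=window, polyorder=degree,
                         mode="interp")


def snip_baseline(y_smooth: np.ndarray, m_snip: int) -> np.ndarray:
    """SNIP lower-envelope baseline of a (smoothed) spectrum.

    Increasing-window variant: for m = 1..m_snip each interior sample is
    replaced by ``min(b[i], (b[i-m] + b[i+m]) / 2)``.  The result never
    exceeds the input and is unchanged on linear segments.
    """
    b = np.asarray(y_smooth, dtype=float).copy()
    n = b.size
    if not 1 <= m_snip < n / 2:
        raise ValueError("m_snip must satisfy 1 <= m_snip < n/2")
    for m in range(1, m_snip + 1):
        mid = 0.5 * (b[: n - 2 * m] + b[2 * m :])
        np.minimum(b[m : n - m], mid, out=b[m : n - m])
    return b


def classic_deconvolve(
    y_corrected: np.ndarray,
    shape: PeakShape,
    lambda1: float,
    lambda2: float = 0.1,
    tol: float | None = None,
    max_iter: int = 5000,
    min_peak_height: float | None = None,
    x0: np.ndarray | None = None,
) -> DeconvolutionResult:
    """Two-pass sparse deconvolution of a baseline-subtracted spectrum.

    Selection pass: Hessian ``L^t L + lambda2 I`` and linear term
    ``lambda1 1 - L^t y`` under ``x_p >= 0``; then local-maximum support
    extraction and a penalty-free debiasing pass restricted to the support,
    exactly mirroring the joint estimator's second stage.
    """
    y = np.asarray(y_corrected, dtype=float)
    n = y.size
    lty = correlate_peaks(y, shape)

    def apply_Q(v: np.ndarray) -> np.ndarray:
        out = correlate_peaks(convolve_peaks(v, shape), shape)
        if lambda2 != 0.0:
            out = out + lambda2 * v
        return out

    problem = QuadraticProblem(
        apply_Q=apply_Q,
        q=lambda1 - lty,
        lower=np.zeros(n),
        upper=np.full(n, np.inf),
    )
    report1 = solve_pbb(problem, x0=x0, tol=tol, max_iter=max_iter)
    stage1 = report1.solution
    floor = (
        min_peak_height
        if min_peak_height is not None
        else 1e-8 * max(float(np.max(np.abs(y))), 1e-300)
    )
    support = extract_support(stage1, floor)
    if support.size == 0:
        peaks = np.zeros(n)
        report2 = SolverReport(
            solution=peaks, iterations=0, kkt_residual=0.0,
            objective_trace=[], converged=True,
        )
    else:
        def apply_Q2(v: np.ndarray) -> np.ndarray:
            return correlate_peaks(convolve_peaks(v, shape), shape)

        upper = np.zeros(n)
        upper[support] = np.inf
        problem2 = QuadraticProblem(
            apply_Q=apply_Q2, q=-lty, lower=np.zeros(n), upper=upper
        )
        report2 = solve_pbb(problem2, tol=tol, max_iter=max_iter)
        peaks = report2.solution
    residual = y - convolve_peaks(peaks, shape)
    return DeconvolutionResult(
        peaks=peaks,
        baseline=np.zeros(n),
        support=support,
        stage1_peaks=stage1,
        reports={"stage1": report1, "stage2": report2},
        residual=residual,
    )


def sequential_deconvolve(
    y: Spectrum, shape: PeakShape, config: SequentialConfig
) -> DeconvolutionResult:
    """Full sequential pipeline on a raw spectrum.

    Smooths, estimates and subtracts the SNIP baseline (negative residues
    are kept: the nonnegativity constraint on the peaks absorbs them), then
    runs the classical two-pass deconvolution.  The returned ``baseline``
    is the SNIP estimate.
    """
    smoothed = savitzky_golay(y.intensity, config.m_sg, config.sg_degree)
    baseline = snip_baseline(smoothed, config.m_snip)
    result = classic_deconvolve(
        y.intensity - baseline,
        shape,
        lambda1=config.lambda1,
        lambda2=config.lambda2,
        tol=config.tol,
        max_iter=config.max_iter,
        min_peak_height=config.min_peak_height,
    )
    result.baseline = baseline
    result.residual = y.intensity - baseline - convolve_peaks(
        result.peaks, shape
    )
    return result
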