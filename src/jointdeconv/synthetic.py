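"""Synthetic benchmark spectra with known ground truth.

The generator emulates a low-resolution linear MALDI-ToF spectrum on n=500
channels: a smooth parametric baseline

    ``x_b[i] = C(s) + s * exp(-3 i / n) - 2 i / n``,   i = 1..n,

with shape flag ``s in {-1, 0, +1}`` (curved down, straight line, curved up)
and offset ``C = 5`` for ``s = 1`` and ``C = 2`` otherwise, plus ten
Gaussian peaks of common width ``sigma_p = 10`` channels at fixed centers
and heights, plus i.i.d. zero-mean Gaussian noise.  The merit factor used to
score a recovered peak list blurs both lists with the peak shape before
taking a normalized Euclidean distance, so small center misalignments are
penalized smoothly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .operators import convolve_peaks
from .spectrum import PeakShape, Spectrum

__all__ = [
    "TRUE_PEAK_TABLE",
    "SIGMA_P",
    "SyntheticTruth",
    "make_baseline",
    "make_truth_peaks",
    "make_spectrum",
    "merit_Ee",
]

#: (center channel, height) of the ten benchmark peaks
TRUE_PEAK_TABLE: tuple[tuple[int, float], ...] = (
    (50, 1.0),
    (90, 0.5),
    (170, 0.5),
    (200, 3.0),
    (230, 2.0),
    (260, 1.0),
    (350, 0.5),
    (370, 3.0),
    (390, 2.0),
    (410, 1.0),
)

#: common Gaussian peak width of the benchmark, in channels
SIGMA_P: float = 10.0


@dataclass
class SyntheticTruth:
    """Generation parameters and realized ground truth of one spectrum."""

    n: int = 500
    s: int = -1
    sigma_noise: float = 1.0
    seed: int = 1
    sigma_p: float = SIGMA_P
    peak_table: tuple[tuple[int, float], ...] = TRUE_PEAK_TABLE
    baseline: np.ndarray = field(default=None, repr=False)
    peaks: np.ndarray = field(default=None, repr=False)
    shape: PeakShape = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.s not in (-1, 0, 1):
            raise ValueError("s must be -1, 0 or +1")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be nonnegative")
        centers = [c for c, _ in self.peak_table]
        if sorted(centers) != centers or len(set(centers)) != len(centers):
            raise ValueError("peak centers must be strictly increasing")
        if any(h <= 0 for _, h in self.peak_table):
            raise ValueError("peak heights must be positive")

    @property
    def C(self) -> float:
        return 5.0 if self.s == 1 else 2.0


def make_baseline(s: int, n: int = 500) -> np.ndarray:
    """Parametric baseline evaluated at channels i = 1..n."""
    if s not in (-1, 0, 1):
        raise ValueError("s must be -1, 0 or +1")
    C = 5.0 if s == 1 else 2.0
    i = np.arange(1, n + 1, dtype=float)
    return C + s * np.exp(-3.0 * i / n) - 2.0 * i / n


def make_truth_peaks(
    n: int = 500,
    peak_table: tuple[tuple[int, float], ...] = TRUE_PEAK_TABLE,
) -> np.ndarray:
    """Sparse ground-truth peak list: height at its center channel
    (1-based channel c maps to index c-1)."""
    x = np.zeros(n)
    for center, height in peak_table:
        if not 1 <= center <= n:
            raise ValueError(f"peak center {center} outside 1..{n}")
        x[center - 1] = height
    return x


def make_spectrum(truth: SyntheticTruth) -> tuple[Spectrum, SyntheticTruth]:
    """Realize one synthetic spectrum: baseline + blurred peaks + noise.

    Deterministic for a fixed seed; the returned truth carries the realized
    baseline, sparse peak list and the Gaussian peak shape used.
    """
    baseline = make_baseline(truth.s, truth.n)
    peaks = make_truth_peaks(truth.n, truth.peak_table)
    shape = PeakShape.gaussian(truth.sigma_p)
    clean = baseline + convolve_peaks(peaks, shape)
    rng = np.random.default_rng(truth.seed)
    noise = truth.sigma_noise * rng.standard_normal(truth.n)
    truth.baseline = baseline
    truth.peaks = peaks
    truth.shape = shape
    return Spectrum.from_intensity(clean + noise), truth


def merit_Ee(
    x_hat: np.ndarray, x_true: np.ndarray, shape: PeakShape
) -> float:
    """Normalized blurred peak-list distance
    ``||L (x_hat - x_true)|| / ||L x_true||``.

    Zero for a perfect recovery, one for an empty one.
    """
    x_hat = np.asarray(x_hat, dtype=float)
    x_true = np.asarray(x_true, dtype=float)
    denom = float(np.linalg.norm(convolve_peaks(x_true, shape)))
    if denom == 0.0:
        raise ValueError("ground-truth peak list is identically zero")
    num = float(np.linalg.norm(convolve_peaks(x_hat - x_true, shape)))
    return num / denom
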