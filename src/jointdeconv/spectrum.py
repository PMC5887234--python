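"""Core data containers: uniformly sampled spectra and discrete peak shapes.

A spectrum is a pair of equal-length vectors ``(axis, intensity)`` where the
axis (m/z values or plain channel indices) is strictly increasing and
uniformly spaced.  The deconvolution model itself is channel based: all
operators act on the intensity vector, and axis values only matter when
reporting peak positions or converting a peak width given in axis units into
channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spectrum", "PeakShape"]

#: relative tolerance on axis-step uniformity
_AXIS_RTOL = 1e-6


@dataclass(frozen=True)
class Spectrum:
    """A 1-D spectrum on a uniformly sampled axis.

    Parameters
    ----------
    axis:
        Strictly increasing, uniformly spaced sample positions (m/z or
        channel units).
    intensity:
        Measured intensities ``y``, same length as ``axis``.
    """

    axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", y)
        if axis.ndim != 1 or y.ndim != 1:
            raise ValueError("axis and intensity must be 1-D vectors")
        if axis.size != y.size:
            raise ValueError(
                f"axis ({axis.size}) and intensity ({y.size}) lengths differ"
            )
        if axis.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not (np.all(np.isfinite(axis)) and np.all(np.isfinite(y))):
            raise ValueError("spectrum contains non-finite values")
        steps = np.diff(axis)
        if np.any(steps <= 0):
            raise ValueError("axis must be strictly increasing")
        step = steps.mean()
        if np.max(np.abs(steps - step)) > _AXIS_RTOL * abs(step):
            raise ValueError(
                "axis is not uniformly sampled (relative tolerance 1e-6)"
            )

    @classmethod
    def from_intensity(cls, intensity: np.ndarray) -> "Spectrum":
        """Build a spectrum on the canonical channel axis 1..n."""
        y = np.asarray(intensity, dtype=float)
        return cls(np.arange(1, y.size + 1, dtype=float), y)

    @property
    def n(self) -> int:
        return self.intensity.size

    @property
    def step(self) -> float:
        """Uniform axis spacing."""
        return float((self.axis[-1] - self.axis[0]) / (self.n - 1))


@dataclass(frozen=True)
class PeakShape:
    """Discrete, unit-amplitude convolution kernel of the peak shape ``p``.

    The kernel has odd length ``2r + 1`` with its maximum at the central
    element; convolving a sparse peak list with it produces the smooth peak
    contribution of the spectrum model.
    """

    kernel: np.ndarray
    sigma: float | None = None  #: Gaussian width in channels, if applicable
    axis_sigma: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        object.__setattr__(self, "kernel", k)
        if k.ndim != 1 or k.size % 2 != 1:
            raise ValueError("kernel must be a 1-D vector of odd length")
        if not np.all(np.isfinite(k)):
            raise ValueError("kernel contains non-finite values")
        if np.any(k < 0):
            raise ValueError("kernel must be nonnegative")
        if int(np.argmax(k)) != k.size // 2:
            raise ValueError("kernel maximum must sit at the central element")

    @property
    def radius(self) -> int:
        """Truncation radius r (kernel length is 2r+1)."""
        return self.kernel.size // 2

    @classmethod
    def gaussian(cls, sigma: float, step: float = 1.0) -> "PeakShape":
        """Unit-amplitude Gaussian kernel ``exp(-((i-c)/sigma_c)^2 / 2)``.

        Parameters
        ----------
        sigma:
            Peak width in axis units.
        step:
            Axis spacing; ``sigma / step`` gives the width in channels.
            The kernel is truncated at ``r = ceil(4 * sigma_c)`` channels.
        """
        if not np.isfinite(sigma) or sigma <= 0:
            raise ValueError("sigma must be positive and finite")
        if not np.isfinite(step) or step <= 0:
            raise ValueError("axis step must be positive and finite")
        sigma_c = sigma / step
        r = int(np.ceil(4.0 * sigma_c))
        i = np.arange(-r, r + 1, dtype=float)
        kernel = np.exp(-0.5 * (i / sigma_c) ** 2)
        return cls(kernel=kernel, sigma=sigma_c, axis_sigma=sigma)
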