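"""Generate a synthetic linear MALDI-ToF benchmark spectrum.

The spectrum is a curved baseline plus ten Gaussian peaks of width 10
channels at tabulated centers/heights, plus i.i.d. Gaussian noise.  The
script prints the generation parameters and writes the spectrum (and its
ground truth) as CSV next to this file.
"""

from pathlib import Path

import numpy as np

from jointdeconv import (
    Spectrum,
    SyntheticTruth,
    make_spectrum,
)
from jointdeconv.io import write_spectrum_csv

out = Path(__file__).parent

truth = SyntheticTruth(n=500, s=-1, sigma_noise=1.0, seed=1)
spectrum, truth = make_spectrum(truth)

write_spectrum_csv(spectrum, out / "synthetic_spectrum.csv")
write_spectrum_csv(
    Spectrum(spectrum.axis, truth.baseline), out / "synthetic_baseline.csv"
)

print(f"n = {truth.n} channels, baseline shape s = {truth.s}, "
      f"noise sd = {truth.sigma_noise}, seed = {truth.seed}")
print(f"true peaks (channel, height): {truth.peak_table}")
print(f"intensity range: [{spectrum.intensity.min():.2f}, "
      f"{spectrum.intensity.max():.2f}]")
print(f"noise accounts for sd = {np.std(spectrum.intensity - truth.baseline - np.convolve(truth.peaks, truth.shape.kernel)[truth.shape.radius:truth.shape.radius+500]):.3f} "
      "of the signal (should be close to the requested sd)")
print("wrote synthetic_spectrum.csv and synthetic_baseline.csv")
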