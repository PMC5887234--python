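"""CSV readers and writers for spectra and peak lists.

Spectrum files are two numeric columns (axis, intensity), comma separated,
with an optional single header line that is auto-detected.  Peak lists are
written with one row per supported peak: position in axis units, channel
index (0-based) and debiased height.  All numbers are serialized with 12
significant digits so that a write/read round trip is lossless well below
solver tolerances.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .joint import DeconvolutionResult
from .spectrum import Spectrum

__all__ = [
    "SpectrumParseError",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "write_peaks_csv",
]


class SpectrumParseError(ValueError):
    """Raised when a spectrum CSV cannot be parsed; carries the line number
    when one specific line is at fault."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Parse a two-column spectrum CSV into a :class:`Spectrum`."""
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with path.open() as fh:
        lines = fh.readlines()
    start = 0
    if lines:
        first = lines[0].strip().split(",")
        try:
            [float(tok) for tok in first]
        except ValueError:
            start = 1  # header line
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        stripped = raw.strip()
        if not stripped:
            continue
        tokens = stripped.split(",")
        if len(tokens) != 2:
            raise SpectrumParseError(
                f"expected 2 comma-separated columns, got {len(tokens)}",
                line=lineno,
            )
        try:
            rows.append((float(tokens[0]), float(tokens[1])))
        except ValueError:
            raise SpectrumParseError(
                f"non-numeric cell in {tokens!r}", line=lineno
            ) from None
    if len(rows) < 2:
        raise SpectrumParseError("need at least 2 data rows")
    data = np.asarray(rows, dtype=float)
    try:
        return Spectrum(axis=data[:, 0], intensity=data[:, 1])
    except ValueError as exc:
        raise SpectrumParseError(str(exc)) from exc


def _fmt(x: float) -> str:
    # shortest exact decimal representation: write/read round trips are
    # bit-identical
    return repr(float(x))


def write_spectrum_csv(
    spectrum: Spectrum, path: str | Path,
    header: tuple[str, str] = ("mz", "intensity"),
) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"{header[0]},{header[1]}\n")
        for a, v in zip(spectrum.axis, spectrum.intensity):
            fh.write(f"{_fmt(a)},{_fmt(v)}\n")


def write_peaks_csv(
    result: DeconvolutionResult, axis: np.ndarray, path: str | Path
) -> None:
    """Write the supported peaks (position, channel, height), sorted by
    position; zero-height support members are dropped."""
    axis = np.asarray(axis, dtype=float)
    idx = [i for i in result.support if result.peaks[i] > 0]
    frame = pd.DataFrame(
        {
            "position": [axis[i] for i in idx],
            "channel": idx,
            "height": [result.peaks[i] for i in idx],
        }
    ).sort_values("position")
    with Path(path).open("w") as fh:
        fh.write("position,channel,height\n")
        for _, row in frame.iterrows():
            fh.write(
                f"{_fmt(row['position'])},{int(row['channel'])},"
                f"{_fmt(row['height'])}\n"
            )
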