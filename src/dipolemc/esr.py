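"""ESR nitroxide spin-probe spectral parameters.

A rapidly tumbling nitroxide radical (TEMPO, 16-DOXYL) shows a three-line
first-derivative ESR spectrum.  Two scalar reporters are computed from it:

* rotational correlation time (seconds), for an isotropic environment::

      tau = 5.95 * dH0 * ( sqrt(I0/I+1) + sqrt(I0/I-1) - 2 ) * 1e-10

  where ``I0``, ``I+1``, ``I-1`` are the peak-to-peak amplitudes of the
  central, low-field and high-field lines and ``dH0`` is the central
  peak-to-peak linewidth in gauss.  Larger tau means a more rigid (ordered)
  probe environment.

* partition parameter ``F = P / H`` for the TEMPO probe, the ratio of the
  high-field line amplitude of the aqueous component (``P``) to the low-field
  line amplitude of the lipid component (``H``), reporting the probe's
  distribution between water and membrane.  Note this is amplitude(water) /
  amplitude(lipid); no inverted convention is applied.

Line parameters can be supplied directly or extracted from a two-column
(field, amplitude) derivative spectrum; a synthetic derivative-Lorentzian
spectrum generator provides test fixtures in place of instrument output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SpectrumLines",
    "PartitionAmplitudes",
    "Spectrum",
    "LineExtractionError",
    "rotational_correlation_time",
    "partition_parameter_F",
    "extract_line_params",
    "synth_nitroxide_spectrum",
    "load_spectrum",
    "save_spectrum",
]

# Peak of u/(1+u^2)^2 (derivative-Lorentzian shape) at u = 1/sqrt(3).
_DERIV_LORENTZ_PEAK = 3.0 * math.sqrt(3.0) / 16.0


class LineExtractionError(ValueError):
    """A window contains no usable extremum pair."""


@dataclass(frozen=True)
class SpectrumLines:
    """Peak-to-peak amplitudes of the three nitroxide lines + central width."""

    I0: float
    Iplus1: float
    Iminus1: float
    deltaH0: float  # gauss

    def __post_init__(self) -> None:
        if min(self.I0, self.Iplus1, self.Iminus1) <= 0:
            raise ValueError("line amplitudes must be > 0")
        if self.deltaH0 <= 0:
            raise ValueError("central linewidth must be > 0")


@dataclass(frozen=True)
class PartitionAmplitudes:
    """TEMPO partition amplitudes: P aqueous (high-field), H lipid (low-field)."""

    P: float
    H: float

    def __post_init__(self) -> None:
        if self.P <= 0 or self.H <= 0:
            raise ValueError("amplitudes must be > 0")


@dataclass
class Spectrum:
    """First-derivative ESR spectrum on a strictly increasing field axis."""

    field: np.ndarray  # gauss
    amplitude: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.field.ndim != 1 or self.field.shape != self.amplitude.shape:
            raise ValueError("field and amplitude must be 1D arrays of equal length")
        if len(self.field) < 16:
            raise ValueError("spectrum must have at least 16 points")
        if not np.all(np.diff(self.field) > 0):
            raise ValueError("field axis must be strictly increasing")


def rotational_correlation_time(lines: SpectrumLines) -> float:
    """Rotational correlation time tau in seconds.

    Invariant under common rescaling of the three amplitudes and strictly
    increasing in the central linewidth.  For physically valid isotropic
    spectra (I0 >= I+1, I0 >= I-1) the result is non-negative.
    """
    ratio_sum = (
        math.sqrt(lines.I0 / lines.Iplus1)
        + math.sqrt(lines.I0 / lines.Iminus1)
        - 2.0
    )
    return 5.95 * lines.deltaH0 * ratio_sum * 1e-10


def partition_parameter_F(amps: PartitionAmplitudes) -> float:
    """Partition parameter F = P / H (aqueous over lipid amplitude)."""
    return amps.P / amps.H


def _window_extract(
    spectrum: Spectrum, lo: float, hi: float, smooth: int | None
) -> tuple[float, float]:
    """(peak-to-peak amplitude, max-min field separation) within [lo, hi]."""
    if hi <= lo:
        raise ValueError(f"empty field window ({lo}, {hi})")
    mask = (spectrum.field >= lo) & (spectrum.field <= hi)
    if mask.sum() < 3:
        raise LineExtractionError(
            f"window ({lo}, {hi}) G contains {int(mask.sum())} points; "
            "no extremum pair"
        )
    amp = spectrum.amplitude[mask]
    fld = spectrum.field[mask]
    if smooth is not None and smooth >= 3:
        from scipy.signal import savgol_filter

        win = min(smooth | 1, len(amp) - (1 - len(amp) % 2))
        if win >= 3:
            amp = savgol_filter(amp, win, polyorder=2)
    i_max = int(np.argmax(amp))
    i_min = int(np.argmin(amp))
    pp = float(amp[i_max] - amp[i_min])
    if pp <= 0 or i_max == i_min:
        raise LineExtractionError(
            f"window ({lo}, {hi}) G: no distinct max/min pair"
        )
    return pp, abs(float(fld[i_min] - fld[i_max]))


def extract_line_params(
    spectrum: Spectrum,
    line_windows: list[tuple[float, float]],
    smooth: int | None = None,
) -> SpectrumLines | PartitionAmplitudes:
    """Extract line parameters from non-overlapping field windows.

    Three windows (in increasing field order: low-field, central, high-field)
    yield :class:`SpectrumLines` — I+1 from the low-field window, I0 and the
    peak-to-peak linewidth from the central one, I-1 from the high-field one.
    Two windows yield :class:`PartitionAmplitudes` for the TEMPO partition
    measurement: H from the lipid low-field window, P from the aqueous
    high-field window.  ``smooth`` (odd integer >= 3) applies a quadratic
    Savitzky-Golay filter before locating extrema, for noisy spectra.
    """
    windows = sorted((float(lo), float(hi)) for lo, hi in line_windows)
    for (lo1, hi1), (lo2, _) in zip(windows, windows[1:]):
        if lo2 < hi1:
            raise ValueError("line windows must not overlap")
    if len(windows) == 3:
        ipls, _ = _window_extract(spectrum, *windows[0], smooth)
        i0, dh0 = _window_extract(spectrum, *windows[1], smooth)
        imns, _ = _window_extract(spectrum, *windows[2], smooth)
        return SpectrumLines(I0=i0, Iplus1=ipls, Iminus1=imns, deltaH0=dh0)
    if len(windows) == 2:
        h, _ = _window_extract(spectrum, *windows[0], smooth)
        p, _ = _window_extract(spectrum, *windows[1], smooth)
        return PartitionAmplitudes(P=p, H=h)
    raise ValueError("expected 2 (partition) or 3 (three-line) windows")


def synth_nitroxide_spectrum(
    line_centers,
    amplitudes,
    widths,
    noise_sd: float = 0.0,
    seed: int = 0,
    field: np.ndarray | None = None,
    n_points: int = 4096,
    pad: float = 10.0,
) -> Spectrum:
    """Synthetic first-derivative spectrum: a sum of derivative Lorentzians.

    Each line is parameterised by its centre (gauss), its peak-to-peak
    amplitude, and its peak-to-peak width (the field separation of the
    derivative extrema, i.e. ``2 g / sqrt(3)`` for a Lorentzian of half-width
    ``g``).  Seeded Gaussian noise of standard deviation ``noise_sd`` is
    added.  Deterministic for a given seed.
    """
    centers = np.asarray(line_centers, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    wids = np.asarray(widths, dtype=float)
    if not (centers.shape == amps.shape == wids.shape):
        raise ValueError("line_centers, amplitudes, widths must be equal length")
    if np.any(amps <= 0) or np.any(wids <= 0):
        raise ValueError("amplitudes and widths must be > 0")
    if field is None:
        field = np.linspace(centers.min() - pad, centers.max() + pad, n_points)
    else:
        field = np.asarray(field, dtype=float)
    signal = np.zeros_like(field)
    for c, a, w in zip(centers, amps, wids):
        g = w * math.sqrt(3.0) / 2.0  # Lorentzian half-width at half-maximum
        u = (c - field) / g
        signal += (a / (2.0 * _DERIV_LORENTZ_PEAK)) * u / (1.0 + u * u) ** 2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=field.shape)
    return Spectrum(field=field, amplitude=signal)


def load_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column ASCII spectrum (field_gauss, amplitude)."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (field, amplitude)")
    return Spectrum(field=data[:, 0], amplitude=data[:, 1])


def save_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([spectrum.field, spectrum.amplitude]),
        header="field_gauss amplitude",
    )
    return path
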