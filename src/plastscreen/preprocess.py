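"""Derived FTIR spectra: standardization, Savitzky-Golay second
derivatives, mean and standard-deviation spectra, and SD-based
replicate selection.

The standard-deviation spectrum — the pointwise SD across a film
replicate's measurement grid — doubles as a spatial-heterogeneity
marker: fungal attack roughens the film surface chemistry, so attacked
replicates show systematically larger SD spectra than controls.  The
replicate entering the downstream PCA is the one with the largest
integrated SD spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "DerivedSpectra",
    "DegenerateSpectrumError",
    "standardize",
    "standardize_set",
    "second_derivative",
    "second_derivative_set",
    "mean_spectrum",
    "sd_spectrum",
    "sd_integral",
    "select_replicate_by_sd",
    "scaled_sd_overlay",
    "derive",
]

#: Default Savitzky-Golay window (points) and polynomial order for the
#: second derivative.  13 points is ~48 cm^-1 on a 4 cm^-1 grid —
#: wide enough to suppress noise, narrow enough to resolve the
#: 20-50 cm^-1 bands typical of polymer MIR spectra.
DEFAULT_SG_WINDOW = 13
DEFAULT_SG_POLYORDER = 2


class DegenerateSpectrumError(ValueError):
    """Spectrum has zero intensity variance and cannot be standardized."""


@dataclass(frozen=True)
class DerivedSpectra:
    """The four derived representations of one measurement set."""

    standardized: SpectrumSet
    second_derivative: SpectrumSet
    mean_spectrum: Spectrum
    sd_spectrum: Spectrum
    sd_integral: float


def standardize(s: Spectrum) -> Spectrum:
    """Z-score a spectrum: mean 0, sample SD 1 (n-1 denominator)."""
    y = s.intensities
    sd = y.std(ddof=1)
    if sd == 0:
        raise DegenerateSpectrumError("constant spectrum cannot be standardized")
    return s.with_intensities((y - y.mean()) / sd)


def standardize_set(spectra: SpectrumSet) -> SpectrumSet:
    m = spectra.intensity_matrix()
    sd = m.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateSpectrumError("constant spectrum in set cannot be standardized")
    return spectra.map_intensities((m - m.mean(axis=1, keepdims=True)) / sd)


def _check_uniform(grid: np.ndarray) -> float:
    steps = np.diff(grid)
    h = steps[0]
    if not np.allclose(steps, h, rtol=1e-6, atol=1e-9 * abs(h)):
        raise ValueError("second derivative requires a uniform wavenumber grid; resample first")
    return float(h)


def second_derivative(
    s: Spectrum,
    window_pts: int = DEFAULT_SG_WINDOW,
    poly_order: int = DEFAULT_SG_POLYORDER,
) -> Spectrum:
    """Savitzky-Golay second derivative with respect to wavenumber.

    Values are in intensity units per cm^-2 (the 1/h^2 scaling is
    applied).  Edges use scipy's polynomial-extension interpolation.
    Band centers appear as minima of the result.
    """
    if poly_order < 2:
        raise ValueError("poly_order must be >= 2 for a second derivative")
    if window_pts % 2 == 0 or window_pts < poly_order + 2:
        raise ValueError("window_pts must be odd and >= poly_order + 2")
    h = _check_uniform(s.wavenumbers)
    d2 = savgol_filter(s.intensities, window_pts, poly_order, deriv=2, delta=h, mode="interp")
    return s.with_intensities(d2)


def second_derivative_set(
    spectra: SpectrumSet,
    window_pts: int = DEFAULT_SG_WINDOW,
    poly_order: int = DEFAULT_SG_POLYORDER,
) -> SpectrumSet:
    if window_pts % 2 == 0 or window_pts < poly_order + 2:
        raise ValueError("window_pts must be odd and >= poly_order + 2")
    if poly_order < 2:
        raise ValueError("poly_order must be >= 2 for a second derivative")
    h = _check_uniform(spectra.grid)
    m = savgol_filter(
        spectra.intensity_matrix(), window_pts, poly_order, deriv=2, delta=h, axis=1, mode="interp"
    )
    return spectra.map_intensities(m)


def mean_spectrum(spectra: SpectrumSet) -> Spectrum:
    """Pointwise arithmetic mean across a set."""
    m = spectra.intensity_matrix().mean(axis=0)
    return spectra[0].with_intensities(m)


def sd_spectrum(spectra: SpectrumSet) -> Spectrum:
    """Pointwise sample SD (n-1) across a set; needs >= 2 members."""
    if len(spectra) < 2:
        raise ValueError("sd_spectrum needs at least 2 spectra")
    sd = spectra.intensity_matrix().std(axis=0, ddof=1)
    return spectra[0].with_intensities(sd)


def sd_integral(spectra: SpectrumSet) -> float:
    """Sum of the SD spectrum over the grid — the heterogeneity score."""
    return float(sd_spectrum(spectra).intensities.sum())


def select_replicate_by_sd(replicates: Sequence[SpectrumSet]) -> int:
    """Index of the replicate with the largest integrated SD spectrum.

    Ties break toward the earliest replicate.  Selection uses the raw
    (unstandardized) SD spectrum, so it scales linearly with intensity.
    """
    if not replicates:
        raise ValueError("no replicates supplied")
    scores = [sd_integral(r) for r in replicates]
    return int(np.argmax(scores))


def scaled_sd_overlay(sd: Spectrum, k: float) -> Spectrum:
    """SD spectrum multiplied by a constant, for display overlays."""
    if k <= 0:
        raise ValueError("scale factor must be positive")
    return sd.with_intensities(k * sd.intensities)


def derive(
    spectra: SpectrumSet,
    window_pts: int = DEFAULT_SG_WINDOW,
    poly_order: int = DEFAULT_SG_POLYORDER,
) -> DerivedSpectra:
    """Compute all four derived representations in one pass."""
    std = standardize_set(spectra)
    return DerivedSpectra(
        standardized=std,
        second_derivative=second_derivative_set(std, window_pts, poly_order),
        mean_spectrum=mean_spectrum(spectra),
        sd_spectrum=sd_spectrum(spectra),
        sd_integral=sd_integral(spectra),
    )
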