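"""Raman relative-change analysis of fungus-colonized plastic films.

Confocal Raman spectra taken on colonized and clean positions of the
same film are compared after (1) baseline subtraction, (2) averaging
the accumulated spectra per position, and (3) normalization to a
reference peak that the treatment leaves intact (e.g. the CH2 rocking
at 844 cm^-1 for PP).  Relative peak-intensity changes then report
which bond vibrations diminished; peaks present only in the treated
spectrum with prominence above a noise-sigma multiple are reported as
new peaks.

Note the deliberate blind spot: because intensities are normalized to
one reference peak, a uniform attenuation of *all* peaks (including the
reference) is invisible — the method measures changes relative to the
reference vibration, not absolute scattering loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.signal import find_peaks, savgol_filter
from scipy.sparse.linalg import spsolve

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "RamanComparison",
    "NormalizationError",
    "baseline_subtract",
    "average_position",
    "normalize_to_peak",
    "estimate_noise_sigma",
    "relative_peak_change",
    "detect_new_peaks",
]


class NormalizationError(ValueError):
    """Reference peak not found or indistinguishable from noise."""


@dataclass(frozen=True)
class PeakChange:
    shift: float
    control_intensity: float
    treated_intensity: float
    change_pct: float | None
    flag: str = ""


@dataclass(frozen=True)
class RamanComparison:
    """Relative peak changes and new peaks between treated and control."""

    reference_shift: float
    peak_changes: tuple
    new_peaks: tuple
    noise_sigma: float


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------


def _als_baseline(y: np.ndarray, lam: float, p: float, n_iter: int) -> np.ndarray:
    # Whittaker smoother with asymmetric weights (Eilers-Boelens style):
    # points above the baseline get weight p, points below 1-p.
    n = y.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    dtd = lam * (d @ d.T)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        W = sparse.diags(w)
        z = spsolve((W + dtd).tocsc(), w * y)
        if not np.all(np.isfinite(z)):
            raise RuntimeError(f"ALS baseline diverged (lam={lam}, p={p})")
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def baseline_subtract(
    s: Spectrum,
    method: str = "als",
    lam: float = 1e6,
    p: float = 0.01,
    n_iter: int = 10,
    poly_order: int = 3,
) -> Spectrum:
    """Estimate and subtract the baseline of a Raman spectrum.

    ``als`` (default) is an asymmetric-least-squares Whittaker
    smoother; ``poly`` iteratively fits a polynomial, discarding points
    far above the fit.  Small negative residuals are retained.
    """
    y = s.intensities
    if y.size < 32:
        raise ValueError("baseline estimation needs at least 32 points")
    if method == "als":
        base = _als_baseline(y, lam, p, n_iter)
    elif method == "poly":
        x = s.wavenumbers
        keep = np.ones(y.size, dtype=bool)
        base = np.zeros_like(y)
        for _ in range(20):
            coeffs = np.polynomial.polynomial.polyfit(x[keep], y[keep], poly_order)
            base = np.polynomial.polynomial.polyval(x, coeffs)
            resid = y - base
            sigma = resid[keep].std()
            new_keep = resid < 2.0 * sigma
            if np.array_equal(new_keep, keep):
                break
            keep = new_keep
            if keep.sum() < poly_order + 2:
                raise RuntimeError(f"polynomial baseline diverged (order={poly_order})")
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return s.with_intensities(y - base)


def average_position(spectra) -> Spectrum:
    """Mean of the accumulated spectra taken at one film position."""
    if isinstance(spectra, SpectrumSet):
        spectra = list(spectra)
    spectra = list(spectra)
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.wavenumbers.shape != grid.shape or not np.allclose(s.wavenumbers, grid):
            raise ValueError("position spectra must share a grid")
    m = np.mean([s.intensities for s in spectra], axis=0)
    return spectra[0].with_intensities(m)


# ---------------------------------------------------------------------------
# normalization and comparison
# ---------------------------------------------------------------------------


def estimate_noise_sigma(s: Spectrum, quiet_window: tuple[float, float] | None = None) -> float:
    """Robust noise SD: 1.4826 * MAD of the detrended signal.

    By default the whole first-difference signal is used (differencing
    removes smooth structure; the factor 1/sqrt(2) undoes the variance
    doubling).  A ``quiet_window`` (cm^-1 interval known to be
    signal-free) restricts the estimate to that region.
    """
    y = s.intensities
    if quiet_window is not None:
        lo, hi = quiet_window
        mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
        if mask.sum() < 8:
            raise ValueError("quiet window covers fewer than 8 points")
        y = y[mask]
    d = np.diff(y)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _locate_peak(s: Spectrum, shift: float, tol: float) -> int:
    """Index of the local maximum nearest ``shift`` within ± tol."""
    mask = np.abs(s.wavenumbers - shift) <= tol
    idx = np.where(mask)[0]
    if idx.size == 0:
        raise NormalizationError(f"no grid points within {tol:g} cm^-1 of {shift:g} cm^-1")
    y = s.intensities
    best = -1
    for i in idx:
        lo = max(i - 1, 0)
        hi = min(i + 1, y.size - 1)
        if y[i] >= y[lo] and y[i] >= y[hi]:
            if best < 0 or y[i] > y[best]:
                best = i
    if best < 0:
        raise NormalizationError(f"no local maximum within {shift:g} ± {tol:g} cm^-1")
    return best


def normalize_to_peak(s: Spectrum, reference_shift: float, search_tol: float = 8.0) -> Spectrum:
    """Divide a baseline-subtracted spectrum by its reference-peak intensity."""
    i = _locate_peak(s, reference_shift, search_tol)
    ref = s.intensities[i]
    sigma = estimate_noise_sigma(s)
    if ref <= sigma:
        raise NormalizationError(
            f"reference peak at {s.wavenumbers[i]:g} cm^-1 ({ref:g}) is within noise ({sigma:g})"
        )
    return s.with_intensities(s.intensities / ref)


def relative_peak_change(
    treated: Spectrum,
    control: Spectrum,
    peaks,
    reference_shift: float,
    match_tol: float = 8.0,
) -> RamanComparison:
    """Percent intensity change per peak after reference normalization.

    Both inputs must be baseline-subtracted; they are normalized to
    ``reference_shift`` here, so the change at the reference peak is 0
    by construction.  Peaks whose control intensity is within the noise
    are flagged ``unquantifiable`` rather than dropped.
    """
    treated_n = normalize_to_peak(treated, reference_shift, match_tol)
    control_n = normalize_to_peak(control, reference_shift, match_tol)
    sigma_t = estimate_noise_sigma(treated_n)
    sigma_c = estimate_noise_sigma(control_n)
    changes = []
    for shift in peaks:
        ic = _locate_peak(control_n, shift, match_tol)
        c_val = float(control_n.intensities[ic])
        try:
            it = _locate_peak(treated_n, shift, match_tol)
            t_val = float(treated_n.intensities[it])
        except NormalizationError:
            t_val = float(treated_n.intensities[ic])
        if abs(shift - reference_shift) <= match_tol:
            changes.append(PeakChange(shift, c_val, t_val, 0.0, "reference"))
        elif c_val <= sigma_c:
            changes.append(PeakChange(shift, c_val, t_val, None, "unquantifiable"))
        else:
            changes.append(PeakChange(shift, c_val, t_val, 100.0 * (t_val - c_val) / c_val))
    return RamanComparison(reference_shift, tuple(changes), (), max(sigma_t, sigma_c))


def detect_new_peaks(
    treated: Spectrum,
    control: Spectrum,
    sigma_mult: float = 3.0,
    match_tol: float = 8.0,
    quiet_window: tuple[float, float] | None = None,
    min_width_pts: int = 3,
) -> tuple:
    """Peaks present in the treated spectrum only.

    Local maxima of the (baseline-subtracted, lightly smoothed) treated
    spectrum with prominence above ``sigma_mult`` times the treated
    noise sigma and no control peak of comparable prominence within
    ``match_tol`` cm^-1.  A minimum width of ``min_width_pts`` grid
    points (at half prominence) rejects single-point noise spikes,
    which carry several-sigma prominence surprisingly often in white
    noise; real Raman bands span many grid points.
    """
    tiny = np.finfo(float).tiny
    sigma = max(estimate_noise_sigma(treated, quiet_window), tiny)
    sigma_c = max(estimate_noise_sigma(control, quiet_window), tiny)
    n = treated.intensities.size
    win = min(9, n if n % 2 else n - 1)
    y_t = savgol_filter(treated.intensities, win, 2)
    y_c = savgol_filter(control.intensities, win, 2)
    t_idx, _ = find_peaks(y_t, prominence=sigma_mult * sigma, width=min_width_pts)
    c_idx, _ = find_peaks(y_c, prominence=sigma_mult * sigma_c, width=min_width_pts)
    t_pos = treated.wavenumbers[t_idx]
    c_pos = control.wavenumbers[c_idx] if c_idx.size else np.empty(0)
    new = [float(p) for p in t_pos if not np.any(np.abs(c_pos - p) <= match_tol)]
    return tuple(new)
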