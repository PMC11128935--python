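"""Spectrum containers, readers/writers and grid resampling.

A :class:`Spectrum` is a single vibrational-spectroscopy measurement:
a strictly increasing wavenumber axis (cm^-1) with one intensity per
point (absorbance for FTIR-ATR, counts for Raman), plus the metadata
needed to place the measurement in a film-screening experiment (polymer,
treatment, strain, replicate, grid position).  A :class:`SpectrumSet`
is a collection of measurements sharing one wavenumber grid — e.g. the
25 grid-point measurements taken on a single film replicate.

Supported on-disk formats are two-column delimited text (wavenumber,
intensity) and the plain-text JCAMP-DX dialects ``XYDATA=(X++(Y..Y))``
(AFFN numbers) and ``XYPOINTS=(XY..XY)``.  Measurement metadata that the
spectrum files themselves cannot carry travels in a manifest CSV with
one row per file.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "SpectrumFormatError",
    "SpectrumRangeError",
    "ModalityRangeWarning",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "resample_to_grid",
    "default_ftir_grid",
    "POLYMERS",
]

#: Polymer codes the toolkit knows about.
POLYMERS = ("LDPE", "PA", "PET", "PP", "PU")

#: Valid wavenumber range per modality (cm^-1).
MODALITY_RANGES = {"FTIR": (400.0, 4000.0), "Raman": (200.0, 3000.0)}


class SpectrumFormatError(ValueError):
    """A spectrum file could not be parsed."""


class SpectrumRangeError(ValueError):
    """A requested grid lies outside a spectrum's wavenumber range."""


class ModalityRangeWarning(UserWarning):
    """Wavenumbers fall outside the conventional range for the modality."""


@dataclass(frozen=True)
class Spectrum:
    """One spectroscopic measurement on a shared wavenumber axis.

    Parameters
    ----------
    wavenumbers : ndarray
        Strictly increasing axis in cm^-1.  Input in descending order
        (the FTIR display convention) is sorted ascending on
        construction, carrying intensities along.
    intensities : ndarray
        Absorbance (FTIR) or counts (Raman); same length as the axis.
    modality : {"FTIR", "Raman"}
    polymer : {"LDPE", "PA", "PET", "PP", "PU", "none"}
    treatment : {"control", "incubated"}
    strain_id, replicate_id : str
    position : tuple of int, optional
        ``(row, col)`` grid index, or ``(i,)`` for axial layouts.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    modality: str = "FTIR"
    polymer: str = "none"
    treatment: str = "control"
    strain_id: str = ""
    replicate_id: str = ""
    position: tuple | None = None

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1 or w.size != y.size:
            raise ValueError("wavenumbers and intensities must be 1-D arrays of equal length")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(y)):
            raise ValueError("spectrum contains non-finite values")
        order = np.argsort(w, kind="stable")
        w, y = w[order], y[order]
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavenumbers contain duplicates")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)
        if self.modality not in MODALITY_RANGES:
            raise ValueError(f"unknown modality {self.modality!r}")
        lo, hi = MODALITY_RANGES[self.modality]
        if w[0] < lo - 1e-9 or w[-1] > hi + 1e-9:
            warnings.warn(
                f"{self.modality} spectrum spans {w[0]:.1f}-{w[-1]:.1f} cm^-1, outside the "
                f"conventional {lo:.0f}-{hi:.0f} cm^-1 window",
                ModalityRangeWarning,
                stacklevel=2,
            )

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with new intensities on the same axis."""
        return replace(self, intensities=np.asarray(y, dtype=float))


@dataclass(frozen=True)
class SpectrumSet:
    """Measurements sharing one wavenumber grid (e.g. one film replicate)."""

    spectra: tuple
    grid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        spectra = tuple(self.spectra)
        if not spectra:
            raise ValueError("SpectrumSet must contain at least one spectrum")
        grid = self.grid if self.grid is not None else spectra[0].wavenumbers
        grid = np.asarray(grid, dtype=float)
        for s in spectra:
            if s.wavenumbers.shape != grid.shape or not np.allclose(s.wavenumbers, grid):
                raise ValueError("all member spectra must share the set grid; resample first")
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "grid", grid)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    def intensity_matrix(self) -> np.ndarray:
        """Stack intensities into an ``(n_spectra, n_points)`` array."""
        return np.vstack([s.intensities for s in self.spectra])

    def map_intensities(self, matrix: np.ndarray) -> "SpectrumSet":
        """New set with intensities replaced row-by-row from ``matrix``."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(self), self.grid.size):
            raise ValueError("matrix shape does not match set")
        return SpectrumSet(
            tuple(s.with_intensities(row) for s, row in zip(self.spectra, matrix)),
            grid=self.grid,
        )


def default_ftir_grid(start: float = 400.0, stop: float = 4000.0, step: float = 4.0) -> np.ndarray:
    """Default FTIR working grid: 400-4000 cm^-1 at 4 cm^-1 steps."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_NUM = r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?"


def _parse_two_column(text: str, path: str) -> tuple[np.ndarray, np.ndarray]:
    w, y = [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = re.split(r"[,;\s\t]+", stripped)
        parts = [p for p in parts if p]
        if len(parts) < 2:
            raise SpectrumFormatError(f"{path}: line {lineno}: expected two columns, got {stripped!r}")
        try:
            w.append(float(parts[0]))
            y.append(float(parts[1]))
        except ValueError:
            if lineno == 1 and not w:
                continue  # header row
            raise SpectrumFormatError(f"{path}: line {lineno}: non-numeric data {stripped!r}") from None
    return np.array(w), np.array(y)


def _parse_jcamp(text: str, path: str) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX: AFFN ``XYDATA=(X++(Y..Y))`` and ``XYPOINTS=(XY..XY)``."""
    lines = text.splitlines()
    records: dict[str, str] = {}
    data_mode = None
    data_lines: list[str] = []
    for line in lines:
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = re.sub(r"[\s_-]", "", key).upper()
            value = value.strip()
            if key == "XYDATA":
                data_mode = "xydata"
            elif key == "XYPOINTS":
                data_mode = "xypoints"
            elif key == "END":
                break
            else:
                records[key] = value
                data_mode = None
        elif data_mode:
            data_lines.append(line)
    if data_mode is None and not data_lines:
        raise SpectrumFormatError(f"{path}: no XYDATA or XYPOINTS record found")

    xfac = float(records.get("XFACTOR", 1.0))
    yfac = float(records.get("YFACTOR", 1.0))
    w, y = [], []
    if data_mode == "xypoints":
        for line in data_lines:
            for pair in re.findall(rf"({_NUM})\s*[, ]\s*({_NUM})", line):
                w.append(float(pair[0]) * xfac)
                y.append(float(pair[1]) * yfac)
    else:  # (X++(Y..Y)): first number per line is X, rest are Y at successive steps
        rows = []
        for line in data_lines:
            nums = [float(v) for v in re.findall(_NUM, line)]
            if len(nums) >= 2:
                rows.append(nums)
        if not rows:
            raise SpectrumFormatError(f"{path}: empty XYDATA block")
        # infer step from consecutive line starts, else FIRSTX/LASTX/NPOINTS
        if "DELTAX" in records:
            step = float(records["DELTAX"])
        elif len(rows) > 1:
            step = (rows[1][0] - rows[0][0]) / (len(rows[0]) - 1)
        elif "FIRSTX" in records and "LASTX" in records and "NPOINTS" in records:
            npts = int(float(records["NPOINTS"]))
            step = (float(records["LASTX"]) - float(records["FIRSTX"])) / max(npts - 1, 1)
        else:
            raise SpectrumFormatError(f"{path}: cannot infer XYDATA abscissa step")
        for nums in rows:
            x0 = nums[0]
            for i, yi in enumerate(nums[1:]):
                w.append((x0 + i * step) * xfac)
                y.append(yi * yfac)
    if not w:
        raise SpectrumFormatError(f"{path}: no data points parsed")
    return np.array(w), np.array(y)


def read_spectrum(path, format: str = "auto", **metadata) -> Spectrum:
    """Read a spectrum from two-column text or JCAMP-DX.

    Parameters
    ----------
    path : path-like
    format : {"auto", "csv2col", "jcamp-dx"}
        ``auto`` sniffs JCAMP by the leading ``##TITLE``/``##JCAMP``
        record; anything else is treated as two-column text.
    **metadata
        Passed to the :class:`Spectrum` constructor (modality, polymer,
        treatment, strain_id, replicate_id, position).
    """
    path = Path(path)
    text = path.read_text()
    if format == "auto":
        head = text.lstrip()[:400].upper()
        format = "jcamp-dx" if head.startswith("##") else "csv2col"
    if format == "jcamp-dx":
        w, y = _parse_jcamp(text, str(path))
    elif format == "csv2col":
        w, y = _parse_two_column(text, str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    if w.size < 8:
        raise SpectrumFormatError(f"{path}: only {w.size} points; at least 8 required")
    return Spectrum(w, y, **metadata)


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column CSV (ascending wavenumber)."""
    arr = np.column_stack([spectrum.wavenumbers, spectrum.intensities])
    np.savetxt(path, arr, delimiter=",", header="wavenumber_cm-1,intensity", comments="", fmt="%.10g")


MANIFEST_COLUMNS = ["path", "modality", "polymer", "treatment", "strain_id", "replicate_id", "row", "col"]


def read_manifest(path) -> list[Spectrum]:
    """Read spectra listed in a manifest CSV (one row per spectrum file).

    Columns: path, modality, polymer, treatment, strain_id,
    replicate_id, row, col; ``path`` is resolved relative to the
    manifest's directory; row/col may be empty for unplaced spectra.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"strain_id": str, "replicate_id": str})
    missing = [c for c in ("path", "polymer", "treatment") if c not in table.columns]
    if missing:
        raise SpectrumFormatError(f"{path}: manifest missing columns {missing}")
    out = []
    for rec in table.to_dict("records"):
        pos = None
        if pd.notna(rec.get("row")) and pd.notna(rec.get("col")):
            pos = (int(rec["row"]), int(rec["col"]))
        elif pd.notna(rec.get("row")):
            pos = (int(rec["row"]),)
        out.append(
            read_spectrum(
                path.parent / rec["path"],
                modality=str(rec.get("modality", "FTIR") or "FTIR"),
                polymer=str(rec["polymer"]),
                treatment=str(rec["treatment"]),
                strain_id="" if pd.isna(rec.get("strain_id")) else str(rec["strain_id"]),
                replicate_id="" if pd.isna(rec.get("replicate_id")) else str(rec["replicate_id"]),
                position=pos,
            )
        )
    return out


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def resample_to_grid(spectra: Iterable[Spectrum] | Spectrum, grid: Sequence[float]) -> SpectrumSet:
    """Linearly interpolate spectra onto a common grid (no extrapolation).

    Raises :class:`SpectrumRangeError` if the grid extends beyond any
    spectrum's measured range.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    spectra = list(spectra)
    out = []
    for i, s in enumerate(spectra):
        if grid[0] < s.wavenumbers[0] - 1e-9 or grid[-1] > s.wavenumbers[-1] + 1e-9:
            name = s.replicate_id or f"spectrum #{i}"
            raise SpectrumRangeError(
                f"grid [{grid[0]:g}, {grid[-1]:g}] exceeds range "
                f"[{s.wavenumbers[0]:g}, {s.wavenumbers[-1]:g}] of {name}"
            )
        y = np.interp(grid, s.wavenumbers, s.intensities)
        out.append(replace(s, wavenumbers=grid, intensities=y))
    return SpectrumSet(tuple(out), grid=grid)
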