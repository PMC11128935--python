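"""FTIR-ATR chemometrics: band identification, correlation-matrix PCA,
ANOVA on component scores, and the relative absorbance decrease (RAD).

The inference chain turns a pair of film measurement sets (control film
vs film incubated with a fungal strain) into per-band degradation
calls:

1. band centers are located as minima of the mean Savitzky-Golay
   second-derivative spectrum (second derivatives sharpen overlapping
   bands; a band's center is a derivative minimum);
2. each measurement's standardized absorbance at the band centers forms
   a measurements x bands matrix;
3. PCA on the band correlation matrix groups covarying bands into
   spectral signals; loadings are scaled by the square root of the
   eigenvalue so a loading is the band-component correlation, which
   makes the conventional |loading| >= 0.5 retention cut and the
   communalities (sum of squared loadings) meaningful;
4. components with at least one |loading| >= 0.5 are tested by one-way
   ANOVA of their scores against the control/incubated grouping;
5. for every band loading highly on a significant component, the
   relative absorbance decrease

       RAD(%) = 100 * (mean A_incubated - mean A_control) / mean A_control

   is computed from the raw (unstandardized) absorbances; negative RAD
   marks loss of the corresponding bond population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import (
    DEFAULT_SG_POLYORDER,
    DEFAULT_SG_WINDOW,
    mean_spectrum,
    second_derivative_set,
    standardize_set,
)
from .spectra import SpectrumSet

__all__ = [
    "BandTable",
    "BandMatrix",
    "BandPCA",
    "DegradationResult",
    "FTIRDegradationAnalyzer",
    "detect_bands",
    "reference_bands",
    "band_absorbances",
    "select_components",
    "anova_on_scores",
    "rad",
    "degradation_report",
    "score_map",
]


# ---------------------------------------------------------------------------
# reference band library
# ---------------------------------------------------------------------------

#: Characteristic MIR band positions (cm^-1) and vibration-mode labels
#: per polymer.  st = stretching, bd = bending, rk = rocking,
#: tw = twisting, wg = wagging; -ip/-oop = in/out of plane.
_REFERENCE_BANDS: dict[str, list[tuple[float, str]]] = {
    "LDPE": [
        (2915.0, "CH2 st"),
        (2840.0, "CH2 st"),
        (1463.0, "CH bd-ip"),
        (1377.0, "CH bd-ip"),
        (718.0, "C-H rocking"),
    ],
    "PA": [
        (3297.0, "N-H st"),
        (3066.0, "amide II overtone"),
        (2932.0, "C-H st"),
        (2857.0, "CH2 st"),
        (1731.0, "CO st"),
        (1631.0, "amide I CO st"),
        (1534.0, "amide II N-H bd-ip / C-N st"),
        (1474.0, "CH2 bd"),
        (1461.0, "CH2 bd"),
        (1439.0, "CH2 bd"),
        (1416.0, "CH2 bd"),
        (1370.0, "C-H bd"),
        (1275.0, "amide III C-N st / N-H bd-ip"),
        (1198.0, "CH2 bd"),
        (1180.0, "CH2 bd"),
        (936.0, "CO bd"),
        (729.0, "amide V N-H bd-oop"),
        (688.0, "amide IV N-H bd-oop"),
        (578.0, "CO bd"),
        (533.0, "chain deformation"),
    ],
    "PET": [
        (1715.0, "CO st"),
        (1409.0, "C-H bd"),
        (1349.0, "C-H bd"),
        (1243.0, "C-C st"),
        (1124.0, "O-C st"),
        (1098.0, "O-C st"),
        (1018.0, "C-H bd"),
        (969.0, "C-H bd"),
        (870.0, "C-H bd"),
        (846.0, "C-H bd"),
        (725.0, "C-H bd"),
    ],
    "PP": [
        (2950.0, "CH3 st"),
        (2917.0, "CH2 st"),
        (2868.0, "CH3 st"),
        (2838.0, "CH2 st"),
        (1459.0, "CH3 bd"),
        (1437.0, "CH2 bd"),
        (1375.0, "CH3 bd"),
        (1359.0, "C-H bd"),
        (1167.0, "C-H bd"),
        (997.0, "CH3 rk"),
        (973.0, "CH3 rk"),
        (900.0, "C-H bd"),
        (841.0, "CH2 rk"),
        (809.0, "C-C st backbone"),
    ],
    "PU": [
        (1705.0, "CO st"),
        (1593.0, "C-N / N-H"),
        (1511.0, "C-N / N-H"),
        (1411.0, "C-C"),
        (1375.0, "C-H"),
        (1308.0, "C-H"),
        (1217.0, "O-C"),
        (1072.0, "C-O"),
        (1040.0, "C-C"),
        (1016.0, "C-H"),
        (813.0, "C-C"),
    ],
}


@dataclass(frozen=True)
class BandTable:
    """Detected or reference band centers with vibration-mode labels."""

    centers: np.ndarray
    labels: tuple
    polymer: str = "none"
    source: str = "detected"

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 1:
            raise ValueError("centers must be 1-D")
        if np.any(np.diff(centers) <= 0):
            order = np.argsort(centers)
            centers = centers[order]
            object.__setattr__(self, "labels", tuple(np.asarray(self.labels, dtype=object)[order]))
        if len(self.labels) != centers.size:
            raise ValueError("labels and centers must have equal length")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return self.centers.size


def reference_bands(polymer: str) -> BandTable:
    """Characteristic band table for one of the supported polymers."""
    if polymer not in _REFERENCE_BANDS:
        raise ValueError(f"no reference band table for polymer {polymer!r}; supported: {sorted(_REFERENCE_BANDS)}")
    entries = sorted(_REFERENCE_BANDS[polymer])
    return BandTable(
        centers=np.array([c for c, _ in entries]),
        labels=tuple(lbl for _, lbl in entries),
        polymer=polymer,
        source="reference",
    )


def detect_bands(
    second_derivs: SpectrumSet,
    depth_factor: float = 5.0,
    merge_tol: float = 8.0,
) -> BandTable:
    """Locate band centers as minima of the mean second-derivative spectrum.

    A minimum qualifies when its depth (negated second derivative)
    exceeds ``depth_factor`` robust-sigma units, where the robust sigma
    is the normal-consistent median absolute deviation (1.4826 x MAD)
    of the mean second derivative; minima closer than ``merge_tol``
    cm^-1 are merged into the deeper one.
    """
    mean_d2 = mean_spectrum(second_derivs)
    d2 = mean_d2.intensities
    grid = mean_d2.wavenumbers
    mad = float(np.median(np.abs(d2 - np.median(d2))))
    threshold = depth_factor * 1.4826 * mad
    idx, props = find_peaks(-d2, height=threshold if threshold > 0 else None)
    if idx.size == 0:
        return BandTable(np.empty(0), ())
    depths = -d2[idx]
    # greedy merge, deepest first
    order = np.argsort(depths)[::-1]
    kept: list[int] = []
    for j in order:
        if all(abs(grid[idx[j]] - grid[idx[k]]) >= merge_tol for k in kept):
            kept.append(j)
    centers = np.sort(grid[idx[np.array(kept)]])
    return BandTable(centers, tuple("unassigned" for _ in centers))


# ---------------------------------------------------------------------------
# band matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandMatrix:
    """Measurements x bands absorbance matrix with group labels.

    ``values`` holds per-spectrum standardized absorbances (the PCA
    input); ``raw`` the corresponding raw absorbances (the RAD input).
    """

    values: np.ndarray
    bands: BandTable
    group: tuple
    raw: np.ndarray | None = None
    positions: tuple | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.bands):
            raise ValueError("values must be measurements x bands")
        if not np.all(np.isfinite(v)):
            raise ValueError("band matrix contains non-finite values")
        if len(self.group) != v.shape[0]:
            raise ValueError("one group label per measurement required")
        if self.raw is not None and np.asarray(self.raw).shape != v.shape:
            raise ValueError("raw matrix must match values shape")
        if self.positions is not None and len(self.positions) != v.shape[0]:
            raise ValueError("one position per measurement required")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "group", tuple(self.group))
        if self.raw is not None:
            object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))
        if self.positions is not None:
            object.__setattr__(self, "positions", tuple(self.positions))


def _band_indices(grid: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest grid index per band center; exact ties break toward the
    lower wavenumber."""
    idx = np.empty(centers.size, dtype=int)
    for i, c in enumerate(centers):
        if c < grid[0] or c > grid[-1]:
            raise ValueError(f"band center {c:g} cm^-1 outside grid [{grid[0]:g}, {grid[-1]:g}]")
        d = np.abs(grid - c)
        idx[i] = int(np.argmin(d))  # argmin returns the first (lower) index on ties
    return idx


def band_absorbances(
    standardized: SpectrumSet,
    bands: BandTable,
    pick_tol: float = 0.0,
    raw: SpectrumSet | None = None,
    group: Sequence[str] | None = None,
) -> BandMatrix:
    """Extract per-measurement band absorbances at the band centers.

    With ``pick_tol`` > 0 each measurement uses its local maximum within
    ``center ± pick_tol`` instead of the fixed nearest grid point.
    ``raw`` supplies the matching unstandardized set so RAD can later be
    computed on true absorbances.
    """
    grid = standardized.grid
    centers = bands.centers
    m = standardized.intensity_matrix()
    raw_m = raw.intensity_matrix() if raw is not None else None
    base_idx = _band_indices(grid, centers)
    n = m.shape[0]
    values = np.empty((n, centers.size))
    raw_values = np.empty_like(values) if raw_m is not None else None
    for j, (c, bi) in enumerate(zip(centers, base_idx)):
        if pick_tol > 0:
            window = np.where(np.abs(grid - c) <= pick_tol)[0]
            sel = window[np.argmax(m[:, window], axis=1)]
        else:
            sel = np.full(n, bi)
        values[:, j] = m[np.arange(n), sel]
        if raw_values is not None:
            raw_values[:, j] = raw_m[np.arange(n), sel]
    if group is None:
        group = tuple(s.treatment for s in standardized)
    positions = tuple(s.position for s in standardized)
    if any(p is None for p in positions):
        positions = None
    return BandMatrix(values, bands, tuple(group), raw=raw_values, positions=positions)


# ---------------------------------------------------------------------------
# correlation-matrix PCA
# ---------------------------------------------------------------------------


class BandPCA(BaseEstimator, TransformerMixin):
    """PCA on the band correlation matrix, factor-analysis style.

    Band columns are z-scored across measurements, the correlation
    matrix is eigendecomposed, and loadings are scaled by the square
    root of the eigenvalue, so each loading equals the Pearson
    correlation between a band and a component.  All components are
    extracted; downstream selection uses the |loading| >= ``loading_cut``
    rule rather than Kaiser or scree criteria.  No rotation is applied
    unless requested.

    Attributes (after :meth:`fit`)
    ------------------------------
    loadings_ : ndarray, (n_bands, n_components)
    eigenvalues_ : ndarray
    explained_variance_ratio_ : ndarray
    components_ : ndarray, (n_components, n_bands)
        Unit-norm eigenvectors (sklearn orientation).
    scores_ : ndarray, (n_measurements, n_components)
        Scores of the training matrix.
    mean_, scale_ : ndarray
        Column means and sample SDs used for standardization.
    """

    def __init__(self, rotate: bool = False):
        self.rotate = rotate

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (measurements x bands)")
        n, p = X.shape
        if n < 3 or p < 2:
            raise ValueError("need >= 3 measurements and >= 2 bands")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.all(self.scale_ == 0):
            raise ValueError("zero total variance: all band columns are constant")
        if np.any(self.scale_ == 0):
            raise ValueError("constant band column cannot enter a correlation-matrix PCA")
        Z = (X - self.mean_) / self.scale_
        corr = (Z.T @ Z) / (n - 1)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)
        eigvec = eigvec[:, order]
        # reproducible sign: largest-|loading| band positive per component
        for k in range(p):
            pivot = np.argmax(np.abs(eigvec[:, k]))
            if eigvec[pivot, k] < 0:
                eigvec[:, k] = -eigvec[:, k]
        if self.rotate:
            eigvec, eigval = self._varimax(eigvec, eigval)
        self.eigenvalues_ = eigval
        self.components_ = eigvec.T
        self.loadings_ = eigvec * np.sqrt(eigval)
        self.explained_variance_ratio_ = eigval / eigval.sum()
        self.n_features_in_ = p
        self.scores_ = Z @ eigvec
        return self

    @staticmethod
    def _varimax(eigvec, eigval, max_iter=100, tol=1e-8):
        # optional orthogonal rotation of the scaled loadings
        L = eigvec * np.sqrt(eigval)
        p, k = L.shape
        R = np.eye(k)
        var_old = 0.0
        for _ in range(max_iter):
            LR = L @ R
            u, s, vt = np.linalg.svd(L.T @ (LR**3 - LR @ np.diag((LR**2).sum(axis=0)) / p))
            R = u @ vt
            var = s.sum()
            if var - var_old < tol:
                break
            var_old = var
        Lrot = L @ R
        new_eig = (Lrot**2).sum(axis=0)
        return Lrot / np.sqrt(new_eig), new_eig

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.components_.T

    def communalities(self, n_components: int | None = None) -> np.ndarray:
        """Per-band sum of squared loadings over the first k components."""
        k = self.loadings_.shape[1] if n_components is None else n_components
        return (self.loadings_[:, :k] ** 2).sum(axis=1)


def fit_pca(m: BandMatrix, rotate: bool = False) -> BandPCA:
    """Fit a :class:`BandPCA` on a band matrix."""
    return BandPCA(rotate=rotate).fit(m.values)


def select_components(model: BandPCA, loading_cut: float = 0.5) -> list[int]:
    """Indices of components carrying at least one |loading| >= cut."""
    keep = np.abs(model.loadings_).max(axis=0) >= loading_cut
    return [int(i) for i in np.where(keep)[0]]


def anova_on_scores(scores: np.ndarray, group: Sequence[str]) -> pd.DataFrame:
    """One-way ANOVA of component scores against group labels.

    Returns a table with one row per component (F, p).  With exactly
    two groups, F equals the square of the pooled two-sample t.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    masks = [group == g for g in labels]
    if any(mask.sum() < 2 for mask in masks):
        raise ValueError("every group needs at least 2 measurements")
    rows = []
    for k in range(scores.shape[1]):
        groups = [scores[mask, k] for mask in masks]
        f, p = stats.f_oneway(*groups)
        rows.append({"component": k, "F": float(f), "p": float(p)})
    return pd.DataFrame(rows)


def rad(mean_before: float, mean_after: float) -> float:
    """Relative absorbance decrease, signed percent.

    ``100 * (after - before) / before``: negative values mean the band
    lost absorbance during incubation.
    """
    if mean_before == 0:
        raise ZeroDivisionError("RAD undefined: mean absorbance before incubation is zero")
    return 100.0 * (mean_after - mean_before) / mean_before


# ---------------------------------------------------------------------------
# degradation report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegradationResult:
    """Outcome of the PCA -> ANOVA -> RAD chain for one film pair."""

    selected_components: tuple
    anova: pd.DataFrame
    significant_components: tuple
    rad_pct: dict = field(default_factory=dict)
    decreased_bands: tuple = ()
    explained_selected: float = 0.0

    @property
    def no_signal(self) -> bool:
        return len(self.significant_components) == 0


def degradation_report(
    m: BandMatrix,
    model: BandPCA,
    alpha: float = 0.05,
    loading_cut: float = 0.5,
    control_label: str = "control",
    incubated_label: str = "incubated",
) -> DegradationResult:
    """Select components, test them, and compute RAD for high-loading bands.

    RAD uses the raw (unstandardized) mean band absorbances: the control
    group is "before incubation", the incubated group "after".  Bands
    enter the RAD table when they load |loading| >= ``loading_cut`` on
    at least one component whose score ANOVA is significant at
    ``alpha``.  An empty result is a valid no-signal outcome, not an
    error.
    """
    if m.raw is None:
        raise ValueError("BandMatrix.raw is required for RAD (raw absorbances)")
    selected = select_components(model, loading_cut)
    if not selected:
        return DegradationResult((), anova_on_scores(model.scores_[:, :0], m.group), ())
    anova = anova_on_scores(model.scores_[:, selected], m.group)
    anova["component"] = selected
    significant = [c for c, p in zip(selected, anova["p"]) if p < alpha]

    rad_pct: dict[float, float] = {}
    decreased = []
    if significant:
        group = np.asarray(m.group)
        ctrl = group == control_label
        incu = group == incubated_label
        high = (np.abs(model.loadings_[:, significant]) >= loading_cut).any(axis=1)
        for j in np.where(high)[0]:
            before = float(m.raw[ctrl, j].mean())
            after = float(m.raw[incu, j].mean())
            center = float(m.bands.centers[j])
            rad_pct[center] = rad(before, after)
            if rad_pct[center] < 0:
                decreased.append(center)
    explained = float(model.explained_variance_ratio_[selected].sum())
    return DegradationResult(
        tuple(selected), anova, tuple(significant), rad_pct, tuple(decreased), explained
    )


def score_map(model: BandPCA, positions: Sequence, component: int) -> pd.DataFrame:
    """Tabulate one component's scores by film grid position.

    Returns a frame with row, col (col = 0 for axial layouts), score
    and sign, ordered by (row, col) then input order — the layout of
    the published score bubble maps.
    """
    scores = model.scores_[:, component]
    if len(positions) != scores.size:
        raise ValueError("positions and scores length mismatch")
    rows = []
    for i, pos in enumerate(positions):
        if pos is None:
            raise ValueError("every measurement needs a position for a score map")
        r = int(pos[0])
        c = int(pos[1]) if len(pos) > 1 else 0
        rows.append({"row": r, "col": c, "score": float(scores[i]), "sign": "+" if scores[i] >= 0 else "-"})
    frame = pd.DataFrame(rows)
    return frame.sort_values(["row", "col"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# end-to-end analyzer
# ---------------------------------------------------------------------------


class FTIRDegradationAnalyzer(BaseEstimator):
    """Full FTIR degradation analysis for one control/incubated film pair.

    Wraps standardization, second-derivative band detection, band
    absorbance extraction, :class:`BandPCA`, score ANOVA and RAD into
    one estimator.

    Parameters
    ----------
    sg_window, sg_polyorder : int
        Savitzky-Golay second-derivative settings.
    depth_factor : float
        Band-detection depth threshold in MAD units.
    merge_tol : float
        Minimum band separation (cm^-1); closer minima merge.
    pick_tol : float
        Half-width (cm^-1) of the per-measurement local-maximum search
        at each band; 0 = fixed nearest grid point.
    loading_cut, alpha : float
        Component retention and significance thresholds.
    bands : BandTable, optional
        Skip detection and use a fixed (e.g. reference) band table.
    """

    def __init__(
        self,
        sg_window: int = DEFAULT_SG_WINDOW,
        sg_polyorder: int = DEFAULT_SG_POLYORDER,
        depth_factor: float = 5.0,
        merge_tol: float = 8.0,
        pick_tol: float = 0.0,
        loading_cut: float = 0.5,
        alpha: float = 0.05,
        bands: BandTable | None = None,
    ):
        self.sg_window = sg_window
        self.sg_polyorder = sg_polyorder
        self.depth_factor = depth_factor
        self.merge_tol = merge_tol
        self.pick_tol = pick_tol
        self.loading_cut = loading_cut
        self.alpha = alpha
        self.bands = bands

    def fit(self, control: SpectrumSet, incubated: SpectrumSet):
        if not np.allclose(control.grid, incubated.grid):
            raise ValueError("control and incubated sets must share a grid")
        combined = SpectrumSet(tuple(control) + tuple(incubated), grid=control.grid)
        group = ("control",) * len(control) + ("incubated",) * len(incubated)
        std = standardize_set(combined)
        if self.bands is not None:
            bands = self.bands
        else:
            d2 = second_derivative_set(std, self.sg_window, self.sg_polyorder)
            bands = detect_bands(d2, self.depth_factor, self.merge_tol)
        if len(bands) < 2:
            raise ValueError(f"only {len(bands)} band(s) detected; PCA needs at least 2")
        self.bands_ = bands
        self.matrix_ = band_absorbances(std, bands, pick_tol=self.pick_tol, raw=combined, group=group)
        self.pca_ = fit_pca(self.matrix_)
        self.result_ = degradation_report(
            self.matrix_, self.pca_, alpha=self.alpha, loading_cut=self.loading_cut
        )
        return self

    def score_map(self, component: int) -> pd.DataFrame:
        if self.matrix_.positions is None:
            raise ValueError("input spectra carried no grid positions")
        return score_map(self.pca_, self.matrix_.positions, component)
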