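"""Seeded synthetic film spectra and respirometry screens with known truth.

The generators emulate the measurement designs of a desk-scale plastic
biodegradation screen so every pipeline stage can be tested without
instrument data:

* FTIR film pairs — a control film and an incubated film measured on a
  grid of positions (5x5 by default; polyurethane foams are measured as
  a 1x10 axial transect).  Each measurement is a sum of Gaussian bands
  at the polymer's characteristic wavenumbers on a linear baseline with
  white noise; fungal attack is planted as per-band fractional
  attenuation applied uniformly, on the film fringe (outermost grid
  ring), or on a random patchy subset of positions.
* Raman position pairs — three accumulated spectra per position
  (colonized and clean), with planted attenuations and optional
  treatment-only peaks.
* respirometry screens — triplicate with/without-plastic bottles per
  strain plus the two uninoculated blank sets, with a planted CO2
  effect for a chosen fraction of responder strains.

Every generator is a pure function of its scenario and seed: the same
inputs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chemometrics import reference_bands
from .respirometry import RespirometrySample
from .spectra import Spectrum, SpectrumSet, default_ftir_grid

__all__ = [
    "SyntheticBand",
    "DegradationScenario",
    "polymer_scenario",
    "pp_raman_scenario",
    "generate_film_pair",
    "generate_raman_pair",
    "generate_respirometry_screen",
]


@dataclass(frozen=True)
class SyntheticBand:
    """One planted Gaussian band."""

    center: float
    fwhm: float = 20.0
    amplitude: float = 1.0
    attenuation: float = 0.0
    is_new: bool = False

    def __post_init__(self):
        if self.fwhm <= 0 or self.amplitude < 0 or not (0.0 <= self.attenuation <= 1.0):
            raise ValueError("require fwhm > 0, amplitude >= 0, attenuation in [0, 1]")


SPATIAL_PATTERNS = ("uniform", "fringe", "patchy")


@dataclass(frozen=True)
class DegradationScenario:
    """Ground truth for one synthetic film (or Raman position) pair."""

    bands: tuple
    spatial_pattern: str = "uniform"
    noise_sd: float = 0.01
    baseline: tuple = (0.0, 0.0)  # (offset, slope per cm^-1)
    grid_shape: tuple = (5, 5)
    n_replicates: int = 1
    seed: int = 0
    modality: str = "FTIR"
    polymer: str = "none"
    wavenumbers: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.spatial_pattern not in SPATIAL_PATTERNS:
            raise ValueError(f"unknown spatial pattern {self.spatial_pattern!r}")
        object.__setattr__(self, "bands", tuple(self.bands))
        if self.wavenumbers is None:
            grid = default_ftir_grid() if self.modality == "FTIR" else np.arange(200.0, 3000.0 + 1, 2.0)
            object.__setattr__(self, "wavenumbers", grid)

    def with_attenuation(self, attenuation: float, centers=None) -> "DegradationScenario":
        """Copy with ``attenuation`` planted on the given band centers
        (all bands if None)."""
        targets = None if centers is None else set(float(c) for c in centers)
        bands = tuple(
            replace(b, attenuation=attenuation) if (targets is None or b.center in targets) else b
            for b in self.bands
        )
        return replace(self, bands=bands)


def polymer_scenario(polymer: str, noise_sd: float = 0.01, spatial_pattern: str = "uniform", seed: int = 0) -> DegradationScenario:
    """Control template for a polymer: bands at the reference positions,
    unit-order amplitudes, zero attenuation.

    Amplitudes cycle through {1.0, 0.7, 0.5} in descending-wavenumber
    order so the planted spectra have the large/medium/small band mix
    of real polymer MIR spectra.  PU uses the 1x10 axial layout.
    """
    table = reference_bands(polymer)
    amps = [1.0, 0.7, 0.5]
    bands = tuple(
        SyntheticBand(center=float(c), fwhm=20.0, amplitude=amps[i % 3])
        for i, c in enumerate(sorted(table.centers, reverse=True))
    )
    shape = (10,) if polymer == "PU" else (5, 5)
    return DegradationScenario(
        bands=bands,
        spatial_pattern=spatial_pattern,
        noise_sd=noise_sd,
        grid_shape=shape,
        seed=seed,
        modality="FTIR",
        polymer=polymer,
    )


#: Raman band positions (cm^-1) used for the synthetic polypropylene
#: film: CH2/CH bending (402), CH2 rocking / C-C (812), CH2 rocking
#: reference (844), CH3 rocking (973, 998), C-C st + CH bd (1156),
#: CH2/CH3 bending (1330, 1458) and the C-H stretching cluster
#: (2843-2950).
PP_RAMAN_CENTERS = (402.0, 812.0, 844.0, 973.0, 998.0, 1156.0, 1330.0, 1458.0, 2843.0, 2885.0, 2925.0, 2950.0)


def pp_raman_scenario(noise_sd: float = 1.0, seed: int = 0) -> DegradationScenario:
    """Synthetic polypropylene Raman scenario; reference peak at 844 cm^-1."""
    bands = tuple(SyntheticBand(center=c, fwhm=12.0, amplitude=100.0) for c in PP_RAMAN_CENTERS)
    return DegradationScenario(
        bands=bands,
        noise_sd=noise_sd,
        baseline=(50.0, 0.02),
        grid_shape=(1,),
        seed=seed,
        modality="Raman",
        polymer="PP",
    )


# ---------------------------------------------------------------------------
# film pairs
# ---------------------------------------------------------------------------


def _positions(shape: tuple) -> list[tuple]:
    if len(shape) == 1:
        return [(i,) for i in range(shape[0])]
    return [(r, c) for r in range(shape[0]) for c in range(shape[1])]


def _attenuation_mask(positions: list[tuple], pattern: str, rng: np.random.Generator) -> np.ndarray:
    """Per-position indicator of whether planted attenuation applies."""
    if pattern == "uniform":
        return np.ones(len(positions), dtype=bool)
    if pattern == "fringe":
        rows = [p[0] for p in positions]
        if all(len(p) > 1 for p in positions):
            cols = [p[1] for p in positions]
            rmin, rmax, cmin, cmax = min(rows), max(rows), min(cols), max(cols)
            return np.array(
                [(p[0] in (rmin, rmax)) or (p[1] in (cmin, cmax)) for p in positions], dtype=bool
            )
        rmin, rmax = min(rows), max(rows)
        return np.array([p[0] in (rmin, rmax) for p in positions], dtype=bool)
    # patchy: seeded Bernoulli(1/2) per position, at least one attacked
    mask = rng.random(len(positions)) < 0.5
    if not mask.any():
        mask[rng.integers(len(positions))] = True
    return mask


def _gaussian_profile(grid: np.ndarray, bands, include_new: bool) -> np.ndarray:
    """Matrix of per-band Gaussian profiles, (n_bands, n_points)."""
    prof = []
    for b in bands:
        if b.is_new and not include_new:
            prof.append(np.zeros_like(grid))
            continue
        sigma = b.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        prof.append(b.amplitude * np.exp(-0.5 * ((grid - b.center) / sigma) ** 2))
    return np.vstack(prof) if prof else np.zeros((0, grid.size))


def generate_film_pair(scenario: DegradationScenario):
    """Generate (control SpectrumSet, incubated SpectrumSet, truth dict).

    Each grid position yields one spectrum per set: baseline + sum of
    Gaussian bands + white noise.  Incubated spectra attenuate each
    band by its planted fraction wherever the spatial pattern applies,
    and add any treatment-only bands.  The truth record carries the
    per-position attenuation actually applied to each band and the
    resulting expected mean attenuation.
    """
    rng = np.random.default_rng(scenario.seed)
    grid = np.asarray(scenario.wavenumbers, dtype=float)
    positions = _positions(scenario.grid_shape)
    mask = _attenuation_mask(positions, scenario.spatial_pattern, rng)
    base = scenario.baseline[0] + scenario.baseline[1] * grid
    prof_ctrl = _gaussian_profile(grid, scenario.bands, include_new=False)
    prof_incu_full = _gaussian_profile(grid, scenario.bands, include_new=True)
    atten = np.array([b.attenuation for b in scenario.bands])

    control, incubated = [], []
    applied = np.zeros((len(positions), len(scenario.bands)))
    for i, pos in enumerate(positions):
        y_c = base + prof_ctrl.sum(axis=0) + rng.normal(0.0, scenario.noise_sd, grid.size)
        control.append(
            Spectrum(grid, y_c, modality=scenario.modality, polymer=scenario.polymer,
                     treatment="control", replicate_id="ctrl-1", position=pos)
        )
        factors = 1.0 - (atten if mask[i] else np.zeros_like(atten))
        applied[i] = 1.0 - factors
        y_i = base + (factors[:, None] * prof_incu_full).sum(axis=0)
        y_i += rng.normal(0.0, scenario.noise_sd, grid.size)
        incubated.append(
            Spectrum(grid, y_i, modality=scenario.modality, polymer=scenario.polymer,
                     treatment="incubated", replicate_id="incu-1", position=pos)
        )
    truth = {
        "positions": positions,
        "attenuation_mask": mask,
        "applied_attenuation": applied,
        "band_centers": [b.center for b in scenario.bands],
        "expected_mean_attenuation": applied.mean(axis=0),
        "new_band_centers": [b.center for b in scenario.bands if b.is_new],
        "seed": scenario.seed,
    }
    return SpectrumSet(tuple(control), grid=grid), SpectrumSet(tuple(incubated), grid=grid), truth


def generate_raman_pair(scenario: DegradationScenario, n_accumulations: int = 3):
    """Generate (control SpectrumSet, treated SpectrumSet, truth).

    Each set holds ``n_accumulations`` spectra taken at one position,
    to be averaged with :func:`plastscreen.raman.average_position`.
    Planted attenuations apply to the treated position; ``is_new``
    bands appear in the treated spectra only.
    """
    rng = np.random.default_rng(scenario.seed)
    grid = np.asarray(scenario.wavenumbers, dtype=float)
    base = scenario.baseline[0] + scenario.baseline[1] * grid
    prof_ctrl = _gaussian_profile(grid, scenario.bands, include_new=False)
    prof_treat = _gaussian_profile(grid, scenario.bands, include_new=True)
    factors = 1.0 - np.array([b.attenuation for b in scenario.bands])
    signal_c = base + prof_ctrl.sum(axis=0)
    signal_t = base + (factors[:, None] * prof_treat).sum(axis=0)

    def _acc(signal, treatment):
        return tuple(
            Spectrum(grid, signal + rng.normal(0.0, scenario.noise_sd, grid.size),
                     modality="Raman", polymer=scenario.polymer, treatment=treatment,
                     replicate_id=f"acc-{k+1}")
            for k in range(n_accumulations)
        )

    control = SpectrumSet(_acc(signal_c, "control"), grid=grid)
    treated = SpectrumSet(_acc(signal_t, "incubated"), grid=grid)
    truth = {
        "band_centers": [b.center for b in scenario.bands],
        "attenuation": [b.attenuation for b in scenario.bands],
        "new_band_centers": [b.center for b in scenario.bands if b.is_new],
        "seed": scenario.seed,
    }
    return control, treated, truth


# ---------------------------------------------------------------------------
# respirometry screens
# ---------------------------------------------------------------------------


def generate_respirometry_screen(
    n_strains: int,
    frac_responders: float = 0.0,
    effect: float = 0.5,
    noise_sd: float = 0.1,
    n_reps: int = 3,
    n_blanks: int = 3,
    baseline_co2: float = 1.0,
    blank_co2: float = 0.1,
    nacl_pct: float = 0.0,
    condition: str = "mixed",
    seed: int = 0,
):
    """Simulate a sealed-bottle CO2 screen with planted responders.

    Per strain: ``n_reps`` with-plastic and ``n_reps`` without-plastic
    bottles around a strain-specific basal CO2 level; responder strains
    release ``effect`` additional CO2 (% of gas phase) in the
    with-plastic bottles.  Two blank sets (medium-only and
    medium+plastic, ``n_blanks`` bottles each) emulate the uninoculated
    controls.  Returns ``(samples, truth)`` where truth lists the
    responder strain ids.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates per condition")
    rng = np.random.default_rng(seed)
    samples: list[RespirometrySample] = []
    for kind in ("none", condition):
        for rep in range(n_blanks):
            co2 = max(rng.normal(blank_co2, noise_sd / 2.0), 0.0)
            samples.append(RespirometrySample("", kind, nacl_pct, True, rep + 1, co2))
    n_resp = int(round(frac_responders * n_strains))
    responders = set(rng.choice(n_strains, size=n_resp, replace=False).tolist()) if n_resp else set()
    truth_ids = []
    for i in range(n_strains):
        sid = f"SYN-{i + 1:04d}"
        basal = max(rng.normal(baseline_co2, 0.2), 0.1)
        if i in responders:
            truth_ids.append(sid)
        for cond, bump in (("none", 0.0), (condition, effect if i in responders else 0.0)):
            for rep in range(n_reps):
                co2 = max(rng.normal(basal + blank_co2 + bump, noise_sd), 0.0)
                samples.append(RespirometrySample(sid, cond, nacl_pct, False, rep + 1, co2))
    truth = {"responders": sorted(truth_ids), "effect": effect, "noise_sd": noise_sd, "seed": seed}
    return samples, truth
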