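# Methods

## Respirometric CO₂ screening

Each strain is incubated in sealed serum bottles in triplicate, with
and without plastic, alongside two sets of uninoculated blanks
(medium-only and medium + plastic). CO₂ is expressed as a percent of
the bottle's total gas phase.

**Blank correction.** Plastic-containing bottles are corrected by the
mean of the plastic-containing blanks; plastic-free bottles by the
medium-only blanks. The matching is per NaCl level. Corrected values
may be negative (seal variability over long incubations); they are
flagged, never clipped, because clipping would bias the group means.
The whole screen is invariant to adding a constant to every bottle.

**Test.** Only when the with-plastic mean exceeds the without-plastic
mean is a test run: a one-tailed pooled-variance (Student) *t* with
df = n₁ + n₂ − 2, alternative "with-plastic is larger". Decreases are
recorded but never tested. An unequal-variance (Welch) variant is
available behind a flag. No multiple-testing correction is applied by
default; a Benjamini–Hochberg column can be added to reports. Classes:
`decrease`, `increase_ns`, `increase_p05` (p < 0.05), `increase_p01`
(p < 0.01); the p01 set is by construction a subset of the p05 set.

Degenerate inputs: two constant, equal groups → `decrease` (not
larger); constant groups with a larger with-plastic mean → p reported
as 0 with a `degenerate` flag.

## FTIR-ATR chemometrics

**Working grid.** 400–4000 cm⁻¹ at 4 cm⁻¹ steps (configurable).
Spectra are stored ascending in wavenumber internally; descending
display order is a rendering concern. Off-grid spectra are linearly
interpolated, never extrapolated.

**Standardization.** Each measurement is z-scored over its wavenumber
axis (mean 0, sample SD 1, n − 1 denominator). This makes absorbance
values comparable across measurements and detectors, at a price
discussed under *Blind spots*.

**Second derivative.** Savitzky–Golay, default window 13 points
(≈ 48 cm⁻¹) and polynomial order 2, scaled by the grid step so values
are per cm⁻². The window resolves the 20–50 cm⁻¹ bands of polymer MIR
spectra without amplifying noise. Order-2 smoothing attenuates
narrow features: a sinusoid at 0.05 rad/cm is reproduced ≈ 11 % low at
this window (≈ 0.3 % at order 4). Band *positions* — the quantity the
pipeline consumes — are unaffected by this amplitude bias; narrow
closely-spaced bands may require a smaller window to stay resolved.

**Band detection.** Band centers are local minima of the mean
second-derivative spectrum whose depth exceeds `depth_factor`
(default 5) robust-sigma units, with sigma the normal-consistent MAD
(1.4826 × MAD) of the mean second derivative. Minima closer than
`merge_tol` (default 8 cm⁻¹) merge into the deeper one, greedily from
the deepest down. A packaged reference table of characteristic band
positions and vibration-mode labels for LDPE, PA, PET, PP and PU can
replace detection when the polymer is known.

**Band matrix.** Per measurement and band, the standardized absorbance
at the grid point nearest the center (exact ties break toward the
lower wavenumber); optionally the local maximum within ± `pick_tol`.
The matching raw absorbances are carried alongside for RAD.

**PCA.** Band columns are z-scored across measurements and the band
correlation matrix eigendecomposed. Loadings are eigenvectors scaled
by √eigenvalue, so each loading is the Pearson correlation between
band and component, the conventional |loading| ≥ 0.5 retention cut is
meaningful, and communalities (sums of squared loadings) reach exactly
1 when all components are kept. All components are extracted; the
loading rule — not Kaiser or scree — selects which are considered.
Signs are fixed so the largest-|loading| band is positive per
component, making runs reproducible across eigensolvers. No rotation
by default (varimax behind a flag). Scores are the standardized data
projected on the eigenvectors; their columns are orthogonal.

**Inference.** Scores of each selected component are tested by
one-way ANOVA against the control/incubated grouping (with two groups
F = t²). Components with p < α (default 0.05) are significant. No
correction is applied across components; with k selected components
the familywise null rate is ≈ 1 − 0.95^k, so a single nominally
significant component among several selected ones is weak evidence —
report all p-values and judge accordingly.

**RAD.** For each band with |loading| ≥ 0.5 on a significant
component, RAD(%) = 100 · (mean raw absorbance incubated − control) /
control, over all grid points of the compared replicates. Raw (not
standardized) absorbances are used: the ratio is undefined on
mean-zero standardized data. RAD is invariant to a global rescaling of
both groups and is 0 when the group means are equal.

**Replicate selection.** Among incubated replicates, the one with the
largest integrated SD spectrum (pointwise sample SD across the grid,
summed over wavenumbers, on raw intensities) enters the PCA — the
spatially most heterogeneous film, heterogeneity being the signature
of enzymatic surface attack.

## Raman comparison

Baseline: asymmetric least squares (Whittaker smoother, default
λ = 10⁶, asymmetry p = 0.01, 10 iterations; iterative-polynomial
alternative). The asymmetric weighting tracks the lower noise
envelope, so residuals on signal-free regions sit ≈ 2σ above zero —
irrelevant after normalization but visible in raw residuals. The three
accumulated spectra per position are averaged (noise ÷ √3), then
normalized to the reference peak (located as the local maximum within
± `search_tol` of the nominal shift; normalization is idempotent and
scale-invariant). Peak changes are 100 · (I_treated − I_control) /
I_control at peak-local maxima within ± 8 cm⁻¹ (tolerating small
shifts); peaks whose control intensity is within noise are flagged
unquantifiable rather than dropped. New peaks are treated-spectrum
maxima with prominence > `sigma_mult` (default 3) × σ, σ being
1.4826 × MAD of the first-differenced signal (÷ √2), after light
smoothing and with a ≥ 3-point width requirement that rejects
single-point noise spikes (which exceed 3σ prominence surprisingly
often in white noise).

## Synthetic data

Film pairs: per grid position (5 × 5 default; 1 × 10 axial for PU),
spectrum = linear baseline + Σ Gaussian bands + white noise. Fungal
attack is planted as per-band fractional attenuation applied
uniformly, on the outermost grid ring ("fringe"), or on a seeded
Bernoulli(½) subset of positions ("patchy"). Polymer templates place
bands at the packaged reference wavenumbers with amplitudes cycling
{1.0, 0.7, 0.5} and FWHM 20 cm⁻¹; FTIR noise SD defaults to 0.01
(1 % of the largest amplitude) and the FTIR baseline to zero —
ATR-corrected absorbance spectra are treated as baseline-free.
Raman scenarios use counts-scale amplitudes (100), a sloped baseline,
noise SD 1, and can include treatment-only bands. Respirometry
screens draw a basal CO₂ level per strain (mean 1 % of gas phase) and
add a planted effect (default 0.5 %) to responder strains'
with-plastic bottles; noise SD defaults to 0.1 %. All generators are
pure functions of scenario + seed.

What the generator does **not** emulate: band-shape changes (Gaussian
only; pseudo-Voigt, asymmetry, and shifts are absent), ATR
penetration-depth wavelength dependence, atmospheric CO₂/H₂O lines,
detector drift, cosmic-ray spikes, and fluorescence backgrounds.
Passing recovery tests therefore demonstrates the statistics are
implemented correctly, not that the pipeline is robust to every
instrumental artifact of real spectra.

## Blind spots and limitations

- **Uniform attenuation is invisible to the FTIR chain.** Per-spectrum
  standardization removes any common scale factor, so attenuating
  *every* band by the same fraction leaves the standardized band
  matrix unchanged and no component separates the groups. The method
  detects *relative* compositional change between bands — which is
  what surface-chemistry degradation produces — not uniform signal
  loss.
- **The Raman analogue:** normalizing to a reference peak absorbs any
  global scaling, including a genuine uniform loss of scattering.
- Overlapping bands closer than roughly half the SG window merge into
  one detected center; no curve deconvolution is attempted.
- RAD is undefined for bands whose control mean absorbance is zero and
  unstable for near-zero means.
- With several components tested at α = 0.05 and no correction, the
  familywise false-positive rate across components exceeds α (see
  *Inference*).

## Problem sizes

The test suite and the acceptance script run the full pipeline on
5 × 5 grids (25 measurements per group, 901-point spectra), 200 seeded
repetitions for parameter recovery, 2000 simulations for the null
calibration, and 1401-point Raman spectra — sizes matching the
measurement designs the toolkit emulates while keeping a complete run
in the tens of seconds on one CPU.
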