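# plastscreen

A desk-scale toolkit for screening plastic-degrading fungi. It
implements the statistics of a three-stage screening workflow:

1. **Respirometric CO₂ screening.** Fungi sealed in serum bottles with
   plastic as the only carbon source release CO₂ (measured as a percent
   of the bottle's gas phase) if they mineralise the polymer. The
   toolkit blank-corrects each bottle with the matched uninoculated
   controls, averages biological triplicates, and — only where the
   with-plastic mean exceeds the without-plastic mean — tests the
   increase with a one-tailed pooled-variance Student *t*-test
   (df = n₁ + n₂ − 2), classing each strain as a decrease, a
   non-significant increase, or an increase at p < 0.05 / p < 0.01.

2. **FTIR-ATR chemometrics.** Film surfaces are measured on a grid
   (25 points per replicate; 10 axial points for polyurethane foams).
   Band centers are located as minima of the Savitzky–Golay second
   derivative of the standardized (z-scored) spectra, standardized
   absorbances at those centers form a measurements × bands matrix,
   and PCA on the band correlation matrix groups covarying bands into
   spectral signals. Loadings are scaled by √eigenvalue so a loading
   is a band–component correlation; components with at least one
   |loading| ≥ 0.5 are retained and their scores tested by one-way
   ANOVA against the control/incubated grouping. For every band
   loading highly on a significant component, the relative absorbance
   decrease

   RAD(%) = 100 · (Ā_incubated − Ā_control) / Ā_control

   quantifies the degradation (negative = loss of that bond
   population). The standard-deviation spectrum across the grid serves
   as a spatial-heterogeneity marker and selects which incubated
   replicate enters the PCA.

3. **Raman relative changes.** Spectra from colonized and clean film
   positions are baseline-subtracted (asymmetric least squares),
   averaged per position, normalized to a reference peak the treatment
   leaves intact, and compared peak by peak; treatment-only peaks with
   prominence above a noise-sigma multiple are reported as new peaks.

A seeded synthetic generator produces film pairs (Gaussian bands at
each polymer's characteristic wavenumbers, with planted attenuation in
uniform / fringe / patchy spatial patterns), Raman position pairs, and
respirometry screens with known ground truth, so the entire pipeline is
testable without instrument data.

## Worked example

Generate a synthetic LDPE film pair (20 % attenuation planted on
alternating bands) and analyze it:

```sh
plastscreen simulate --polymer LDPE --attenuation 0.2 --seed 3 --out-dir demo
plastscreen ftir-analyze demo/manifest.csv --out-dir demo/out
```

which prints

```json
{"replicate_selected": "incu-1", "sd_integrals": {"incu-1": 8.884702440901492},
 "n_bands": 5, "selected_components": [1], "significant_components": [1],
 "explained_selected": 0.9438855480037598,
 "rad_pct": {"720": -19.72645278714541, "1376": 0.37123338781465176,
             "1464": -19.853121652416874, "2840": 0.6648432498875156,
             "2916": -20.03655186731159},
 "decreased_bands": [720.0, 1464.0, 2916.0]}
```

Reading it: all five characteristic LDPE bands were re-detected from
the second-derivative spectra (within one 4 cm⁻¹ grid step of the
planted 718/1377/1463/2840/2915 cm⁻¹ centers). One principal
component carries loadings ≥ 0.5, explains 94.4 % of the band
variance, and separates control from incubated measurements
(significant score ANOVA). The three planted bands come back with
RAD ≈ −20 % — the planted attenuation — while the two untouched bands
change by < 1 %.

The same workflow runs on real data: point `ftir-analyze` at a
manifest CSV listing two-column (wavenumber, intensity) spectrum files
with their polymer/treatment/replicate/position metadata. `screen-co2`
and `raman-analyze` cover the other two stages, and every step is also
available as a library function (`plastscreen.FTIRDegradationAnalyzer`,
`plastscreen.screen_batch`, `plastscreen.relative_peak_change`, …).

## Documentation

`docs/methods.md` describes the statistical model, the default
parameters and why they were chosen, what the synthetic generator does
and does not emulate, and the method's known blind spots.
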