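# octgrid

Error assessment for OCT-derived macular thickness maps.

Spectral-domain OCT devices reduce a macular volume scan to a grid of
retinal thickness values (ILM-to-RPE distance) — typically 128 B-scans of
512 A-scans over a nominal 6 mm × 6 mm area — and summarise it as a
nine-segment ETDRS plot (a central 1 mm subfield plus inner/outer annuli of
3 and 6 mm diameter, each split into superior/nasal/inferior/temporal
quadrants). Three preventable artifacts bias those numbers even when
segmentation is perfect:

1. **Undersampling.** Only the retina the beam actually hits contributes
   data: 8 B-scans of 15 µm-spot A-scans sample just 1.8 % of the nominal
   area, and even 128 B-scans sample ~28 %. Thickness between B-scans is
   interpolated (cubic spline along the slow axis), and the interpolation
   error grows as B-scan density falls.
2. **Decentration.** The scan is centered on the subject's fixation locus,
   which is not always the foveal center; an ETDRS grid anchored at the
   volume center is then displaced from the fovea.
3. **Ocular magnification.** Scan mirrors are calibrated to a model eye of
   axial length 24.46 mm; the true scan side length in an eye of axial
   length *L* is `6 · L / 24.46` mm, so uncorrected rings are not really
   1/3/6 mm in diameter.

`octgrid` implements each manipulation as a tested, composable operation
over a `ThicknessMap` container, quantifies every effect as per-segment and
summed absolute ETDRS differences (plus per-pixel error for undersampling),
and ships a synthetic thickness-map generator (foveal pit + optional
drusen + fixation offset + axial-length cohort + noise) so the whole
pipeline runs without any patient data. A Bland–Altman utility
(`bias ± 1.96·SD` limits of agreement) supports validating one thickness
pipeline against another.

## Worked example

Generate a synthetic subject and run every analysis (all values in µm):

```bash
$ octgrid simulate --n 1 --seed 3 --outdir demo
wrote 1 subjects; manifest: demo/manifest.json
```

The seed-3 subject has axial length 26.91 mm (a long eye, ΔAL = 2.45 mm)
and a true fovea at (−0.184, 0.030) mm, i.e. 0.186 mm of decentration.

```bash
$ octgrid recenter --map demo/synth-0000.csv --fovea sidecar
  # dec summed 22.71   csf 5.99    decentration_mm 0.186
$ octgrid rescale --map demo/synth-0000.csv
  # mag summed 35.11   csf 7.55    abs_dAL_mm 2.45
$ octgrid combined --map demo/synth-0000.csv
  # combined summed 44.42   csf 13.54
$ octgrid undersample --map demo/synth-0000.csv --keep 8
  # mean per-pixel error 3.206   csf error 24.32
```

Reading: centering the ETDRS grid on the volume instead of the fovea
shifts the nine segment means by 22.7 µm in total (6.0 µm in the central
subfield alone); ignoring this eye's 2.45 mm axial-length deviation adds
35.1 µm of summed ring-scale error; committing both artifacts at once
costs 44.4 µm. Reconstructing the map from only 8 of its 128 B-scans
leaves a mean interpolation error of 3.2 µm per pixel and a 24.3 µm error
in the central subfield. The raster geometry itself:

```bash
$ octgrid coverage --bscans 8 --full
{
 "bscan_spacing_um": 750.0,
 "covered_fraction": 0.0177241666084619,
 "min_bscans_full_coverage": 641
}
```

— 8 B-scans 750 µm apart sample 1.8 % of the area, and full coverage at
512 A-scans/B-scan with a 15 µm spot would take 641 B-scans.

The same analyses are available as library calls (`octgrid.etdrs_plot`,
`octgrid.interpolation_error`, `octgrid.decentration_error`,
`octgrid.magnification_error`, `octgrid.combined_error`,
`octgrid.covered_area_fraction`, ...), and `octgrid cohort` batches them
over a simulated cohort manifest into tidy per-subject and summary CSVs.

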