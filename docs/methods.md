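# Methods

## Data model and coordinate conventions

A `ThicknessMap` is an `n_rows × n_cols` grid of retinal thickness values
(µm), rows being B-scans along the slow axis and columns A-scans along the
fast axis; the default raster is 128 × 512 = 65,536 pixels over a nominal
6 mm × 6 mm area. Thickness is the ILM-to-RPE distance computed upstream by
the device; segmentation is not modeled. Validation enforces finite values
strictly inside (0, 1000) µm.

All geometry uses volume-centered Cartesian millimetres: +x is image
right, +y is image up, row index increases with +y (row 0 is the
inferior-most B-scan). Pixels are half-open cells and every membership
decision is made at cell centers: center *c* of *n* cells spanning side
*S* sits at `−S/2 + (c + 0.5)·S/n`. Laterality maps nasal retina to +x in
OD and −x in OS; the device's true image orientation is not documented, so
this is a fixed, overridable convention (`nasal_positive_x`).

The scanner is calibrated to a model eye of axial length 24.46 mm. The
physical side length for an eye of axial length *L* is `S = 6·L/24.46` —
a pure linear rescaling of pixel coordinates about the volume center
(thickness values are axial measurements and are never resampled).
Rescaling about the volume center rather than the fovea reflects that the
scan optics, not the anatomy, set the magnification pivot. Axial lengths
are sanity-bounded to (15, 40) mm. Richer three-parameter schematic-eye
corrections are deliberately out of scope; `MagnificationModel` isolates
the formula so one could be slotted in.

On disk a map is a CSV matrix (floats written with shortest round-trip
representation, so write→read is bit-identical) plus a JSON sidecar
(`subject_id`, `eye`, shape, `nominal_size_mm`, `axial_length_mm`,
`fovea_xy_mm`). The proprietary device export format is undocumented; this
open dialect replaces it.

## ETDRS plots

Rings of radius 0.5 / 1.5 / 3.0 mm around an arbitrary center; annuli are
split into quadrants by the ±45° diagonals. Deterministic boundary rules:
radii compare with `≤` on the outer edge of each zone, and diagonal ties
(|dx| = |dy|) belong to the superior/inferior quadrants. Segment means are
unweighted means over member pixels (no partial-area weighting), which
matches grid-sampled data and lets a brute-force scalar classifier
reproduce the vectorized path exactly — the test suite asserts bit-level
agreement of the two routes.

Per-segment *coverage* is the member-pixel count divided by the
analytically expected count (segment area / pixel area) at the same
lateral scale, clamped to 1. Pixel-center discretization makes interior
coverage ≈ 1 only to about 1 %, and any off-center grid placement (or a
short eye after correction) genuinely truncates the 6 mm ring on a 6 mm
scan — coverage flags this rather than resolving it, since how on-device
software handles off-scan ring area is unspecified. A plot whose nine
segments are all empty raises an error; empty individual segments carry a
NaN mean and zero coverage.

Error reports between two plots use absolute per-segment differences,
their nine-segment sum, the central-subfield error separately, and
percentage errors relative to the reference plot.

## Undersampling and spline reconstruction

`subsample_rows` keeps `n_keep ∈ {8, 16, 32, 64}` (or any divisor of the
row count) stride-centered rows: stride `k = n_rows/n_keep`, indices
`k//2 + i·k`. Centering keeps the top/bottom extrapolation bands
symmetric; the phase of retained rows in the original acquisitions is
unknowable, so it is pinned as a design choice. Reconstruction fits each
column independently with a cubic interpolating spline, not-a-knot end
conditions (the common general-purpose default, pinned by a test against
an independent B-spline construction of the same interpolant), and holds
the nearest kept row's value constant beyond the outermost kept rows to
avoid cubic blow-up. The identity selection (all rows kept) short-circuits
to an exact copy, making the full-density error report exactly zero;
elsewhere kept rows reproduce to 1e−9.

The error report treats the native 128-B-scan map as ground truth: the
signed difference map is kept for display, the mean/max absolute per-pixel
error summarise it, and ETDRS entries compare the native and reconstructed
maps plotted at the same (fovea) center. Because the centered kept-row
pattern is not mirror-symmetric in the grid, the signed error over a
pit-symmetric row band cancels only to a few percent of its absolute mass,
not exactly.

## Fovea localisation and decentration

`find_fovea` Gaussian-smooths the grid (σ = 0.1 mm per axis, converted to
pixels at the map's true lateral scale), takes the argmin within the
central 3 mm × 3 mm window (avoiding peripheral/drusen minima; window
configurable), and refines per axis by a quadratic fit through the 3-point
neighbourhood (vertex offset clamped to ±half a pixel). It never fails:
a pit depth (window median − minimum of the smoothed map) under 10 µm
flags low confidence instead, mirroring automatic fovea finders that
break down in severe pathology.

`decentration_error` compares the fovea-centered plot (reference) to the
volume-centered one, both at nominal lateral scale so the centering effect
is isolated from magnification; the fixation point is modeled as the
volume center. `magnification_error` holds the center fixed and compares
true-scale vs nominal-scale plots. `combined_error` compares the fully
corrected plot (fovea-centered, true scale) to the fully uncorrected one
(volume-centered, nominal); the two artifacts can partially cancel, so no
ordering between combined and single-artifact errors is asserted.

## Coverage geometry

Each A-scan samples a disc of the spot diameter (15 µm default). With
A-scan spacing `a = L/n_a` (centers inset by a/2, matching the pixel-cell
convention) a B-scan row's union area is
`n_a·πr² − (n_a−1)·lens(a, r)`, `lens(a,r) = 2r²·acos(a/2r) −
(a/2)·√(4r²−a²)` for `a < 2r`; rows are disjoint whenever row spacing
≥ 2r (always true for clinical rasters), otherwise the rasterization
oracle is used. Discs are not clipped at the scan boundary (the overhang
is < 0.01 pp for a 15 µm spot).

The oracle evaluates exact disc-union membership at raster cell centers:
the A-scan centers form a product lattice, so the nearest-center squared
distance separates per axis, giving an O(n log n) exact membership test
that converges to the analytic value as resolution shrinks (agreement
within 0.2 pp at 1 µm across the 8–128 B-scan sweep; 0.1 pp at 0.5 µm).

Full coverage needs row spacing ≤ the solid-strip width
`2·√(r² − (a/2)²)`, giving 641 B-scans for the default raster. At the
returned minimum the residual gaps one row earlier are sub-0.01 µm
slivers, below any feasible raster resolution, so the oracle verifies
full coverage at the minimum and clear under-coverage well below it,
while the analytic criterion is checked strictly at n−1. A spot equal to
the scan side still needs two rows (the corners sit just outside the
inset end discs); one row suffices only once the strip width reaches the
full side length.

## Synthetic data generator

The phantom thickness surface is radial about the (offset) fovea:

`T(r) = periphery + ring_amp·exp(−(r − ring_radius)²/(2·ring_sigma²))
        − pit_amp·exp(−r²/(2·pit_sigma²))`

with defaults 270 µm periphery, 60 µm rim at 1.2 mm (σ 0.8 mm) and a
110 µm pit (σ 0.35 mm) — giving ≈ 179 µm at the pit bottom and a
realistic central-subfield/peripheral range. This is a geometric, not
anatomical, model: the analyses under test measure grid geometry and
interpolation, not retinal shape.

Per subject the generator samples the profile at pixel centers computed
with the subject's axial length, radius measured from the fixation
offset, then adds optional drusen-like bumps (count ~ Poisson, default
mean 8 in the drusen-dominant phenotype; amplitude 20–120 µm, σ
0.05–0.25 mm, centers ≥ 0.2 mm from the edge to limit extrapolation
confounds) and i.i.d. Gaussian noise (default SD 2 µm). Cohorts draw
axial length from a truncated normal (24.46 ± 1.2 mm on [21, 30.5]), an
isotropic Gaussian fixation offset with per-axis σ = 0.09·√(2/π) mm
(mean magnitude 0.09 mm, typical of fovea-targeted volumes), and ±5 %
multiplicative pit-parameter jitter. Each subject gets an RNG stream
keyed (seed, index), so extending a cohort never changes earlier
subjects; everything is bit-reproducible from the seed. The sidecar
records the true fovea and axial length as ground truth.

What the phantom does *not* emulate: OCT speckle, eye-motion artifacts,
segmentation failures, and real pathological morphology (the drusen field
is a plausible surrogate only). Passing tests therefore demonstrate the
correctness of the geometric/interpolation machinery and the direction
and rough scale of the three error sources on smooth retinas — not
clinical error magnitudes, which depend on each cohort's anatomy.

## Problem sizes and statistical checks

Property and trend tests use a 100-subject noise-2 µm cohort (fixation σ
0.25 mm, axial σ 1.2 mm) for the monotone-trend checks — cohort-mean
per-pixel interpolation error strictly decreasing over 8→16→32→64 kept
B-scans, and positive Spearman correlations of summed ETDRS error with
decentration and with |ΔAL| — and 500-subject draws for distributional
checks (mean/SD within 3 standard errors; scan-length deviation fraction
monotone in axial SD). Fovea recovery is checked over 50 seeded subjects:
within one slow-axis pixel (0.047 mm) noiseless, within 0.1 mm at 2 µm
noise. The Bland–Altman limits use the large-sample 1.96 multiplier.
Cohort threshold counts default to 20 µm of summed ETDRS error.

## Known limitations

- The device's row/column orientation relative to superior/inferior, and
  the retained-row phase and spline end conditions of on-device
  undersampling, are undocumented; each is pinned here as an explicit
  convention rather than inferred.
- Linear axial-length scaling is the only magnification model.
- The analytic coverage model treats the beam as a hard disc; Gaussian
  beam profiles and axial (depth) sampling are out of scope.
- Real-cohort error statistics are not reproducible from synthetic
  cohorts; only directions, orderings and geometry-level constants are
  asserted.
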