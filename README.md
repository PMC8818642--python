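# nanometrics

Quantitative analysis of nanoscale imaging readouts from muscle-cell
biology: single-molecule localization microscopy (dSTORM) of the actin
cytoskeleton, AFM elasticity mapping, and myotube differentiation assays.
The package is aimed at microscopists and image analysts who have per-event
localization tables, force-distance curves, or labeled segmentation masks
and want reproducible, scriptable numbers out of them.

## What it computes

**Cortical actin bundle width (FWHM) with precision deconvolution.**
From raw localizations (x, y, frame, precision σᵢ in nm): events with
σᵢ < 40 nm are accepted, the bundle orientation is fitted by total least
squares, a Gaussian-kernel (σ = 40–80 nm) density map is built in the
rotated frame, a polynomial centerline is fitted along the per-column
density maxima, and each event's signed perpendicular distance to the curve
is histogrammed and fitted with a single Gaussian (σ_meas).  Because the
observed profile is the true cross-section convolved with the Gaussian
localization error, the precision is removed in quadrature,

    σ_corr = sqrt(σ_meas² − σ_prec²),   σ_prec = RMS(σᵢ),
    FWHM = 2·sqrt(2·ln 2)·σ,

with the fluorophore linker length fixed at 0 nm (phalloidin).

**Blind drift correction.**  Frames are split into equal-count temporal
bins, each bin is rendered at 20 nm/px, and bin-to-reference image
cross-correlation (sub-pixel parabolic peak refinement) gives per-bin
shifts, interpolated per frame and subtracted.

**Actin network skeleton metrics.**  Rendered images are binarized (Otsu's
between-class-variance criterion, or a manual threshold), homogenized with
a 2-D Gaussian of 3–4 px (60–80 nm) and re-binarized, thinned to a 1-px
skeleton, and decomposed into branches terminated by endpoints and
junctions.  Branches shorter than 120 nm are pruned.  Reported: branch
count, per-branch geodesic length (axial step = px, diagonal = √2·px),
mean branch length, and the normalized branch number = branch pixels /
all skeleton pixels.

**AFM elasticity.**  Force–indentation curves are fitted with the Hertz
model for a sharp indenter, F = C·E/(1−ν²)·δ², with C = (2/π)·tan α for a
cone (default α = 35°, ν = 0.5) or 0.7453·tan α for a four-sided pyramid;
the contact point and baseline are found by grid search and the fit is
capped at 0.5 nN.  Grids of curves become elasticity maps and modulus
probability histograms.

**Myotube indices.**  From nuclei + desmin label masks: differentiation
index = desmin-positive cells / total nuclei; fusion index = nuclei in
desmin-positive myotubes (≥ 2 nuclei) / total nuclei; nuclei-per-myotube
histogram over {2, 3–5, >5}; per-myotube area and skeleton-path length.

Every stage has a seeded synthetic-scene generator with recorded ground
truth (`nanometrics.synthetic`), so the whole pipeline is testable without
any microscope data.

## Worked example

```python
from nanometrics.synthetic import BundleSpec, simulate_bundle_localizations
from nanometrics.loc_io import filter_by_precision
from nanometrics.bundle_width import measure_bundle_width

spec = BundleSpec(sigma_true_nm=30.0, seed=42)   # true FWHM = 70.6 nm
table, truth = simulate_bundle_localizations(spec)
table = filter_by_precision(table, 40.0)
m = measure_bundle_width(table)
print(f"FWHM measured : {m.fwhm_meas_nm:.1f} nm")
print(f"FWHM corrected: {m.fwhm_corr_nm:.1f} nm")
```

prints

```
FWHM measured : 79.7 nm
FWHM corrected: 70.4 nm
```

The measured 79.7 nm is the true 70.6 nm bundle width broadened by the
~16 nm RMS localization precision (quadrature: 2.355·√(30² + 15.9²) ≈
80 nm); the deconvolution recovers the true width to within 0.3 nm.

The same operations are available from the shell:

```bash
nanometrics locio filter --max-precision 40 in.csv filtered.csv
nanometrics width --out width.json filtered.csv
nanometrics skeleton --out metrics.json render.tif
nanometrics afm --geometry cone --alpha 35 --out afm.json curve.txt
nanometrics myotube --nuclei n.tif --desmin d.tif --out idx.json
```

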