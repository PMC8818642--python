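# Methods

This note records the models, parameter choices and numerical decisions
behind each analysis stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Coordinate and image conventions

All coordinates are continuous nanometers with the origin at the image
lower-left corner and y increasing with row index.  A rendered pixel
(r, c) covers the half-open square [x₀+c·p, x₀+(c+1)·p) × [y₀+r·p,
y₀+(r+1)·p); an event exactly on a bin edge belongs to the higher-index
pixel (deterministic tie-break).  The default render pixel is p = 20 nm,
chosen so that the 60–80 nm homogenization kernel used before
skeletonization corresponds to a standard deviation of 3–4 pixels.

## Localization tables and filtering

Localization events carry (frame, x, y, precision) with the per-event
precision being the standard deviation of the position estimate.  The
acceptance filter keeps events with precision strictly below 40 nm, the
conventional quality cut for dSTORM data.  Rows with non-finite
coordinates are dropped on read and counted; unknown CSV columns are
carried through untouched.

## Bundle width measurement

The measured cross-section of a filament bundle is modeled as the true
Gaussian profile (SD σ_true) convolved with each event's Gaussian
localization error, so widths add in quadrature and the precision can be
removed by σ_corr = √(σ_meas² − σ_prec²), with σ_prec the RMS of the
contributing events' precisions (a mean-based aggregate is available as an
option).  The linker term is fixed at 0 nm, appropriate for the small
phalloidin label.  Widths are reported as FWHM = 2√(2 ln 2)·σ.  If
σ_prec ≥ σ_meas the structure is narrower than the resolution and the
measurement raises an unresolvable-width error rather than reporting 0.

Stage choices:

- **Orientation** — first principal direction of the centered coordinates
  (total least squares), reported in (−π/2, π/2]; a near-isotropic cloud
  (principal SD ratio < 2) logs a warning.
- **Density map** — events binned at a 10 nm grid pitch and convolved with
  a Gaussian kernel; this equals a direct KDE up to sub-pitch quantization
  and is far cheaper.  Kernel σ defaults to 60 nm and must stay in
  [40, 80] nm unless explicitly overridden; use larger σ for sparser
  data.  "Kernel size" is read as the Gaussian σ.  The grid is padded by
  4σ so mass is conserved to <1%.
- **Centerline** — per x'-column ridge positions from a parabolic
  sub-cell interpolation of the column maximum (an argmax-centered
  centroid window was tried first and carries a bias of up to half a grid
  cell, which the parabola removes); columns below 10% of the global
  density maximum are ignored; the polynomial (default cubic, degrees 1–5
  supported) is fitted with per-column weights √(peak density), so sparse
  edge columns count less.  A map with no y'-variation raises a no-ridge
  error.
- **Distances** — nearest point on the polynomial by dense sampling
  (2 samples/nm) plus 8 Newton iterations on the squared distance,
  accurate to well under 0.1 nm; events whose nearest parameter clips the
  domain boundary are dropped and counted.  Distances are signed (left of
  the increasing-x' tangent positive) and the Gaussian fit center is left
  free, so a biased centerline appears as a shifted, not broadened, fit.
- **Profile fit** — 5 nm histogram bins, least-squares single Gaussian
  (optional constant baseline for high background, off by default since
  the standard profile model is a single Gaussian); a binless sample-SD of
  the ±3σ core is reported as a cross-check diagnostic.

## Blind drift correction

"Blind" means no fiducial markers: the structure itself is the reference.
Frames are split into n contiguous bins of equal event count (robust to
uneven blinking density); each bin is rendered over the common bounding
box, lightly smoothed (σ = 1 px), and cross-correlated against the first
bin.  The integer peak is refined by a 1-D parabolic fit in each axis of
its 3×3 neighborhood; ties between equal peaks break toward the smaller
shift magnitude.  Per-frame shifts interpolate linearly between bin-center
frames and are constant beyond the ends.  Within-bin drift is averaged
away by construction, so the residual scales with (total drift)/n; ten
bins on a 100 nm linear drift leave a few nm RMS.  The estimate is
against a fixed reference bin (the first), not pairwise-sequential.

## Skeletonization and branch metrics

Binarization uses Otsu's criterion, implemented in-package as the
exhaustive between-class-variance maximization over a 256-bin histogram
(an optional scalar gain on the threshold, default 1.0, is exposed).  The
homogenization pass Gaussian-filters the binary mask with σ = 3–4 px and
re-thresholds; it exists to bridge gaps between isolated localization
pixels and is unnecessary for already-solid masks (`smooth=False`).

Thinning uses the standard topology-preserving algorithm
(scikit-image).  Branch points are classified by the Rutovitz crossing
number (number of connected neighbor runs around the 8-neighborhood ring),
which — unlike the raw neighbor count — is not inflated by diagonal
contacts between the arms of a crossing; pixels with ≥3 neighbors inside a
2×2 skeleton block are also marked, catching the junction clumps thinning
occasionally leaves (a 1-px-wide path never contains a 2×2 block).
Removing junction pixels leaves interior chains; each chain, re-attached
to the junction cluster(s) it touches, is one branch.  Diagonal
adjacencies whose two pixels share an axial skeleton neighbor are treated
as redundant shortcuts and ignored during chain tracing.  Geodesic branch
length sums axial steps of p and diagonal steps of √2·p.  Pruning removes
endpoint-terminated branches shorter than 120 nm pixel-wise and iterates
until stable (a junction losing its last spur merges its remaining
branches); junction–junction segments below threshold are dropped from
the accounting without breaking connectivity.

The normalized branch number is branch pixels / all skeleton pixels
(junction pixels excluded from the numerator), hence exactly 1 for
junction-free skeletons and < 1 otherwise.  Branch counts are reported
raw and per µm² of image area.

Digitization limits length accuracy: a straight digital line's 8-connected
geodesic exceeds the Euclidean length by up to ~8.2% (worst at 22.5°), and
ribbon ends erode by about half the ribbon width under thinning.  For
420 nm branches this bounds the per-branch error at roughly ±(30–50) nm;
a small percentage of branches at unfavorable angles exceed a
(1+√2)-pixel band even in ideal rasterizations.

## AFM elasticity

Hertz model for a sharp indenter: F = C·E/(1−ν²)·(δ−δ₀)², with
C = (2/π)·tan α for a cone (Sneddon) and 0.7453·tan α for a four-sided
pyramid (Bilodeau).  The cone with α = 35° is the default — "V-shaped"
cantilever tips are commonly approximated either way, so both are
provided — and ν = 0.5 treats the cell as incompressible.  Units: nm, nN,
Pa.

The contact point δ₀ and force baseline are found by a grid search over
candidate split samples, fitting a flat baseline before and a quadratic
after, minimizing total squared residual; a flat-noise curve (post-contact
rise under 3× the baseline scatter) is rejected.  The final fit refines
(E, δ₀, baseline) jointly, keeping the pre-contact samples in the fit to
anchor the baseline.  The ≤0.5 nN window is applied to the
model-predicted force rather than the noisy measured force: selecting on
measured force preferentially discards upward noise near the cap and
biases E low by ~2% at 5% noise.  Spring-constant calibration is
instrument-side; k (N/m) is an input for raw z/deflection curves, with
F[nN] = k·d[nm] and position z − d.  Elasticity maps hold NaN for failed
fits, excluded from the modulus probability histogram (probabilities sum
to 1).

## Myotube indices

A nucleus belongs to the desmin object containing its centroid (the
counting rule of manual analyses is unstated, so centroid containment is
the implemented default).  Desmin-positive objects are connected labeled
regions, mono- or multinucleated; objects with ≥ 2 assigned nuclei are
myotubes.  Differentiation index = desmin-positive objects / total nuclei;
fusion index = nuclei inside myotubes / total nuclei (objects below 2
nuclei count toward the differentiation index but not the fusion
numerator).  The nuclei-per-myotube histogram uses categories {2, 3–5,
>5}.  Myotube "length" is the longest geodesic path through the object's
skeleton; the ellipse major-axis length is reported alongside since the
field uses both.

## Synthetic scenes: what they emulate, and what they do not

- **Bundles** — events uniform in arc length along a polynomial
  centerline, perpendicular offset N(0, σ_true), plus an isotropic
  Gaussian error with that event's recorded precision, drawn from a
  positive-truncated normal (mean 15 nm, SD 5 nm by default); uniform
  background (50 events/µm² default; the distribution of real background
  is unknown, uniform is an assumption); frames uniform over 30,000
  (within the typical 20,000–50,000-frame acquisition range); default
  density 3,000 events per µm of centerline.  No blinking kinetics,
  bleaching, PSF structure or camera noise — so passing recovery tests
  demonstrates correctness of the estimator under the stated noise model,
  not robustness to photophysical artifacts.
- **Networks** — random planar trees rasterized as ribbons.  Geometry
  defaults (edges 220–420 nm, width 40 nm = 2 px, junction angles ≥ 70°,
  140 nm clearance, growth that leaves no persistent degree-2 node) are
  set so that junction displacement (≈ (w/2)/sin(θ/2)) and end erosion
  stay within the digitization error budget above — i.e. the scenes are
  resolvable by design; real actin networks contain unresolvable geometry
  that no skeleton metric recovers exactly.  Ground truth records branch
  count after merging pass-through nodes and per-branch polyline length.
- **Drift** — per-frame (dx, dy) added by frame index; closed-loop tests
  use two crossing bundles because a single straight bundle leaves the
  along-axis shift unconstrained in the correlation.
- **Force curves** — the Hertz forward model plus additive Gaussian force
  noise, truncated at 0.5 nN, with a flat pre-contact baseline; no
  adhesion, viscoelasticity or tilt.
- **Myotube masks** — deterministic row layout of rectangular myotubes,
  square mononucleated cells and loose nuclei with seeded horizontal
  jitter; non-overlap by construction.  Index ground truth is pure
  arithmetic, so recovery is expected to be exact.

All generators are bitwise-deterministic given their spec + seed.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use: a 4×4 (σ_true, σ_prec)
grid × 20 seeds at ≥ 5,000 events/bundle for width recovery; 12 bundles
per population for the 1.5× width-ratio comparison; ~10⁵ events /
20,000 frames for the drift closed loop; 200 random 8-bit images for the
Otsu oracle; 100 random 12-edge networks for topology recovery; 4
noiseless + 200 noisy curves for Hertz recovery.  These sizes give
stable statistics (estimates vary by well under the test tolerances
across seeds) while keeping a full run in seconds.

## Known limitations

- Width measurement assumes one bundle per ROI and Gaussian cross-
  sections; multi-modal profiles need manual ROI splitting.
- Drift correction is lateral (x, y) only and assumes the structure is
  static over the acquisition.
- Skeleton metrics operate on rendered images, not raw localizations;
  sub-pixel filament geometry is quantized at the render pixel.
- The Hertz fit ignores finite sample thickness (bottom effect), adhesion
  and viscoelastic relaxation; moduli from thin cell regions are
  overestimates.
- Nucleus assignment by centroid can mis-assign nuclei lying across
  object boundaries; a majority-overlap option would differ on such
  cases.
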