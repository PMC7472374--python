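# Methods

## The correction model

Close-up, zoomed mobile-phone images of the skin carry *positive-
displacement pincushion distortion*: observed points are pulled radially
inward toward the principal point, with the displacement growing from
zero at the center to several pixels at the left/right borders.  For
stereo photogrammetry of the skin surface this is fatal — disparities of
a fraction of a pixel encode tens of micrometres of depth, so a border
displacement of a few pixels corrupts the reconstructed topography far
more than it disturbs the visual impression.

The package corrects this distortion per pixel.  Writing points relative
to the principal point, which is taken to be the image center
(`xc = width/2`, `yc = height/2`), each calibration correspondence
between an ideal point at radius `ru` and its distorted observation at
radius `rd` yields a distortion ratio

    R = ru / rd            (R ≥ 1 for pincushion, R(0) = 1).

A reduced single-coefficient division model absorbs the ratio into

    k = (1 − R) / rd²,

and the per-pixel correction coefficient λ is the root, continuous at
zero, of

    k·ru²·λ² + λ − 1 = 0,   i.e.  λ = (−1 + √(1 + 4k·ru²)) / (2k·ru²).

The Distortion Correction Matrix (DCM) stores R, k and λ at every pixel;
correction relocates a distorted pixel radially:

    (xn, yn) = λ·(xd − xc, yd − yc) + (xc, yc) ≈ (xu, yu).

Because correspondences exist only at measured calibration points, R is
interpolated over the distorted radius by an even polynomial with no
constant term (R − 1 = c₁rd² [+ c₂rd⁴ …]), fitted by least squares
*separately for the left and right image halves* — real lenses distort
the two halves unequally, and the halves of this model are fully
independent.  Half membership is the sign of x − xc, with the midline
assigned to the left half.  At correction time the ideal radius is
unknown and is taken as ru = R(rd)·rd, which collapses the product
k·ru² to (1 − R)·R², evaluated directly to avoid cancellation; the
limit λ = 1 is returned when |k·ru²| < 1e−12.

**Accuracy of λ.**  Expanding the root gives λ = R + 4(R−1)² + O((R−1)³):
the relocation overshoots the ideal radius by ≈ 4(R−1)²·rd pixels.  For
fine distortion (R − 1 of a few 1e−3) this is below 0.05 px; at the
reference magnitude used here (R − 1 up to 0.0275 at the border) it
reaches ~1.2 px and is the dominant term of the corrected residuals.
This is a property of the reduced model itself, not of its
implementation, and it is what limits the quantitative depth-staircase
recovery below.

## The synthetic stereo rig

Ground truth comes from a simulated non-convergence stereo acquisition:
a pinhole camera (focal length f = 5.6 mm, pixel pitch 3.5 µm, so
f = 1600 px; 800×600 frames) photographs a planar target at working
distances z = 60…80 mm in 5 mm steps, then translates laterally by the
b = 10 mm baseline for the second exposure.  At z = 60 mm the field of
view spans 30 mm of object plane (26.67 px/mm), emulating a 2.0×-zoomed
close-up; the horizontal angle of view is 2·atan(400/1600) = 28.07°.

The lens applies the full two-coefficient division model as the
*forward* ground truth,

    (xu, yu) = (xd, yd) / (1 + λ₁rd² + λ₂rd⁴),

with separate (λ₁, λ₂) per image half and all coefficients negative
(inward displacement).  The ideal→distorted direction has no closed
form and is inverted by bisection on the radius (monotone map; bracket
refined 90 times, residual checked against 1e−10).  Distorted images
are rendered *exactly*: the target's intensity profile is analytic (unit
background minus unit-depth Gaussians of σ = 1.2 px at the line
centers), and each distorted pixel evaluates that profile at its
closed-form undistorted coordinate — no resampling blur anywhere.

The reference lens coefficients (λ₁ᴸ = −1.1453e−7, λ₂ᴸ = −1.0737e−13,
right half 1.35× stronger) are fixed so that the five-distance protocol
produces maximum corresponding-line distances of 0.240 mm at z = 60 mm
rising monotonically to 0.318 mm at z = 80 mm — the magnitude range
reported for real zoomed phone optics.  In object-plane millimetres the
distortion of a fixed pixel-space lens scales with z, which is why the
maximum grows with working distance even though the pixel geometry is
unchanged.

### Targets

* **Vertical line pattern** — dark Gaussian-profile lines at 1 mm
  object-plane intervals, symmetric about the sheet center, sheet wide
  enough to fill both views at every distance.  In the stereo protocol
  the sheet is laterally offset by *half a line spacing* (0.5 mm) from
  the reference optical axis: with a 30 mm field of view and a 10 mm
  baseline an axis-aligned grid puts lines exactly on the shared
  field-of-view edges, while the half-spacing offset leaves exactly 20
  cleanly shared lines at every working distance.
* **Scalar bar** — the same grid with 20 lines whose heights step
  toward the camera by 50 µm per line (line i at depth i × 50 µm; total
  span 1 mm above the reference plane).  The bar is centered midway
  between the two camera stations so both views keep all 20 lines in
  frame; a 4 px visibility margin accommodates the slight outward
  magnification of the deepest lines.

## Pipeline

1. **Calibrate** (`calibrate_from_images`): detect lines in the ideal
   rendering over the full height and in 21 horizontal bands of the
   distorted image (one (x, y) observation per line per band, counts
   must agree).  A vertical line fixes only the ideal x-coordinate Xu;
   under a radial model the corresponding ideal point of an observation
   (xd, yd) is collinear with the center, so yu = Xu·yd/xd and
   R = Xu/xd exactly.  Observations within 5 px of the vertical midline
   are dropped (ill-conditioned quotient).  The ratio field is fitted
   with degree 4 in the standard protocol and the DCM built over the
   full grid.  Calibration is done once, from the reference view at the
   shortest distance, and the same matrix is applied at every distance
   (one lens, one matrix).
2. **Correct** (`warp.correct_image`): forward-splat every source pixel
   to the nearest integer cell of its relocated position.  Collisions
   keep the source with the smaller distorted radius (less-distorted
   information), ties resolved in row-major order; output is
   bit-reproducible.  Unhit in-bounds cells form the hole mask; holes
   are filled from the Euclidean-nearest donor cell
   (`scipy.ndimage.distance_transform_edt`; among exactly equidistant
   donors the transform's deterministic internal choice applies).
3. **Match** (`linematch`): subpixel line centers from
   intensity-weighted centroids of column-mean profiles (±5 px windows
   around `scipy.signal.find_peaks` minima), computed on a central band
   of 60 rows so the measured positions reflect the on-axis geometry
   that the disparity model assumes.  On corrected images the column
   means use only cells that received a real source pixel — filled hole
   cells are copies, not measurements, and would bias the centroids.
   Corresponding lines are paired by the integer index offset whose
   median distance best matches the expected disparity b·f/z, the series
   is anchored on the first shared line (d₁ = 0, so an anchor error
   propagates, as it does in the real protocol), and the average
   correction rate is computed literally as
   mean((dd − dc)/dd)·100 over lines with |dd| > 1e−6 mm.
4. **Regress** (`regress.fit_linear`): ordinary least squares of
   working distance on the per-distance maximum line distance, with R²
   and the two-sided slope t-test (n − 2 df), via
   `scipy.stats.linregress`.  Predicting distortion from geometry is
   the physically natural direction, but the distance-on-ratio
   orientation is the convention of the protocol and is the default.
   Note on units: with the maxima expressed in object-plane mm the
   five-point reference table gives slope 141.13 and intercept 26.25;
   a slope of ~6.9 arises only if the ratio is expressed in units ~20×
   larger (i.e. pixels at ~20 px/mm), so reports produced here always
   state mm.
5. **Depth staircase** (`run_scalar_bar_experiment`): line positions
   are detected in the distorted images and corrected *as coordinates*
   through the matrix (the DCM is a point map; re-detecting on splatted
   images would add ±0.5 px quantisation to a 0.22 px/step disparity
   signal).  Per-line depths follow from dz = z − b·f/d with d the raw
   corrected disparity.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `working_distance_mm` | 60–80, 5 mm steps | camera–object distance; sets px/mm = 1600/z |
| `baseline_mm` | 10 | lateral translation between the stereo exposures |
| `focal_mm`, `pixel_pitch_mm` | 5.6, 0.0035 | pinhole focal model (f = 1600 px) |
| `spacing_mm` | 1.0 | line interval of the calibration grid |
| `line_sigma_px` | 1.2 | Gaussian cross-section of a rendered line; ≥4σ separation enforced |
| `degree` | 4 (protocol), 2 (fit default) | even radial polynomial degree of R − 1 |
| `n_bands` | 21 | calibration bands; sets the y-coverage of correspondences |
| `n_lines` | 20 | corresponding lines matched per stereo pair |
| `depth_step_mm` | 0.05 | scalar-bar height step per line |
| `noise_sigma` | 0 | optional additive intensity noise (seeded) |

## What the simulation does and does not emulate

The simulator reproduces the geometry of the acquisition — pinhole
projection, baseline translation, per-half division-model pincushion
distortion, depth-dependent disparity — with analytically exact
rendering and no photometric effects.  It does **not** model sensor
noise (available but off by default), defocus or motion blur,
vignetting, illumination gradients, skin texture, decentering or
thin-prism distortion, or imperfect principal-point location.  Passing
tests therefore demonstrate the correctness and the intrinsic accuracy
limits of the *method* under ideal measurement conditions; on real
images, detection noise and model mismatch will add to every residual
reported here.

## Numerical choices

* Pixel coordinates are 0-based, x rightward, y downward; a pixel's
  center is at its integer index.  Lengths are mm at module boundaries
  and px inside the math core.
* The radial bisection tolerance is 1e−10; the λ quadratic is
  considered degenerate below |k·ru²| = 1e−12; ratio-field evaluation
  clamps beyond the largest fitted radius (with a warning) so corner
  pixels outside the calibrated annulus reuse the boundary value.
* Grayscale conversion of color input uses ITU-R BT.601 luma weights;
  images are written as 16-bit PNG.
* Eq-rate exclusion threshold: lines with |dd| ≤ 1e−6 mm (in practice
  only the anchored first line) are excluded from the correction rate.

## Known limitations

* **λ overshoot.**  The corrected residual grows as ≈ 4(R−1)²·rd; at
  the reference magnitude this is ~0.02–0.06 mm of residual line
  distance (comfortably below 0.1 mm) but the *average correction rate
  exceeds 100%* (102–120%) because many residuals flip sign.  Rates in
  the 80–90% range arise only when measurement noise dominates the
  residual, as it does on real images.
* **Hole fraction.**  Forward splatting necessarily leaves at least as
  many in-bounds holes as source pixels are pushed out of frame —
  approximately border displacement × perimeter / area.  At the
  reference magnitude (8–11 px border displacement) that is ~5% of
  pixels; sub-percent hole fractions occur only for sub-pixel border
  displacements.  Hole counts are reported, never assumed.
* **Depth-staircase resolution.**  The 50 µm step produces a disparity
  increment of b·f·Δz/z² ≈ 0.22 px at z = 60 mm, while the λ-overshoot
  gradient between adjacent border lines reaches ~0.18 px.  The
  corrected staircase is strictly monotone at the reference magnitude,
  but individual step sizes and the recovered 1 mm span are biased by
  up to ~13% / ~26% there; quantitative step recovery within 10% needs
  roughly one order of magnitude finer distortion (verified in the
  fine-distortion property tests at one tenth of the reference lens).
* The correction is purely radial about a fixed center; decentering,
  tangential terms and principal-point estimation are out of scope.
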