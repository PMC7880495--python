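# Methods

`scintdose` reconstructs time-resolved 2D absorbed-dose distributions from
video of a flat scintillator sheet filmed by a tilted, mirrorless camera, and
provides the QA metrics used to validate such a detector.  This note records
the models, the numerical choices, and what the synthetic test bench does and
does not establish.

## Measurement model

A scintillator sheet lies in the plane z = 0 (world coordinates in mm, the
isocenter at the origin).  Its light output is proportional to the local
absorbed dose.  A pinhole camera with Brown lens distortion (two radial
terms k1, k2 and two tangential terms p1, p2) views the sheet from the side
at an angle.  The recorded brightness of a scintillator point deviates from
proportionality to dose through, in order:

1. **perspective and lens distortion** — the plane is imaged obliquely;
2. **inverse-square falloff** — brightness scales as (d0/d)² with d the
   point-to-lens distance and d0 a reference distance (the camera-isocenter
   distance unless configured otherwise);
3. **scintillator inhomogeneity** — a smooth multiplicative field from the
   non-uniform phosphor coating;
4. **channel split** — the green phosphor emission distributes over the RGB
   channels in fixed proportions (defaults 10.5 / 51.5 / 38.0 %);
5. **optics blur** — a Gaussian point-spread function on the sensor;
6. **noise** — Poisson shot noise, Gaussian read noise (clipped at zero),
   and transient hot pixels: scattered photons striking the sensor directly,
   producing single-pixel saturations lasting one frame (configurable to
   two).

The reconstruction chain inverts these effects step by step, in a fixed
order: RGB → grayscale (equal 1:1:1 channel weights, preserving each
channel's contribution) → beam-segment detection → frame-based noise
reduction (FBNR) → per-segment accumulation → rectification onto a physical
grid → multiplicative flat-field correction → linear dose calibration →
optional learned penumbra/backscatter correction.

## Segment detection

Step-and-shoot deliveries pause the beam between segments.  A frame is
classified beam-on when its mean intensity reaches a configurable fraction
(default 0.05) of the maximum per-frame mean of the stack; maximal runs
shorter than `min_frames` (default 3) are discarded.  The rule is invariant
to uniform intensity rescaling.  Two caveats are inherent to it: a stack
containing only background yields one spurious run (only the all-zero stack
is guaranteed empty), and the threshold must clear the background pedestal
(background light plus clipped read noise plus the hot-pixel contribution to
the frame mean).  The synthetic bench uses 0.3, which separates its weakest
calibration acquisition from the pedestal by a wide margin; the softer
default of 0.05 is retained in the library API for darker acquisitions.

## Frame-based noise reduction

For frame n and pixel (x, y) strictly above the activity level, the filter
counts active frames in the forward window [n, n+k]; if fewer than
`threshold` are active, the pixel is zeroed in frame n (transient → hot
pixel), otherwise kept (persistent → scintillation).  Defaults k = 5,
threshold = 3.  Windows truncated by the stack end scale the threshold by
the actual/nominal window-length ratio rather than fabricating frames.

Three consequences of the forward window are worth recording:

- The comparison is strictly greater than the activity level, so the default
  level 0 means "any positive intensity counts".  A greater-or-equal rule at
  level 0 would count zero pixels as present and keep every hot pixel.
- The trailing `threshold − 1` frames of a beam segment embedded in a longer
  video fail persistence by construction.  For clinical-length segments
  (hundreds of frames) the loss is negligible; at desk scale it is material,
  so the pipeline filters each detected segment as its own sub-stack, where
  the end-truncation rescues the trailing frames.  The price is that hot
  pixels arriving in a segment's final two frames are kept.
- The activity level must sit above the noise pedestal for the filter to act
  at all; the bench uses 30 brightness units (far below any beam-on signal,
  far above background ≈ 0.2 plus noise tails).

## Geometric calibration and rectification

A chessboard with 22.0 mm squares placed at the scintillator position (plus
optional extra tilted views) is rendered/photographed.  Lens calibration is
a planar bundle adjustment: intrinsics (fx, fy, cx, cy), distortion
(k1, k2, p1, p2) and one 6-dof pose per view are refined jointly by
Levenberg-style least squares on the corner reprojection error, initialized
from the board homography decomposition.  The sensor-to-plane homography is
then estimated (normalized DLT) from the undistorted corners of the
reference view.  Corners come either from the generator's ground truth
(test mode) or from a Harris-based detector with sub-pixel refinement and
grid ordering (production mode); the detector assumes the board interior is
fully visible and moderately tilted.

Rectification maps each output-grid point through the inverse homography and
the forward distortion model and samples the raw frame bilinearly — one
resampling pass for both corrections.  The default output grid is 176 mm
over 2048 px, pitch 176/2048 = 0.0859375 mm (0.086 mm at three decimals);
the bench uses 256 px (pitch 0.6875 mm) to keep the suite fast.  Out-of-view
grid points are zeroed and flagged in a validity mask.

## Brightness corrections and dose calibration

The 2D correction map is built from a 20 × 20 cm² open-field acquisition:
the rectified flat-field is normalized to its isocenter value — the mean of
a 5 × 5 px central patch, for noise robustness — and inverted elementwise.
A final exact renormalization by the map's own center pixel makes the map
exactly unity at the isocenter (the patch mean gets it there up to noise;
without this step the stated unity invariant would only hold approximately).
Pixels below 20% of the isocenter value are outside the open field and are
masked (map value 1).  If a trusted reference profile of the open field is
supplied, the map becomes reference/flat-field so the beam's own
non-flatness is not imprinted; by default the open field is treated as flat
(the residual error is bounded by its flatness, ~1–2%).  Optional Gaussian
smoothing (bench: σ = 1 px) is applied before inversion so the map does not
inject its own shot noise into later measurements.

Dose calibration is ordinary least squares with a free intercept on
(corrected central brightness, dose) pairs spanning 20–200 cGy; R² and RMSE
are reported.  Conversion clips negative doses at zero.  Output factors
normalize central doses per field size to the 10 × 10 cm² field.

Brightness corrections are applied to the accumulated plane rather than per
frame: all operations involved are linear, so they commute with the
per-frame sum, and one rectification per segment is far cheaper.

## Penumbra / backscatter deconvolution

Measured planes M(x, y) differ from true planes D(x, y) through optical
blur, residual flat-field error and a ~2.5% global deficit from the missing
backscatter under the sheet.  A small convolutional network C = f(M) —
default three 3 × 3 convolution layers, 8 channels, rectified-linear
activations, single channel in and out, shape-preserving zero padding — is
trained to minimize the RMSE between C and D.  Weights and biases are
initialized uniformly in [0.000, 0.001]; the architecture is fully
configurable and nothing downstream depends on a particular depth.

Training is full-batch Adam (β₁ = 0.9, β₂ = 0.999) in pure NumPy (im2col
convolutions, hand-written backpropagation), bit-deterministic given the
seed.  Because the initial gain of the network is tiny, the step size first
has to grow weights to order one and then fine-tune; a cosine-decayed
learning rate (peak 5 × 10⁻³) does both within the desk-scale budget of
2000 epochs.  The hardware protocol's 60000 epochs remain available via
`TrainConfig`.  Planes are normalized by the maximum reference dose before
training and rescaled on application; outputs are clipped at 0 cGy.
Training pairs at desk scale are square patches cut from
pipeline-reconstructed synthetic fields and the matching ground truth
resampled to the rectified grid — patches keep epochs cheap while the
convolutional model applies to full planes at the same pixel pitch.

## QA metrics

**Gamma index.** γ(r_ref) is the minimum over evaluated positions of
√[(ΔD/DD)² + (Δr/DTA)²], with ΔD globally normalized to the reference
maximum; a reference pixel passes at γ ≤ 1 and pixels below the low-dose
threshold (default 5% of the reference maximum) are not scored.  The
evaluated plane is interpolated bilinearly on a search disc of radius
3 × DTA sampled at DTA/10.  The accelerated search visits offsets by
increasing radius and retires pixels whose running minimum can no longer
improve — an exact pruning.  An independent brute-force implementation
(plain per-pixel exhaustive scan with its own interpolation) serves as the
oracle on grids up to 128 px.  Evaluated-side interpolation is a fixed
convention; local-normalization and 3D gamma are out of scope.

**Beam profiles.** Over the central 80% of the field width: flatness =
100 (Dmax − Dmin)/(Dmax + Dmin); symmetry = 100 max|D(x) − D(−x)|/D(0);
penumbra = lateral distance between the 80% and 20% crossings of the
central-axis dose on each edge, linearly interpolated between samples.

**PDD.** Measured depth-dose values are rescaled so the value at the
normalization depth (default 5.0 cm) matches the reference percentage
there; per-depth relative errors are reported at the common depths.

## The synthetic bench: what it shows and what it does not

The generator emulates the acquisition physics listed above with defaults
chosen as a plausible desk-scale detector: 240 × 320 sensor, focal length
350 px, camera 260 mm behind and 180 mm above the isocenter, k1 = −0.2,
gain 400 brightness units per cGy at the isocenter distance, background 0.2,
read noise σ = 0.3, Poisson gain 0.25, two hot pixels per frame at amplitude
2000 (hot-pixel statistics scaled to the small sensor so their share of the
frame mean is realistic), 5% peak scintillator inhomogeneity with 25 mm
correlation length, 1.5 px optical blur, 24 fps.  Field edges are logistic
sigmoids whose 80–20% distance equals the penumbra parameter (4–6 mm
defaults, typical of a 6 MV beam).

Passing tests on this bench demonstrate internal consistency — each
correction inverts the artifact the generator introduced, parameter recovery
is unbiased at the stated noise levels, and the metrics satisfy their closed
forms — not clinical accuracy.  Real detectors add effects the generator
omits: energy-dependent scintillator response and quenching, camera ISO
nonlinearity (modelled here only as a single free gain), rolling shutter,
codec artifacts, backscatter physics beyond a scalar deficit, and room
scatter.  Clinical accuracy figures published for hardware detectors of
this type are therefore not reproduction targets of this package.

## Numerical choices and degenerate inputs

- Undistortion inverts the Brown model by 25 fixed-point iterations
  (round-trip error < 0.05 px over the sensor at the bench's distortion).
- Bilinear interpolation throughout (nearest-neighbour available in
  `rectify` for resolution studies); out-of-extent samples are zero/NaN and
  masked, never extrapolated.
- Homographies are normalized to H₃₃ = 1 and must be full-rank.
- `detect_segments` returns no segments for a stack whose maximum frame mean
  is ≤ 0; degenerate calibration fits (all brightness equal, fewer than two
  points, non-positive slope) are rejected with messages.
- The desk-scale problem sizes — 256 px rectified grid, 64 px training
  patches, 2000/800 training epochs, 1–3 s beam segments — are the package's
  own test-bench choices; every size is a parameter.

## Known limitations

- Mean-based segment detection needs signal frames to dominate the
  background pedestal; very small or very weak fields on a bright background
  require a higher relative threshold or trimmed videos.
- The forward FBNR window trades the trailing two frames of each segment
  (rescued by per-segment filtering) against hot pixels arriving in those
  frames (kept).  Dark-frame subtraction and median filtering are not
  implemented.
- The production chessboard-corner detector expects a fully visible board
  under moderate perspective; extreme tilts need the test-mode corner input.
- Gamma pass rates at desk-scale grids carry a boundary effect: binary-mask
  comparisons (rotation invariance) are limited by edge-pixel flips at the
  sensor's resolution.
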