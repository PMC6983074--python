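# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `icpcv`, and what the synthetic experiments do and do
not establish.

## Coordinate and anatomical conventions

Images use the raster convention throughout: origin at the top-left,
x rightward, y downward, pixel units, 0-based indices. Angles measured
from the image horizontal are therefore positive when the line drops to
the right. "Left" and "right" eyes are named by their position in an
upright, *non-mirrored* frontal image, so the image-left eye has its
inner (nasal) corner on its right side; `SegmentationConfig.mirror_view`
flips the inner/outer assignment for mirrored webcam streams. Whether a
given camera mirrors its image is a property of the capture stack, not
of the algorithm, so it is a configuration flag rather than a guess.

## Synthetic gaze model

The generator replaces live capture with an affine-plus-noise model
chosen to be the simplest data-generating process under which both the
quadratic polynomial mapping and the neural regressors are exactly
learnable — which is what makes parameter-recovery testing meaningful.

For a target `t` (screen px) on a `W×H` screen, each eye's pupil center
is

```
PC = R_yaw(base + g ∘ (t/(W,H) − ½) − c) + c + τ + ε
```

where `base` is the eye's rest position, `g = (24, 16)` px is the gaze
gain per normalized screen unit, `R_yaw` rotates about the face center
`c` by the in-plane head angle, `τ` is the head translation, and
`ε ~ N(0, σ²I)` is landmark noise. Corners follow the same rigid
transform without the gaze term. The gain corresponds to roughly ±12 px
of horizontal pupil travel across a full screen width — consistent with
an eyeball of ~12 mm radius imaged at webcam resolution at arm's length;
capture distance and camera intrinsics are deliberately subsumed into
the gain rather than modeled.

Defaults: 1920×1080 screen; eye centers at (270, 210) and (370, 210)
with ±30 px corner offsets (inner-corner separation 40 px, typical
intercanthal-to-palpebral proportions); landmark noise 0 (fixed-head
noiseless conditions) unless stated. "Free-head" sessions draw one head
pose per calibration point — translation uniform in ±20 px per axis and
in-plane rotation uniform in ±3° — and hold it for that point's frames,
emulating a user who settles into a new posture at each fixation.
Unconstrained capture involves slight head roll as well as translation,
and the roll is what gives the DES/TA components of the 8-D feature
their discriminative value; a pure-translation model would make the 8-D
and 6-D variants nearly equivalent by construction.

Rendering produces an 8-bit grayscale frame: skin background (180),
bright sclera ellipse (230), dark pupil disk (20), optional eyebrow band
(60), plus optional Gaussian pixel noise. The renderer is deliberately
schematic — no iris texture, eyelids, shadows, or 3-D perspective — so
pixel-level tests isolate the segmentation arithmetic. Head yaw in
`render_face` rotates landmark *positions* in-plane while ellipses stay
axis-aligned, which is adequate for the small-angle detection sweeps it
serves but not a 3-D head model. Consequences: passing tests demonstrate
correctness of the operators and of parameter recovery under the stated
model, not performance on photographic eye images, where iris/sclera
contrast, eyelid occlusion and specular glints dominate the error
budget.

## Segmentation choices

* **Binarization**: the Value channel of an eye ROI has three intensity
  populations — pupil, skin and sclera. Two-class Otsu places its
  threshold between the two *largest* populations, which merges a small
  pupil with the skin class; the default is therefore 3-class multi-Otsu
  taking the darkest boundary, which isolates the pupil irrespective of
  its area. Plain Otsu and a fixed threshold remain available via
  `threshold_method`.
* **Morphology**: one erosion then one dilation with a 3×3 square
  structuring element (both configurable) removes speckle noise without
  biasing the centroid of a convex pupil.
* **Component selection**: largest 8-connected foreground component;
  ties resolve to the first label in row-major scan order.
* **Centroid**: uniform-weight center of gravity over foreground pixels,
  subpixel, reported in frame coordinates (ROI offset added).
* **Corners**: Canny (σ = 1.0) on the ROI; the corner is the contour
  point of minimal/maximal x. When several contour pixels share the
  extreme column — a thinned edge runs vertically through the horizontal
  extreme of a flat eye outline — the corner is the vertical midpoint of
  that run (topmost of the two middles for even runs). Taking the
  topmost pixel instead biases the corner upward by several pixels on
  low-eccentricity ellipses.
* **ROI partition**: integer band boundaries by floor division with the
  remainder absorbed by the last band, making partitions deterministic
  and translation-equivariant.

## Eye-presence gate

Face/eye detection is a pluggable interface. Two backends ship: a
fixture backend returning the renderer's ground-truth face box, and a
pupil-pair blob detector that accepts a frame when two similar, compact
dark blobs lie on a near-horizontal line (default tilt tolerance 4°) and
infers the face box by inverting the 4-row / 5-column layout. The tilt
tolerance gives the gate a frontal working range of about ±2.5° of
in-plane rotation on clean frames — beyond it, detection fails and the
caller is expected to halt processing until the eyes reappear. A trained
cascade or neural detector can be dropped in through the same callable
interface.

## Feature definitions

* `PCECV`: ϑ₀ per (eye, corner) is the corner-to-pupil vector divided by
  that eye's inner-to-outer corner distance; averaging over the two
  corners and then the two eyes equals the mean of the four normalized
  vectors. The expansion `(1, ϑx, ϑy, ϑx², ϑy², ϑxϑy)` feeds a 2×6
  matrix fit by unregularized least squares (`numpy.linalg.lstsq`); a
  design of rank < 6 raises rather than silently regularizing.
* `ICPCV`: per-eye `PC − IC` in raw pixels (no normalization). TA is the
  angle of the vector from the left-inner to the right-inner corner
  against the horizontal, in degrees, reduced to (−90°, 90°]; with
  y-down coordinates a clockwise-rotated head gives positive TA. The 8-D
  ordering `(CESx, CESy, DES, TA, ICPCVx_l, ICPCVy_l, ICPCVx_r,
  ICPCVy_r)` is frozen so serialized models remain portable. The 6-D
  variant is the 8-vector with DES and TA removed — the only subset
  consistent with its observed inferiority under head movement, since it
  keeps head position (CES) but discards the scale and roll cues.
  An optional flag normalizes ICPCV by DES for experimentation; off by
  default.

## Regressors

One scalar-output network per screen coordinate (the x and y mappings
are allowed different effective capacities), trained on z-scored
features with targets divided by screen width/height. Standardization is
stored with the model; constant features (e.g. DES under a fixed head)
get unit divisor and contribute zero after centering. Raw pixel-scale
inputs would put sigmoid units deep into saturation at these learning
rates, so the normalization record is considered part of the model.

* **MLP** — one hidden layer (default 10 units), sigmoid hidden and
  output, full-batch gradient descent on MSE, lr 0.4, 10,000 iterations.
* **DNN** — exactly five hidden layers (default 5-10-10-10-5), ReLU
  hidden, sigmoid output, full-batch Adam (lr 0.01, β₁ 0.9, β₂ 0.999,
  ε 1e-8), 100 iterations, MSE. With so few iterations the outcome is
  noticeably initialization-dependent: most seeds land near the
  polynomial baseline, an occasional seed stalls several times higher.
  This variability is a property of the configuration, left visible
  rather than averaged away inside the trainer.
* **RBFN** — Gaussian units; centers from seeded k-means on the training
  features; one shared width equal to the mean distance from each center
  to its nearest other center (data-to-center distances collapse to zero
  on sessions that revisit identical targets, so the inter-center
  spacing is the robust choice); output weights by ridge least squares
  (λ = 1e-6) with a bias unit; predictions clamped to [0, 1].

Initialization is Glorot-uniform, seeded; identical (config, data, seed)
reproduce identical weights bitwise. Sigmoid outputs guarantee on-screen
predictions for MLP/DNN after denormalization; RBFN clamps instead. A
joint two-output mode is available but non-default.

## Protocols

Screen grids are not pinned to specific pixel coordinates by the capture
design, so the package fixes a documented convention: the 9-point
calibration grid spans the screen with 10% margins, evenly spaced,
visited row-major, 40 frames per point (360 samples). The test grid
expands each calibration point into a 2×2 cluster spaced 80 px
(points at ±40 px per axis), visited top-to-bottom within columns,
columns left-to-right — 36 distinct points, 10 frames each, again 360
samples. The diamond trajectory places 9 points sweeping left to right
across the mid-band, alternating ±25% of screen height about the
midline; each point's estimate is the mean of 10 per-frame predictions.
`dwell_seconds` is carried as metadata only — the artifact has no
real-time capture loop. All counts and offsets are configurable.

## Problem sizes and determinism

Default experiments use 360-sample sessions, 50-eye rendering batches,
100-mask centroid checks, and 5-seed comparisons for the feature
robustness contrast; these sizes give stable statistics while keeping
the full suite and the acceptance script in the tens of seconds. Every
stochastic component takes an explicit integer seed, and session
generation derives per-frame seeds from one generator so results are
reproducible bit-for-bit (rendering, CSV bytes) or to floating tolerance
(landmarks).

## Known limitations

* The renderer's simplicity means segmentation results do not transfer
  quantitatively to photographic imagery; the operators do.
* The head model is 2-D rigid (translation + in-plane roll); out-of-plane
  yaw/pitch, perspective foreshortening and distance changes are not
  simulated beyond what the gain parameter absorbs.
* The blob-pair eye gate is designed for the synthetic renderer; real
  deployments should plug in a trained detector.
* The RBFN recipe (centers, width, ridge) is one reasonable convention
  among several; its accuracy is sensitive to the width heuristic when
  calibration targets repeat exactly.
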