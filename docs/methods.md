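# Methods

## The measurement model

A colorimetric sensor array transduces the headspace volatiles of an
oil sample into colour changes of six indicator dyes. The package works
from two 8-bit RGB photographs of the same physical array — one before
exposure, one after — assumed untouched between captures (no sub-pixel
registration is attempted; a guard rejects pairs whose paired spot
centroids move by more than 5 px). The analyte fingerprint is the
per-pixel absolute colour change |post − pre| inside the segmented
spots, summarised as 18 features: the mean change per spot and per RGB
channel, in 8-bit gray levels.

The absolute value deserves a note: the subtraction direction
(final − initial) is fixed, but a dye may darken or lighten, and the
displayed 6-bit window (3–62) of difference maps is nonnegative.
Taking |post − pre| guarantees nonnegative fingerprints for either
response direction. The cost is that a signed response crossing zero
along a mixture series folds; the synthetic generator's default
responses are sign-consistent per channel so that folding never occurs
on its data (see below).

## Segmentation pipeline

1. **Luminance**: 0.2989 R + 0.5870 G + 0.1140 B (BT.601). These
   four-decimal weights sum to 0.9999, so a uniform gray level g maps to
   0.9999 g; this is intentional and matched by the tests.
2. **Otsu threshold**: the 256-bin histogram over [0, 256) is split at
   the level maximising between-class variance; ties go to the smallest
   threshold. The spot class is the side whose mean luminance differs
   more from the mean of the image-border pixels — the border of a
   scanned plate is reliably background, and nothing forces dyes to be
   darker than the substrate.
3. **Area opening**: 8-connected foreground components smaller than
   1000 px are removed (strict inequality; a 1000-px component
   survives).
4. **Erosion + area closing**: erosion by a disk (default radius 3 px;
   out-of-raster pixels count as background) peels residual rim, then
   background components not touching the raster border and smaller
   than 1000 px are filled. Hole filling is implemented directly
   because the filling rule must exclude border-connected background.
5. **Labelling**: components are labelled 1..6 in reading order. Rows
   are formed by scanning centroid rows top to bottom and starting a
   new row when the gap exceeds half the median component height —
   robust to slight plate rotation and fully deterministic. A component
   count other than the expected 6 raises a segmentation error rather
   than guessing.

All morphology uses 8-connectivity. Geometry is 0-based (row, col),
origin top-left.

## Exposure-time analysis

The response magnitude is the Euclidean norm of the 18-vector. For a
time-lapse, the pre capture is segmented once and every frame is
differenced against it. The steady state is the earliest sampled time t
such that all samples within (t, t + 10 min] stay within 2% of the peak
norm of norm(t); times whose window extends beyond the recording cannot
be certified and are skipped. Both the 2% tolerance and the 10-min
window are configurable; the windowed rule makes an otherwise visual
judgement algorithmic. Among candidate exposure conditions the one with
the largest final-time norm wins, with ties broken by earlier steady
state, then input order. First-order kinetics A·(1 − e^(−t/τ)) are
fitted by nonlinear least squares to recover τ.

## Chemometrics

- **PCA** is centred but not scaled: predictor standardisation is a
  separately searched classifier hyperparameter, and scaling twice
  would blur what the search is selecting. Components follow a
  deterministic sign convention (largest-magnitude loading entry
  positive). The component count fed to the classifier is the smallest
  k reaching 95% cumulative explained variance on the tuning
  calibration set, overridable to sweep k explicitly.
- **SVM**: soft-margin SVC, one-vs-one multiclass. Kernels: linear
  u·v, polynomial (1 + u·v)^d with d ∈ {2, 3, 4}, Gaussian
  exp(−‖u − v‖²/s²). The kernel scale s applies only to the Gaussian
  kernel. Standardisation (per-predictor centring/scaling by training
  mean/SD) is applied inside the classifier pipeline so each
  cross-validation fold and each calibration split learns its own
  transform; a zero-variance predictor gets scale 1. Vote ties in the
  one-vs-one reduction follow scikit-learn's confidence-augmented
  scheme.
- **Random search**: each of n_iter evaluations draws the kernel
  uniformly, the polynomial order uniformly when relevant, kernel scale
  and box constraint log-uniformly on [10⁻³, 10³] (the range spans six
  orders of magnitude, so a log-uniform draw is the natural choice),
  and the standardisation flag uniformly. The objective is the
  stratified 10-fold CV misclassification fraction on the calibration
  split, with one fold assignment shared across all evaluations so
  configurations compete on identical folds. The argmin is first-found
  on ties; the running minimum is the tuning curve.
- **Stratified folds and splits**: with 13 classes in a 73-sample
  calibration set, classes hold 5–6 samples — fewer than 10 folds — so
  fold assignment deals each class's shuffled samples round-robin
  across folds with a rotating offset (folds then simply lack some
  classes in their test part). Calibration/prediction splits use
  largest-remainder proportional allocation per class with at least one
  calibration sample per class; the calibration size is
  round-half-up(0.7 n), giving 73/31 for n = 104.
- **Validation**: the tuned configuration is refitted from scratch on
  each of ten stratified 70/30 splits — PCA and standardisation are
  learned on the calibration part only — and the prediction-part errors
  are averaged; per-split confusion matrices (rows true, columns
  predicted, fixed 13-class order) are kept and pooled.

Every stochastic operation takes an explicit seed; a single fit seed
derives the tuning-split, search and evaluation seeds.

## The synthetic generator

The generator emulates the study conditions: a 2×3 array on a light
plate, 13 classes (pure quince seed oil; 10, 20, 30, 40, 50, 100%
sunflower; the same grades of sesame), 8 samples per class = 104 total.

- **Geometry**: 480×640 px image, spot radius 40 px (area ≈ 5027 px,
  comfortably above the 1000-px opening threshold), 160-px grid pitch —
  a 2-cm plate with 5-mm spot spacing at roughly 80 px/cm. Spots are
  antialiased by analytic pixel coverage. Ground-truth masks contain
  only fully covered pixels, so masked means of the rendered shift are
  undiluted by the rim.
- **Colour model**: each dye has a fixed pre-exposure colour and three
  pure-oil response matrices (6 dyes × RGB). A blend's response is the
  linear interpolation (1 − f)·quince + f·adulterant — a smooth
  stand-in for volatile blending. No per-dye response values are
  published for this system, so the defaults are package design
  choices constrained to be (a) mutually ≥ 40 gray levels apart in
  Frobenius norm between pure oils, (b) strongest for dyes S1, S4 and
  S6 under sesame, (c) sign-consistent per channel across oils so the
  |·| fingerprint distance from pure quince grows monotonically with
  the adulteration fraction, and (d) bounded so no channel clips at
  the noise levels used. They are validated against generator ground
  truth only.
- **Nuisance structure**: i.i.d. Gaussian pixel noise (default SD 3
  gray levels, independent per capture, clipped and quantised to
  8 bits) and a random linear illumination ramp of up to 5% fractional
  slope, shared by the pre and post captures of a sample (a fixed
  scanner geometry). Noise is spatially uncorrelated; illumination is
  the only correlated effect modelled.
- **Kinetics**: the shift at time t scales by 1 − e^(−t/τ) with
  τ = 15 min, placing the response within 2% of its plateau near
  60 min — the exposure duration the steady-state rule should recover.
- **Determinism**: all randomness flows from one sample seed
  (illumination, then pre noise, then post noise); identical seeds give
  bit-identical images.

### What the generator does not emulate

Real plate photographs have textured substrates, non-circular and
ragged spots, chromatic illumination, camera noise that is neither
Gaussian nor pixel-independent, registration shifts between captures,
and dye responses that are nonlinear in the mixture fraction and
correlated across channels. Passing tests on generator data therefore
demonstrate the correctness and internal consistency of the pipeline —
segmentation recovers known geometry, features recover known shifts,
the classifier recovers known classes at realistic noise — not field
performance on laboratory images. In particular the 0% repeated-split
error on default synthetic data reflects the generator's clean class
structure, and the published headline error rates of the physical
system are not reproducible desk-side because its 104 laboratory
samples are not deposited.

## Numerical choices and degenerate inputs

- Display rescaling clips to [3, 62] and rounds half away from zero;
  the endpoints map exactly to 0 and 255.
- Constant rasters cannot be thresholded (degenerate histogram error);
  all-zero response profiles cannot yield a steady state ("no
  response").
- A mixture fraction outside [0, 1], overlapping or out-of-bounds
  spots, and spot areas ≤ 1000 px are rejected at generator
  construction.
- Rounding to 8 bits makes a half-integer true shift recoverable only
  to 0.5 gray levels; the noise-free recovery checks use exactly that
  tolerance.
- Test suites and the acceptance script run the imaging-heavy checks on
  down-scaled geometries (240×320 or 120×160 px with 19–20 px spots)
  chosen to keep every constraint of the full geometry, including the
  1000-px opening threshold, while rendering quickly.

## Known limitations

- The absolute-value fingerprint discards response direction; two dyes
  shifting by +Δ and −Δ are indistinguishable in features.
- Row-major spot labelling assumes an approximately axis-aligned grid;
  strong plate rotation (row gaps below half the median spot height)
  would merge rows.
- The one-vs-one tie-break follows scikit-learn rather than an explicit
  aggregate-decision-value chain; ties are vanishingly rare on
  continuous scores.
- Model JSON artefacts store the fitted PCA and SVM parameters for
  inspection and exchange, but `evaluate` refits from the stored
  configuration rather than reconstructing the dual form.
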