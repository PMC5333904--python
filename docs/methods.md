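# Methods

This note documents the models, numerical choices, and limitations behind
`mristand`: what each component assumes, why its defaults are what they
are, and what the phantom-based tests do and do not establish about real
data.

## Intensity conventions

Volumes are floating point internally.  The nominal 12-bit scale
(I_min = 0, I_max = 4095) of uniform MP2RAGE-style T1-weighted images is a
dataset convention, declared per volume (or via a TOML config) and never
assumed silently: out-of-range voxels are counted and reported on read, and
quantisation to integers happens only on request at write time.  Premature
rounding would corrupt the cumulative-distribution metrics, which resolve
single intensity levels.

Skull-stripped background is represented by exact zero.  Both the
distortion simulator and the transform evaluator leave exact-zero voxels at
zero: interscan exposure variation acts on tissue signal, not on air, and
several downstream steps (brain masking, re-segmentation) identify the
brain as the non-zero support.  One consequence worth stating: the RLS line
has no (0, 0) anchor, so without this rule a positive offset would lift the
background off zero and break every later stage.

All inputs to a comparison must share one voxel grid (shape equal, voxel
sizes within 1e-6 mm).  Spatial registration is deliberately out of scope;
mature external tools solve it, and grid enforcement keeps the package's
claims purely about intensities.

## The phantom

The generator emulates the features of a skull-stripped T1-weighted brain
volume that the standardisation methods actually consume, and nothing more:

- **Geometry** — nested ellipsoids (CSF shell ⊃ GM ribbon ⊃ WM core, mild
  per-axis anisotropy) plus a central GM sphere, the "hypothalamus",
  embedded in WM.  The sphere and the WM shell around it provide the
  pure-tissue ROI pair that RLS needs.  The default sphere radius of
  8 voxels yields ~2100 ROI voxels, at the lower limit of what supports a
  reliable median.
- **Intensities** — per-tissue Gaussians.  GM mean 1907 and WM mean 3246
  are the tissue-median sample means of a 7T MP2RAGE population; the SDs
  75.9 (GM), 58.5 (WM), 130.9 (CSF) are that population's between-subject
  SDs of the tissue means, used here as within-image noise so that the
  histogram peaks have realistic widths relative to their separation.  The
  CSF mean (600) is a design choice — no published value exists for this
  scale — set well below the GM mode-search window so CSF can never
  contaminate mode detection.  Noise is Gaussian, not Rician: the emulated
  images are magnitude-combined and bias-corrected, and at these SNRs the
  Rician correction is negligible compared with the between-subject effects
  under study.
- **Distortions** — monotone maps modelling interscan variation: global
  offset, linear (exposure scaling with intensity), tissue-piecewise
  (per-tissue over/underexposure), and smooth non-linear (monotone cubic
  through control points).  The default benchmark distortion emulates the
  study population's extreme-decile selection: GM/WM median shifts with
  magnitudes in [60, 120] and [45, 90] (≈0.8–1.6× the population SDs),
  converted to the line through the two shifted anchors.  Larger shifts are
  representable but push small-ROI histograms out of any shared intensity
  range, which no real extreme-decile sample exhibits.
- **Cohorts** — for the maintenance criterion, the outer GM radius shrinks
  linearly with subject age (default 0.0012 grid fractions/year around age
  45, with small jitter), giving whole-brain GM volumes a strong negative
  age correlation, the biological signal standardisation must not destroy.

What the phantom does *not* emulate: cortical folding, partial-volume
voxels, spatially varying bias fields, vessels, lesions.  Tests passing on
phantoms therefore demonstrate the *algorithmic* properties of the methods
(recovery of known distortions, anchor exactness, distribution agreement,
preservation or destruction of volume–age structure) — not segmentation
robustness to anatomy, which is owned by the upstream tools this package
deliberately does not replace.

## Histogram smoothing and mode detection

The histogram uses unit-width bins over [I_min, I_max + 1).  Mode detection
proceeds in three steps:

1. **Robust loess** over the contiguous occupied support: locally weighted
   *quadratic* regression, tricube kernel, window = 1% of the histogram's
   data points (41 bins on the 12-bit scale), five bisquare reweighting
   iterations.  One deliberate deviation from textbook loess: the bisquare
   scale is the *per-window* median absolute residual rather than the
   global one.  Histogram counts are Poisson, so residual scale varies by
   orders of magnitude between peaks and empty stretches; a global scale
   classifies entire peak regions as outliers and flattens them (observed:
   a ~90-unit GM-mode displacement), which inverts the purpose of the
   robustness step.  The local scale suppresses isolated spikes while
   leaving peaks intact.
2. **Spline parameterisation**: a least-squares cubic spline with break
   points every 32 intensity units, fitted to the loess output
   (interpolation on supports too short for that).  32 units sits well
   below the narrowest tissue SD (58.5), so genuine peaks survive while
   residual bin-level wiggle — the dominant source of mode-estimate
   variance — is removed.
3. **Mode = highest local maximum of the spline** inside the fixed GM
   (1000, 2500) and WM (3000, 3500) windows, located on a 0.25-unit grid
   with parabolic refinement; ties go to the lower intensity for
   determinism.  A window containing no interior maximum is an error, not a
   guess.  Describing the mode as a "second-derivative zero-crossing" only
   makes sense for a spline fitted to the *cumulative* histogram (whose
   second-derivative zeros are density extrema); that reading is available
   behind the `on_cumulative` flag and agrees with the default on unimodal
   windows.

Mode-estimate precision is sample-size-limited: the GM peak is wide
(SD 76), and at ~85k brain voxels (a 64³ phantom) the estimate's sampling
SD is several intensity units, while at the acquisition scale the package
targets (~2.3M brain voxels, a 192³ phantom, matching a 320×320×240
skull-stripped volume) both modes localise within ±5 units.  Accuracy
statements are therefore made at that scale.

## Segmentation

Three-class fuzzy c-means on intensities (fuzziness m = 2, convergence when
centroid movement < 1e-3, cap 200 iterations), with centroids initialised
at the 10th/50th/90th brain-intensity percentiles — deterministic by
construction, so every pipeline run is exactly reproducible without seed
plumbing.  An optional per-iteration blending of memberships with their
6-neighbour mean (`smoothing_weight`) provides light spatial
regularisation; the default is 0 because the phantom's class separation
(≥ 13 SDs between adjacent tissue means) already yields ≥ 98% voxel
accuracy, and adaptive gain-field machinery is unnecessary for
bias-corrected input.  Hard labels take the class of maximal membership,
ties toward the lower-intensity class.  Background voxels are whatever the
brain mask excludes (default: exact zeros).

## The five transforms

All five produce a serialisable monotone `TransformFunction` clamped to the
declared range.

- **PHM / SPS** (piecewise linear): anchor exactness is structural — the
  target mode/mean maps onto the reference's by construction.
- **NHM**: interpolating cubic spline, not-a-knot ends, through the PHM
  mode anchors plus (1, 1) and (I_max−1, I_max−1) guard points.  With this
  few points a least-squares spline degenerates to interpolation, so
  interpolation is used directly.  Cubic splines through steep anchor
  configurations can overshoot: the builder scans a dense grid, logs any
  non-monotonicity, and evaluates such transforms through a monotone
  (cumulative-maximum) envelope instead of the raw spline.
- **CHM**: the intensity range is divided into 1024 equal classes; each
  target class maps to the reference class of nearest relative cumulative
  frequency (ties to the lowest level, for determinism), and the lookup is
  forced non-decreasing.  The lookup output is the *lower edge* of the
  chosen reference class, which keeps intensity 0 fixed.  A resolution
  limit is intrinsic here: a step lookup cannot match cumulative
  distributions more finely than the largest single-class mass.  On
  multimodal brain histograms the peak classes carry roughly 0.8% of all
  voxels, so the best achievable max-CDF discrepancy is ~0.004 — about 4×
  the naive 1/1024 expectation.  This is a property of class-resolution
  quantile matching itself, not of this implementation, and holds equally
  at acquisition-scale voxel counts.
- **RLS**: the unique line through (GM-ROI median_T → GM-ROI median_R) and
  (WM-ROI median_T → WM-ROI median_R), applied globally and clamped to the
  range (whether to clamp or allow >I_max outputs is an open convention;
  clamping is chosen and logged in the transform's domain).  On noiseless
  phantoms RLS composed with any linear distortion is the identity to
  machine precision — unless the distortion itself saturates WM at the
  range ceiling, in which case the information is destroyed before any
  method runs; the benchmark redraws such distortions (~0.6% of the
  sampled parameter box) and says so.

## Evaluation statistics

- **Wilcoxon signed-rank**: zero differences dropped, tie-corrected normal
  approximation, *no* continuity correction, two-tailed p from the normal,
  effect size r = Z/√N with N = 2·n_pairs.  This is the one convention
  under which 20 one-signed tie-free pairs give |Z| = 3.92 and under which
  every published (Z, r) table cell reconstructs to print precision; scipy's
  implementation serves as an independent cross-check in the tests, not as
  the implementation.
- **Pitman–Morgan**: t = r_sd·√(n−2)/√(1−r_sd²) with r_sd the correlation
  of (x+y) with (x−y); df = n−2 (t(18) at n = 20).  Shapiro–Wilk normality
  p-values for both samples are attached as a screening report (delegated
  to scipy), not used for gating.
- **Steiger's Z** for dependent correlations sharing one variable: the
  common-index, pooled-r variant (Steiger 1980, Z1*).  The exact variant
  used in older software is not recoverable from descriptions, so this one
  is pinned by a Monte-Carlo type-I-error oracle in the tests.  Effect size
  Cohen's q = |z(r₁) − z(r₂)| (Fisher z), graded 0.10/0.30/0.50 =
  small/medium/large.
- **ICC**: test–retest agreement uses ICC(3,1) — two-way mixed,
  consistency, single measures (via pingouin) — appropriate when both runs
  come from the same rater.
- **No multiple-testing correction** anywhere: the evaluation criteria are
  separate questions with no global hypothesis; p < 0.05 per test.
- **Boundary intensity**: the rater procedure (adjust the white point of a
  red–white–blue transfer function until it outlines the GM/WM border) is
  automated for phantoms as the median intensity of face-adjacent GM/WM
  interface voxels.  The transfer-function presets are: T1-weighted — range
  (0, 4000), red→white→blue, white at 60%; quantitative-T1 — range
  (950, 3700), blue→white→red, white at 40%.  Converting a white fraction
  to intensity uses the declared range; note that 5.3% of a (0, 4000) range
  is 212 levels, so a printed "211 levels" for an SD of 5.3% reflects an
  unrounded SD, a one-level discrepancy the conversion function documents
  but cannot remove.

## Benchmark problem sizes

Defaults are chosen so a full run completes in minutes on one CPU while
keeping every statistical contrast well-powered: benchmark cohorts use 40³
or 48³ grids (FCM on tens of thousands of brain voxels), mode-accuracy
claims use 192³ phantoms (acquisition-scale voxel counts, see above), the
correlation-maintenance contrast uses 100 cohorts × 12 subjects, and
recovery properties use 20 sampled distortions.  All randomness flows from
named seeds recorded in each run's manifest, and rerunning a configuration
reproduces the CSV reports byte for byte.

## Known limitations

- The phantom's tissue histograms are exactly Gaussian, so CHM's failure
  mode (imposing the reference's GM/WM volume ratio) appears in its purest
  form; real histograms with skew and partial volume would blur, but not
  remove, the effect.
- `fuzzy_segment` is intensity-only; it will not resist bias fields.  It is
  a stand-in for adaptive fuzzy segmenters on already-corrected images.
- `standardize` from the CLI derives RLS ROIs from the phantom's central-
  sphere geometry; on real data the ROI medians should be computed from
  externally drawn masks and passed through the library API.
- Mode detection requires the GM/WM peaks to fall inside the fixed search
  windows; sequences with different contrast need re-windowed calls.
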