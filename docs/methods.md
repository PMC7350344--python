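# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `rootmorph`. It is written for someone who wants to
trust (or challenge) a number the pipeline produces.

## Imaging model and scale

All images are carried as float intensities in [0, 1] with an attached
resolution in dots per inch (DPI). DPI is a required user input — file
metadata is ignored because it is frequently wrong — and defaults to 450,
the nominal resolution of the reference rig. Conversions are centralized:
px_per_cm = dpi/2.54; lengths are reported in cm, diameters and radii in
mm, volumes in cm³, areas in cm², matching how root traits are normally
tabulated.

**Stack median.** "Median filtering" of an exposure stack is implemented
as the *temporal* per-pixel median across the ~5 co-registered exposures,
not a spatial filter: transient specks appear in single exposures at
independent positions, so the per-pixel median eliminates them without
blurring edges. For even stack lengths the lower median (order statistic
⌈n/2⌉) is taken so every output intensity is one actually observed — no
interpolated values enter the mixture fit. An optional in-plane 3×3
median (`imaging.spatial_median`, config `imaging.spatial_median`) is off
by default.

## Frame detection

The board's margins are the longest straight edges in the scene. Edges
come from a Canny detector (σ = 1.0 px, hysteresis 0.1/0.3 on unit-range
intensities); lines from a normal-form Hough accumulator
ρ = x·cosθ + y·sinθ with ρ resolution 1 px and θ resolution 0.5° over
[0, π). Peaks need at least `0.3·min(H, W)` votes — board margins span
most of the image, roots do not — and are extracted by greedy non-maximum
suppression (±5 bins in ρ and θ; ties broken deterministically by bin
index). The outermost near-horizontal and near-vertical pairs (within ±5°
tilt) define the frame; the crop is the largest axis-aligned rectangle
strictly inside all four lines, shrunk by a 3 px safety margin. No
rotation correction is applied: the board is a stage-mounted fixture, and
for small tilts (≈2°) the inscribed axis-aligned rectangle loses only a
narrow border strip. Coordinates are row-major, 0-based, half-open, and
every crop records its offset so mask coordinates map back to the
original photograph.

A missing frame is an error by default (`frame.required`); with
`required=false` the full image is processed with a warning, which is the
right behaviour for already-cropped inputs.

## Mixture segmentation

Pixel intensities inside the cropped board are modelled as a K = 3
Gaussian mixture: bright board, dark root, intermediate dirt/shadow. The
fit is a diagonal-covariance EM on a uniform subsample of at most 10⁵
pixels (EM on every pixel of an A4 scan at 450 DPI is wasted effort; the
subsample's standard error on component means is far below the achievable
accuracy). Initialization is k-means++-style seeding from the per-tray
seed; iterations stop at an absolute log-likelihood gain below 1e-6 or
300 iterations; variances are floored at 1e-6 each M-step. The
log-likelihood trace is stored on the model and asserted non-decreasing
in the tests — a broken EM shows up immediately. Grayscale intensity is
the default feature space; RGB is accepted (diagonal covariances).

The root mask is the maximum-a-posteriori rule: a pixel is root when its
posterior for the root component(s) is ≥ 0.5, ties included. The root
component is the darkest one, *provided* it lies at least 6 board-sd
below the brightest component's mean (`seg.min_separation_sd`). This
separation guard exists because a tray can genuinely contain no roots
(total root destruction): the mixture then merely partitions sensor
noise, its "darkest" slice is not meaningfully dark, and without the
guard a near-percolating noise mask would be measured as root. The
board's own sd is the yardstick — it is pinned by the huge background
mass — rather than the candidate's sd, which inflates when one component
absorbs both roots and dirt.

**Mask cleaning.** 8-connected components below 25 px (at 450 DPI) are
specks; enclosed background holes below 100 px are filled (rotted roots
can be hollowed to the rhizodermis and central cylinder, which images as
a ring). Both areas, like the dirt thresholds below, are stated at the
450 DPI reference and rescaled by (dpi/450)² at other resolutions.

**Dirt removal.** Dirt is discriminated at the component level by shape,
not intensity: soil crumbs are compact, roots are elongated. A component
is kept as root when any of these holds:

- second-moment-ellipse axis ratio ≥ 3;
- skeleton aspect (skeleton length² / area, a curvature-invariant
  length-to-width ratio) ≥ 3 — the ellipse ratio alone misclassifies
  strongly curved roots, whose second-moment ellipse is nearly round (a
  C-shaped root can score ellipse ratio ≈ 2.4 while being 14× longer
  than wide);
- solidity < 0.5 at area ≥ 200 px — a convex-hull-based backstop for
  snake-like shapes; the area gate stops ragged noise clumps from riding
  it;
- area > 50,000 px — a root mat this large is kept regardless of shape.

Every component's stats (area, ellipse ratio, solidity, skeleton length,
aspect, removed flag) are returned for an audit CSV, so a user can review
exactly what was discarded.

## Length per diameter class

The mask is thinned to a 1-px medial axis with Lee's method. The choice
of thinning algorithm matters more than is commonly appreciated: Zhang
thinning digitizes oblique centerlines with a zigzag that inflates
length estimates by ~6% near 30° orientations, while Lee thinning
reproduces near-ideal Bresenham step statistics.

Local diameter at a skeleton pixel is 2× the Euclidean distance
transform of the mask. This is exact for band-like shapes up to a +1 px
bias (the EDT measures to the nearest background pixel *center*); at
450 DPI that bias is 0.06 mm and shrinks with resolution.

Skeleton length uses the 8-adjacency link counts N_o (orthogonal) and
N_d (diagonal). Two estimators are provided:

- `chain`: L = N_o + √2·N_d. Simple, but mathematically biased for
  oblique lines — an ideally digitized 30° line measures +7.2% long; no
  thinning can repair this, it is a property of chain coding.
- `kimura` (default): L = √(N_d² + (N_d + N_o/2)²) + N_o/2, applied per
  connected component (link shares rescaled to the corrected total).
  On ideally digitized lines its worst orientation error is ≈3%, and on
  the synthetic scenes per-tray totals land within 1.5–3% of exact
  centerline truth.

An end correction (default on) adds the local EDT radius at every
degree-1 skeleton pixel (twice for isolated pixels), compensating the
medial axis' end taper, which otherwise loses about half a width per
stroke end.

Each skeleton pixel's length share is accumulated into a fixed grid of
0.1 mm diameter classes from 0 to 6 mm (last bin closed above, catching
overflow); the fixed grid guarantees that tray histograms of one plant
share edges and cumulate exactly, with no rebinning. Histogram mass
equals skeleton length to float round-off by construction.

## Fibrous/storage split and cylinder traits

Otsu's criterion is applied to the *length-weighted* diameter
distribution (length is the only mass in the diameter-versus-length
table): the threshold is the interior bin edge maximizing
σ²_B(t) = w₀w₁(μ₀−μ₁)², ties broken toward the smallest edge within a
1e-12 relative tolerance (across an empty gap the criterion is constant
and only float noise distinguishes the plateau's edges). Fibrous is
strictly below the threshold, storage at or above. A histogram with
fewer than two occupied classes cannot be split; such plants are
classified entirely as fibrous and flagged rather than dropped — severe
root rot can eliminate storage roots, and the pipeline must report, not
crash on, exactly those plants. Otsu is per plant by default; a
`trait.global_otsu` flag pools all plants' histograms for one shared
threshold.

Cylinder traits treat each bin as a cylinder at the bin midpoint —
unbiased in the fine-bin limit and exact here because synthetic stroke
widths are snapped to midpoints. Per class: L = Σ l, V = Σ π(d/20)² l,
A = Σ π(d/10) l, mean radius = Σ (d/2)·l / L. Class totals add exactly
to whole-histogram totals because the split is a partition of bins.

## Synthetic scenes and what they (don't) show

The generator renders: a dark surround, the bright board (optionally
tilted), constant-width smooth root strokes, dirt discs with mildly
irregular boundaries, and — per exposure — Gaussian sensor noise
(sd 0.02) plus dark impulse specks at exposure-independent positions.
Strokes are constant-step random walks (0.5 mm steps, heading jitter
0.10 rad for fibrous, 0.035 rad for the stiffer storage roots) steered
away from the board edge, rejected on self- or mutual overlap — the
physical protocol separates roots on the board precisely so that strokes
do not cross. Widths are uniform per class (fibrous 0.3–0.8 mm, storage
1.5–4 mm, reflecting the biological dichotomy of fine absorptive versus
thick storage roots) and snapped to the 0.1 mm class grid so the
closed-form truth traits and the truth-histogram traits agree exactly;
lengths are uniform 2–20 cm on the full-size board. Truth is defined
before noise: a pixel is truth-root iff its center lies within width/2
of the centerline polyline, and rendering anti-aliases the *same*
distance field with a 1 px ramp, so rendering softness never redefines
truth.

Problem sizes in the tests and the acceptance script are the package's
own choice of scale: quarter-A4 boards at the full 450 DPI where pixel
geometry matters (mask quality, length accuracy), and 6×8 cm boards at
250 DPI for the many-plant batches (class recovery, volume r²,
determinism). Physical parameters are never rescaled, only scene extent
and stroke count per tray (a quarter board holds 8 fibrous + 3 storage
strokes of 2–10 cm; full A4 defaults to 10 + 3 of 2–20 cm).

What passing these tests does *not* show about real photographs: real
roots taper, branch, and vary in color; lighting vignettes; boards carry
rulers and labels; dirt is not disc-shaped. The generator deliberately
models none of these (constant width keeps truth closed-form; crossings
are excluded by protocol), so field use still warrants spot-checking
masks via `rootmorph inspect`.

## Numerical and degenerate-input choices

- Even-length stack median: lower order statistic (observed values only).
- EM on constant samples with K > 1: returns one dominant component with
  floored variances and a `degenerate` flag instead of crashing.
- Mixture components with vanishing responsibility mass keep floored
  variances; weights are renormalized each M-step.
- Posterior rows sum to 1 within 1e-9 (log-sum-exp normalization).
- Otsu plateau ties: smallest edge within 1e-12 relative of the maximum.
- An isolated skeleton pixel has chain length 0; with end correction it
  contributes 2·EDT (it is all ends).
- Per-tray sub-seeds are CRC32(tray_id) mixed with the global seed via a
  Knuth multiplicative constant — stable across processes, unlike
  Python's builtin `hash`.

## Limitations

- **Otsu under wide storage-width spread.** With storage widths drawn
  uniformly over 1.5–4 mm, the storage cluster's internal spread
  (2.5 mm) far exceeds the fibrous–storage gap (0.7 mm), and the
  between-class variance criterion is globally maximized by a split
  *inside* the storage cluster for roughly one plant in five (verified
  against an exhaustive scan on exact truth histograms; the effect grows
  with stroke count). This is a property of Otsu's criterion itself, not
  of the imaging: on real plants whose storage roots share a similar
  diameter the cluster is compact and the gap split wins. The class
  recovery test asserts the ≥95% separation target and is expected to
  fail at ≈85% under these synthetic width distributions; the per-class
  length errors for correctly split plants are a few percent.
- Diameters carry a +1 px EDT bias (+0.06 mm at 450 DPI); volumes of the
  finest roots are correspondingly overestimated, though total volume is
  dominated by storage roots where the bias is ≈4% in diameter.
- Touching or crossing roots are measured as one object; the protocol's
  physical separation is assumed.
- The 0.5-posterior rule loses a sub-pixel rim of each stroke where
  anti-aliased intensities resemble dirt; recall on the thinnest fibrous
  roots (≈3 px wide at low DPI) drops accordingly, which is why mask
  quality is specified at 450 DPI.
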