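# Methods

## The measurement model

The pipeline treats one two-channel field (nucleus stain, whole-cell
stain) as the unit of acquisition.  Analysis proceeds in three steps.

**Segmentation.**  Nuclei are found by a global Otsu threshold with a
robust noise floor (median + 5 robust SD — Otsu alone bisects a blank
channel's noise), hole filling, and a minimum nucleus size (default
40 μm²) that removes stain speckle.  Cytoplasm foreground comes from the
same thresholding rule; connected foreground containing several nuclei
is split by a nucleus-seeded watershed on the distance transform.  A
watershed split is only *kept* if the stain intensity actually dips at
the shared boundary: for each touching pair of seeded regions, the mean
seam intensity on each side is compared with that region's own mean, and
the regions are merged back when the average relative seam brightness
exceeds 1 − `min_separation_level` (default 0.05).  This distinguishes
two touching cells (dim seam on both sides, because stain falls off
toward each cell's membrane) from one binucleate cell (bright interior
along the cut).  Foreground with no nucleus is kept as an object with
`n_nuclei = 0` so the gate can count it.

**Gating.**  An object is accepted as a single analyzable cell when it
does not touch the 1-pixel image border ("wholly contained" is read
strictly), contains exactly one nucleus (membership of the nucleus
*centroid* in the object mask — simple and unambiguous), and has area
≥ `min_area` (765 μm² default, applied in physical units so the rule is
magnification independent; the boundary case is accepted).  Rejections
record the first failing rule in the order border → nucleus count →
size, which makes the per-reason accounting stable.

**Morphometry.**  Length and width are image-aligned bounding-box
extents; area is pixel count × pixel_size².  The perimeter estimator is
the arc length of the marching-squares boundary contour after a light
Gaussian smoothing along the contour (σ = 1 px).  Raw contour length
overestimates smooth boundaries by up to ~8% (staircase bias), while
Crofton-style direction counting underestimates axis-aligned straight
edges by ~5%; the smoothed contour keeps both a rasterized disk
(within ~1% of 2πr) and an axis-aligned square (within ~1% of 4s)
accurate, which the shape ratios inherit.  The convex hull is the
rasterized hull image of the mask's pixel centers: the mask is a subset
of its hull image, so the hull area ratio is ≥ 1 exactly; the hull
perimeter uses the same contour estimator as the cell perimeter, so the
perimeter ratio is ≤ 1 up to rasterization tolerance (≈1%) and equals 1
for convex cells.  "Perimeter to area ratio" is implemented as the
dimensionless circularity P²/(4πA), the standard roundness measure that
equals 1 for a disk; a literal P/(4πA) is not dimensionless and is
available only by computing it from the returned size columns.

## The statistics workflow

Trimming removes exactly ⌊f_lo·N⌋ smallest and ⌊f_hi·N⌋ largest values
per variable (defaults 0.05/0.05), ties broken by stable input order;
the retained count identity N − ⌊0.05N⌋ − ⌊0.05N⌋ is property-tested.
Box-Cox uses y′=(y^λ−1)/λ with the λ=0 limit ln y; λ defaults are 0 for
the seven right-skewed descriptors and 2 for the two left-skewed ones
(boxed frame ratio, convex hull perimeter ratio).  The natural log is
used throughout — skewness, KS and linear-model R² are all invariant to
the base.  Skewness is the adjusted Fisher–Pearson estimator
(mainstream-package convention); constant samples return 0 and are
flagged degenerate.

PD-model ranking fits ordinary least squares of the group PD number on
each (variable × {group mean, group SD}) summary and sorts by R², ties
alphabetical.  The two-way ANOVA uses Type II sums of squares because
the donor×passage design is unbalanced in practice (the senescent
passage often lacks a donor); interaction requires within-cell
replication and missing design cells are reported by name.  Pairwise
comparisons are Welch t tests by default (group variances grow strongly
with passage), Bonferroni-corrected by the number of comparisons and
gated on ANOVA significance at 95%.  KS comparisons use the standard
two-sample statistic; being rank-based they are exactly invariant under
strictly increasing transforms, which the tests assert as an identity.

Fold changes are ratios of passage means to the reference passage,
reported at one decimal with the raw ratio retained.  In the pipeline
report the passage means are computed from *within-group* trimmed data
(each donor×passage group trimmed 5%/5%, donor means weighted equally):
trimming is meant to remove per-sample artifacts, and trimming the
pooled table instead would clip the upper tail of the largest-cell
groups and systematically compress the very contrast the fold table
reports.  The pooled per-variable trim is still applied for the
distributional analyses and the headline retained-count accounting.

## Growth, telomeres, markers

PD = log₂(N_H/N₁) per passage (N in cells/cm²; at passage 0 the seeded
count is the CFU-F colony density, entered as a number).  Cumulative PD
is the running sum; the rate is PD per culturing day.  A culture is
flagged senescent at the first passage with confluency < 30% after ≥ 14
days; both clauses must hold, and missing confluency makes the rule not
evaluable (warning).

TRF densitometry: ladder calibration interpolates log₁₀(length) linearly
in migration position (standard gel migration behaviour) and refuses
extrapolation beyond the rung span.  Background is a rolling-minimum
baseline (window 51 samples, smoothed by a same-width moving average)
subtracted with clipping at zero.  The mean TRF is Σ(ODᵢLᵢ)/Σ(ODᵢ) over
profile samples — the summation index runs over samples, not bands —
restricted to the inclusive 3–20 kbp window (a 1e-9 kbp tolerance keeps
bands at exactly 3 or 20 kbp from being dropped by interpolation
round-off).  The statistic is invariant to uniform OD scaling and always
lies within the window.  Replicate lanes are averaged at the level of
lane means.  Shortening rates are per-donor OLS slopes of length (bp) on
cumulative PD, sign-flipped so shortening is positive, with the cohort
mean ± SD across donors.

Marker tables (one row per donor×passage group; columns: mean cell area,
PD/day, p16, p21, SA-β-gal, mean telomere length) are summarized by a
complete-case Pearson matrix (constant columns yield NaN with a warning)
and by PCA on standardized columns, components ordered by explained
variance, PC1 oriented so the cell-area loading is positive and later
components oriented by their largest-magnitude loading.  Inference on
the correlations (tests, intervals) is deliberately out of scope.

## The synthetic-data generator

The generator defines the study conditions the pipeline is exercised
under.

* **Cell areas** are lognormal, moment-matched to the per-passage means
  and SDs of the published group table (p1 1827±329, p3 2352±386,
  p5 4198±1628, pSEN 8744±2494 μm², with PD numbers 19.3±1.5, 28.3±2.1,
  33.5±4.7, 36.6±7.1).  The lognormal family reflects the strong right
  skew of real cell-area distributions.  The published SDs are SDs of
  donor means, used here as per-cell spread — a deliberate approximation
  (no per-cell data exist to calibrate against), which makes the
  generated within-group skewness milder than the real ~0.96.
* **Cell shapes** are smoothed star-convex polygons (radius-perturbed
  circles, Gaussian-smoothed along the contour) — a fixture choice, not
  biology; nothing downstream depends on the outline family.
* **Fields** are 512×512 px at 0.65 μm/px (a typical 10× high-content
  setting; configurable — the pipeline only ever uses physical units).
  Placement is reject-and-resample with a 2-px clearance, at most 100
  attempts per cell (`PlacementError` beyond that), keeping fields as
  sparse as a low-density plating.  Configurable fractions of objects
  are border-crossing cells, touching pairs (adjacent masks, separate
  ground-truth labels), binucleate cells, and anucleate debris below the
  765 μm² gate.  Stain rendering gives each cell a radial intensity
  falloff (edge at 65% of center) so touching cells have a detectable
  seam; Gaussian read noise (SD 10 on a 100 background, cells at
  ~380–650) is added per channel.
* **TRF lanes** are Gaussian bands in position space with width
  equivalent to `smear_sd` kbp at the band location, so the profile's
  OD-weighted mean converges to the analytic mixture mean Σ(wL)/Σw as
  the smear narrows (closure verified to 0.5% at smear 0.05 kbp); at
  zero smear the band's grid sample is snapped to its exact position,
  making the recovery exact.
* **Marker panels** are multivariate normal draws with the published
  6×6 correlation matrix as target (verified positive definite;
  a nearest-PSD repair with warning exists for user-supplied matrices)
  and realistic per-marker locations/scales.  Affine marginals keep the
  Pearson structure exact, so sample correlations converge to the target
  as rows grow.

What the generator does *not* emulate: optics (PSF, vignetting,
autofocus failure), uneven illumination, staining variability between
runs, and the heavy artifact burden of real high-content screens.
Passing tests therefore demonstrate correctness of the measurement and
statistics machinery under controlled conditions, not robustness to
every real-world imaging failure mode.

## Numerical and design choices

* Thresholds default to Otsu per channel rather than iteratively tuned
  platform-specific values; all gating parameters are exposed in the
  config.
* Per-field intensity handling needs no exposure compensation because
  thresholds are computed per field; hardware exposure control is out of
  scope.
* Problem sizes in the bundled runs and checks (hundreds of cells per
  group, 50-field gating suites, 500-replicate null simulations) are
  chosen to give stable estimates — gating proportions to ~1%, type-I
  rates to ~1 percentage point — while keeping a full run in tens of
  seconds.
* Determinism: every generator consumes an explicit integer seed;
  pipeline stages derive child seeds from the run seed via
  `SeedSequence.spawn`, so identical config+seed reproduces byte-identical
  numeric tables.
* Degenerate inputs fail loudly and early: empty masks, disconnected
  masks, non-monotone ladders, zero in-window OD, empty design cells,
  nonpositive values under Box-Cox (with the offending index named).

## Known limitations

* The watershed merge heuristic assumes stain falls off toward the
  membrane; cell types with uniformly flat cytoplasmic stain would need
  a lower `min_separation_level` (0 trusts every watershed split).
* The senescence rule needs confluency records; the optional image-based
  estimator (foreground fraction) is only calibrated for synthetic data.
* Fold-change recovery at the senescent passage is sensitive to how
  trimming interacts with heavy upper tails; the within-group trim used
  for the fold table is the package's resolution of that tension (see
  above), and pooled-trim means remain available from the group
  summaries.
* The marker panel correlations are recovered as drawn; with real donor
  panels (a handful of rows) sampling error on r is large, and the
  package deliberately reports coefficients without inference.
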