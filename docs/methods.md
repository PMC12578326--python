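# Methods

This note documents the models, parameter choices and numerical conventions
behind `parallign`, and what the synthetic benchmarks do and do not
establish.

## Segmentation

Images are converted to grayscale (luma weighting for RGB; integer inputs
rescaled so the dtype maximum maps to 255) and then to the [0, 1] range for
filtering.  Curvilinear structures are enhanced with the multi-scale Frangi
vesselness measure at σ ∈ {0.25, 0.50, …, 3.5} px (14 scales, matching
branch widths up to roughly 7 px), max-pooled over scales and max-normalized
to [0, 1].  The vesselness constants are the conventional α = β = 0.5 for
the anisotropy term and γ = 15 applied to the Hessian of the [0, 1]-scaled
image.  Because typical fluorescence intensities are far below the level
where the structureness term suppresses anything at that γ, the response is
effectively the pure anisotropy measure — which is exactly what makes the
on-ridge/off-ridge contrast sharp on clean data; on noisy data the
small-object filter (below) does the cleanup.

Thresholding mimics a 10-step user slider: slider value *s* maps to the
intensity threshold t = round(25.5·s) (half-up), and a pixel is kept iff
response·255 ≥ t.  The mapping is the simplest monotone map covering the
full 0–255 range.  The default slider is 2 (t = 51): chosen during design
as the lowest setting that keeps the noiseless-background false-positive
rate below 1% while covering planted structures completely; users facing
faint staining should lower it to 1.

8-connected components smaller than `min_object_px` (default 20 px) are
removed; the mask is then thinned with a topology-preserving
skeletonization.  8-connectivity is the single connectivity convention used
everywhere (components, neighbor counts, path steps).

## Branch extraction

Skeleton pixels are classified by 8-neighbor count: 1 = endpoint,
2 = internal, ≥ 3 = junction.  Junction pixels are assigned to **no**
branch; the remaining pixels split into connected components, each ordered
into a path by walking from a tip (axial steps preferred over diagonal ones
so no pixel is skipped).  This makes the decomposition an exact partition:
Σ segment pixels + junction pixels = skeleton pixels, a conservation law the
tests assert.  Note that on a rasterized crossing more than one pixel can
have ≥ 3 neighbors — the arms still split correctly; only the junction
pixel count differs from the idealized single-pixel crossing.

Single-pixel fragments (isolated between junctions) are kept as degenerate
segments with length 0 and undefined orientation; any positive length
filter removes them.

Branch length is the polyline arc length (1 per axial step, √2 per diagonal
step).  Orientation is the principal axis of the path pixel cloud
(total-least-squares line through the second moments), folded into
[0°, 180°), with 0° horizontal and 90° vertical; an endpoint-chord
estimator is available as `branches.chord_orientation`.  The principal axis
was chosen because it is robust to the jagged rasterization of thin
skeletons; a curved branch receives the single global orientation of its
axis, matching the one-angle-per-branch data model.  The length filter is
inclusive (length ≥ threshold survives).

## Parallel grouping

Orientations are axial (period 180°); all angular arithmetic is circular on
the doubled angle, and the group mean is the circular mean.  Grouping is a
deterministic angle-sorted greedy pass: sort branches by orientation (ties
by branch id), seed a group with the first unassigned branch, and let every
later unassigned branch join if its circular distance to the group's
*running* circular mean is within the tolerance (default ±10°).  Greedy
growth against the running mean bounds the within-group spread — transitive
chaining could link 0° to 90° through intermediates.  Singletons are not
groups.  Spatial proximity is measured (`min_distance`, the brute-force
minimum pixel-pair distance) but not used for grouping by default, mirroring
the null model, which is purely angular; an optional `max_pair_distance_px`
cap is available because proximity is biologically meaningful.

## Null model

With *n* branches and alignment probability p = 1/n, group size follows
Binomial(n, 1/n); the expected count of groups of size k is n·P(k) (pmf
evaluated in log space).  The 1/n scaling keeps the baseline from
saturating in dense images.  Three modes:

* **analytic** — real-valued n·P(k); totals use the closed forms
  groups = n(1 − P(0) − P(1)) and lines = n(1 − P(1)).  As n → ∞,
  lines/n → 1 − e⁻¹ ≈ 0.632.
* **integerized** (default) — each n·P(k) rounded *up* to an integer,
  including sizes while n·P(k) ≥ 0.1.  This is the convention for
  tabulated per-image group counts and the simulated parallelism
  percentage: at n = 61 it yields {2: 12, 3: 4, 4: 1, 5: 1} = 18 groups,
  and at n = 109 it yields 31 groups.
* **montecarlo** — seeded replicates; each replicate draws one
  Binomial(n, 1/n) alignment count per branch and histograms them; the
  replicate average converges to the analytic expectations (the tests
  require agreement within three standard errors at 10⁵ replicates).

A uniform random-angle draw (`simulate_random_angles`) is retained as an
exploratory geometric baseline; it is *not* the default because clustering
uniform angles at ±10° saturates as n grows, precisely the density
dependence the binomial model avoids.  The acceptance computations use the
integerized mode throughout, which best matches the tabulated group-count
convention; callers can select the analytic mode where real-valued
expectations are preferable.  The package-default seed for stochastic modes
is 20251031.

Degenerate boundary: at n = 2 the analytic model gives lines = n(1 − P(1))
= 1, i.e. PS = 0.5 (the k = 2 term 2·n·P(2) = 1 agrees with the closed
form).

## Parallelism statistics

PM = Σₖ k·freq[k] / n is the fraction of branches in parallel groups
("group size × frequency" summed, over total branches); PS is the same
under the null model; PMS = PM/PS.  Group-weighted parallelism is
Σₖ k²·freq[k] (each group contributes its size, weighted by its size), so
Σₖ k²·freq[k] ≥ 2·Σₖ k·freq[k] with equality only when all groups are
pairs.  Fractions are stored as fractions and rendered as percentages only
at the reporting boundary.  Cross-image aggregation reports per-metric mean
and sample SD (n − 1 denominator, the common spreadsheet convention) and
ordinary least-squares regressions of measured and simulated line counts
(and weighted sums) on n, with Pearson r.  A constant-y regression is
reported as slope 0, r 0 with a degeneracy flag; constant x across a batch
(identical branch counts) flags the fit as degenerate with slope NaN.  The
Mann–Whitney utility uses the two-sided normal approximation with tie
correction; for samples of ≤ 8 the exhaustive permutation distribution is
used in the tests as the independent oracle (the U statistic must match
exactly; the p-value to within the approximation error).

## Synthetic fixtures

The generator renders anti-aliased bright lines (4× supersampled coverage of
the exact geometry) at ~80% of full intensity on a dim background
(204 vs 20), with optional within-group angle jitter, arc curvature, a
Gaussian point-spread blur (default σ = 0.8 px, emulating a
diffraction-limited microscope), and additive Gaussian noise.  Defaults
emulate the study conditions: 512 px canvas, line widths 2–4 px (inside the
Frangi σ range), lengths ~100–140 px, planted groups of 2–4 branches with
18 px spacing, group base angles separated by more than twice the grouping
tolerance, and distractor angles kept > 2·tolerance from every group and
> tolerance from each other so the ground-truth grouping is unambiguous.
Line placement is rejection-sampled with a minimum line-to-line clearance
(14 px) so branches neither touch nor merge — planted images are
junction-free by design.

The ground-truth pixel mask contains only *fully covered* line pixels;
anti-aliased boundary pixels are excluded because their labeling is
ambiguous at sub-pixel rendering.  Pixel-recovery scores (≥ 95% coverage,
≤ 1% background) refer to that core mask.

What passing these benchmarks shows: the chain of filtering, thinning,
splitting, measuring and grouping is internally consistent and recovers
known geometry exactly in clean conditions and robustly under σ = 10
intensity noise with 5° angular jitter.  What it does not show: performance
on real micrographs with uneven illumination, crossing and touching
branches, intensity variation along branches, or out-of-focus structure —
those require tuning the threshold and length sliders per dataset, which is
why they are exposed.

## Problem sizes and determinism

The test suite and the acceptance script run at the study's own scales
(98 simulated images; Monte Carlo at 10⁵ replicates for n up to 250; 20
noisy fixture seeds for recovery scoring) and complete in a few minutes on
one CPU.  Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); identical seeds give bit-identical images,
tables and CSV exports, which the tests assert byte-for-byte.
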