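# Methods

`icehab` classifies floating glacier ice in vertical aerial photographs of
tidewater glacier fjords into three habitat classes — **icebergs** (connected
ice objects of at least 1.6 m², large enough to support a hauled-out harbor
seal), **brash ice** (ice pieces below 1.6 m², typically object-level
mixtures of ice and water pixels), and **water** — and aggregates per-frame
statistics into survey-level habitat estimates with uncertainty. This note
records the models, parameter choices, numerical conventions, and the open
design decisions the implementation had to settle.

## Scene model and preprocessing

A *scene* is one non-overlapping sampling frame: an RGB image with square
pixels of known ground size, optionally geolocated by its center
latitude/longitude and flying altitude. Frames are standardized to a common
pixel size (default 0.04 m) by bilinear interpolation before
classification; the 1000-pixel iceberg floor is calibrated to that
resolution, and at any other pixel size the 1.6 m² floor governs (the
pixel count is a resolution-specific proxy for the biological constant).
Resampling is applied before enhancement; the order is configurable and
immaterial for the operators used here.

Photographic enhancement is defined by three auditable operators applied
in sequence, emulating the intent (edge and contrast boost) of an
interactive photo-editing recipe that is not reproducible bit-for-bit:

1. linear contrast expansion about mid-gray, `v' = 0.5 + (1+c)(v-0.5)`
   with `c = 0.2` by default (a "+20" contrast slider);
2. a vibrance-style saturation boost weighted by `(1 - s)` so
   already-saturated pixels change little, gain 0.2;
3. an unsharp mask, amount 0.4, Gaussian radius 1.0 px.

All gains are configurable; zero gains are the identity. The intensity
channel of the standard RGB→IHS transform, `I = (R+G+B)/3`, drives all
segmentation: the color channels of fjord scenes are strongly correlated,
and brightness alone separates ice from water.

## Segmentation primitives

**Contrast split.** A binary bright/dark segmentation over a threshold
chosen from 25 evenly spaced candidates between the 1st and 99th intensity
percentiles of the domain (percentile bounds make the grid robust to
outlier pixels; density configurable). The default selection criterion is
the between-class variance `(n_b n_d / n²)(μ_b - μ_d)²` (Otsu), the
canonical formalization of "maximize the contrast between the two
classes". A raw mean difference `μ_b - μ_d` and a ratio objective are
selectable, but the mean difference is maximized at an extreme percentile
cut whenever one class dominates the frame — near-terminus scenes are
~90% ice — which collapses the split; it is therefore not the default.
A **minimum-contrast guard** (default 0.1 intensity units) declares a
domain unsplittable when even the best cut separates bright from dark by
less than the guard. This is the analog of the minimum-contrast parameter
of contrast-split segmentation in commercial OBIA software, and it
matters: without it, a forced split of a near-uniform domain simply cuts
the noise distribution in half, shaving ~30% off every uniform iceberg
and turning percolating noise clusters on all-water frames into spurious
candidates. The rule set maps "unsplittable" to *all dark* on the
scene-level split and *stays whole* on the within-object split.

**Multi-resolution segmentation (MRS).** Bottom-up pairwise region
merging. The cost of merging regions a and b is the growth in weighted
heterogeneity

```
f = (1 - w_shape) Δh_color + w_shape Δh_shape
Δh_color  = Σ_c w_c (n_m σ_m - n_a σ_a - n_b σ_b)
Δh_shape  = w_cmpct Δh_cmpct + (1 - w_cmpct) Δh_smooth
h_cmpct   = n · perimeter / sqrt(n)        (size-weighted compactness)
h_smooth  = n · perimeter / bbox_perimeter (size-weighted smoothness)
```

with perimeter the crack-edge count and bbox the axis-aligned bounding
box. Merging stops when the cheapest merge would cost at least `scale²`.
Operating point: scale 50, shape weight 0.2, compactness 0.5,
4-connectivity, intensity channel only. Heterogeneity is computed with
channels rescaled to the conventional 0–255 reflectance byte range
(`channel_range`, configurable), so `scale` keeps its customary OBIA
magnitude although the package stores floats in [0, 1]: at unit channel
range a threshold of 50² would merge essentially any desk-scale image
into one segment.

*Merge order.* The exact scheduling used by commercial implementations is
unpublished. This package merges strictly lowest-cost-first (a lazy
priority queue with deterministic tie-breaking on (cost, smaller id,
larger id)), which (i) is reproducible and independent of scan order and
seed, (ii) equals a from-scratch greedy re-scan oracle by construction,
and (iii) makes partitions nest exactly across `scale` — a larger scale
only continues the same merge sequence — so segment count is provably
non-increasing in scale. A local mutual-best-fitting schedule was
considered and rejected because its result is scan-order dependent and
need not match the greedy partition. Equivalence with the original
commercial outputs cannot be guaranteed, only the stated cost model.

## Texture and geometry features

**GLCM homogeneity** `Σ_ij P(i,j)/(1+(i-j)²)` over gray-level
co-occurrence pairs. Defaults: 32 quantization levels over the *scene's*
intensity range (global, not per object, so the water threshold is
comparable across objects), the four principal offsets at distance 1,
symmetric counting. Both pixels of a pair must lie inside the object (no
texture bleed across borders). Because the homogeneity weight depends
only on the level difference, the statistic is computed as a weighted
pair mean without materializing the matrix; a batch variant computes all
segments of a label map at once. Objects with no interior pair have
undefined texture and fall to brash, the mixed/ambiguous class. The
quantization depth and offsets are assumptions (the source workflow does
not state them) and are configurable.

**Geometry.** Area is pixel count × pixel area. Perimeter uses the
crack-boundary convention (count of exposed pixel edges × pixel size).
**Angularity** is the ratio of the object perimeter to the perimeter of
the smallest rectangle enclosing the object. "Smallest" is interpreted as
the minimum-perimeter *rotated* rectangle (orientation-invariant;
axis-aligned selectable), fit over the convex hull of pixel centers with
each side padded by one pixel to cover pixel extents. Under these
conventions an axis-aligned filled rectangle scores exactly 1.0 and
raggedness only increases the score, consistent with reported scene means
near 1.8 and maxima near 4.7; a Euclidean contour perimeter would score
convex shapes below 1 and was rejected. Padding also keeps single-pixel
and collinear objects well defined.

## The classification rule set

Per scene, in order:

1. intensity from the (enhanced) RGB frame;
2. contrast split of the non-excluded domain: bright objects become
   candidate icebergs, dark objects stay unclassified;
3. candidate components (4-connectivity, avoiding diagonal leakage
   between brash fragments) below 1000 px / 1.6 m² revert to
   unclassified;
4. MRS of the unclassified domain only (candidate icebergs are not
   re-segmented);
5. per segment: GLCM homogeneity < 0.45 → water, else brash; undefined
   texture → brash;
6. a second contrast split within each candidate component (water objects
   are excluded by construction): dark sub-objects → brash, bright
   sub-components re-filtered by the size floor (failures → brash),
   survivors → icebergs with full geometry.

The second split is the "false iceberg" fix: clusters of sub-1.6 m²
fragments close enough to appear bright pass step 2 as one large object
but break into constituent pieces under their internal contrast. The size
filter is deliberately re-applied after the second split — otherwise
sub-floor bright shards would persist as icebergs, contradicting the
class definition. Degenerate inputs: a constant dark scene classifies as
water/brash with zero icebergs; a fully excluded scene is an error.

The homogeneity rule is implemented exactly as stated in the source
workflow — *below* 0.45 → water — although the standard formula gives
smooth regions homogeneity near 1. The rule is discriminative for real
4 cm imagery, where open water carries fine glint/capillary-wave texture
(low homogeneity) while snow-covered ice surfaces are locally smooth and
bright (high homogeneity); the synthetic generator renders the classes
accordingly.

## Survey statistics, extrapolation, uncertainty

Per-scene percentages are over the non-excluded area and sum to 100;
iceberg size and angularity are means over the scene's iceberg objects
and absent when a scene has none. Survey summaries report mean, SD
(n−1 denominator: sample statistics over sampled frames), maximum, and n
per variable, with equal per-scene weighting. Distance to the glacier
terminus is the minimum point-to-segment distance after an
equirectangular projection about the terminus' mean latitude (adequate at
fjord scale; no map projections beyond this).

Fjord-wide iceberg area is `mean_iceberg_pct/100 × fjord_area_km2 × 10⁶`
m². Its uncertainty combines a classification component (fraction of
iceberg area lost to misclassification as brash; default 0.26) and a
frame-edge scale-distortion bound (default 0.07, an input rather than a
derived quantity — the pinhole-geometry derivation depends on unstated
camera details) in quadrature: 0.26 ⊕ 0.07 = 0.2693, reported as 27% at
the default 2-decimal rounding. Quadrature is used because the sources
are independent and an arithmetic sum (33%) is inconsistent with the
combined figure the workflow is known to produce.

Representativeness of the sampled frames is checked by repeated seeded
subsampling (default 100 trials of 40 frames, without replacement within
a trial) of the mean iceberg percentage. The analytic standard error of
the survey mean is computed as the SD of per-scene iceberg fractions over
√n — the formula is an assumption, as the source states the value but not
the estimator. Cover maps are gridded by exact radial-basis-function
interpolation (thin-plate spline default): the surface passes through
every measured point and may over/undershoot between points.

## Accuracy assessment

Up to 100 random points per class are sampled, seeded and without
replacement, stratified by the *reference* map by default ("where that
class was present"; stratification by the classified map is selectable —
the source phrasing is ambiguous about which map defines presence). The
classified-by-reference confusion matrix yields overall accuracy,
producer's (column recall) and user's (row precision) accuracies,
commission/omission as their complements, and Cohen's κ
`(p_o - p_e)/(1 - p_e)` with `p_e = Σ row_i col_i / N²` (undefined and
reported absent when p_e = 1). Classes may be collapsed (e.g. both ice
classes into "ice") with the grand total preserved. Percentages are
reported to 1 decimal and κ to 2, matching the precision of the published
figures. No κ variance estimate and no area-weighted accuracy adjustment
are provided.

## Synthetic scenes

The generator emulates the *structure* of the survey imagery, not its
photometry: dark water (mean intensity 0.15) with a smooth illumination
gradient (amplitude 0.03) and per-pixel glint noise (SD 0.05, enough to
keep water's co-occurrence homogeneity below the 0.45 threshold); brash
fragments near intensity 0.70 (noise SD 0.015); icebergs near 0.85 (noise
SD 0.01) as radially perturbed ellipses whose Fourier roughness parameter
monotonically raises expected angularity; a small optical blur
(σ = 0.4 px). Default frame geometry matches the survey frame (2018 ×
3045 px at 0.04 m ≈ 80.7 × 121.8 m); default composition is mid-fjord
(45% brash, ~36 icebergs lognormal about a 5.7 m² mean, truncated to
[2.5, 1000] m²). Across a survey, brash coverage follows a terminus-
distance gradient decaying from ~0.90 at the calving face to ~0.02 at
11 km.

Brash fragments are placed one per jittered grid cell with a one-pixel
empty boundary between cells, as squarish superellipses whose fill rises
with the requested coverage. This guarantees that every connected brash
component stays below 1.6 m² — without the moat, overlapping fragments
coalesce into connected ice pieces above the floor, which *are* icebergs
by the class definition, making the ground truth self-contradictory —
while still allowing near-melange coverage (~0.93 maximum). Icebergs are
kept disjoint by a 2-px moat where space allows. Ground truth (class map
and object table, derived from the same map so areas agree exactly) is
recorded before noise; everything is bit-reproducible from the seed.

What the generator does **not** model: sun glint lobes, sediment-covered
or dark ice, melange, shadows, seals, wave structure beyond white noise,
or frame-edge perspective distortion. Passing recovery tests therefore
demonstrates the correctness of the machinery on scenes whose classes are
photometrically separable, not field-level performance; the published
field accuracy figures (overall 75.6%, κ 0.63) are reproduced from the
published confusion-matrix counts, not re-measured.

## Problem sizes and numerical choices

Desk-scale runs (tests, the acceptance script) use 200 × 300 px frames
at 0.04 m with 3 icebergs and 20% brash — the package's chosen default
experiment size; the generator accepts full survey-frame dimensions.
Oracle equivalence for the region merger is checked on 8 × 8 images
against a from-scratch greedy implementation, and for the threshold
search on 16 × 16 two-component mixtures against exhaustive scan over
distinct intensities. Ties in the merge queue break on (cost, smaller id,
larger id); contrast-split ties break toward the lower threshold;
segment labels are renumbered in row-major order of first occurrence.
RBF interpolation requires ≥ 3 non-collinear points and rejects
duplicate points with conflicting values. Label rasters are paletted PNG
with palette index = class code (0 excluded, 1 water, 2 brash,
3 iceberg), so write/read round-trips are bit-exact.

## Known limitations

- MRS is a pure-Python region merger: ~5 s for a 10⁵-pixel domain.
  Full-resolution survey frames (6 × 10⁶ px) are out of its comfortable
  range; standardizing to a coarser pixel size first is the practical
  path (the m² floor adapts automatically).
- The contrast-split and MRS cost models match the stated formulas, not
  any particular commercial implementation's unpublished details.
- Geolocation handling is a local equirectangular approximation; no
  geodetic datum handling, no GeoTIFF georeferencing on outputs (label
  rasters are plain PNG; polygons are GeoJSON in scene-local meters).
- Accuracy metrics assume point samples are independent; no spatial
  autocorrelation correction.
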