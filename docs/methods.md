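# Methods

This note documents the measurement conventions, the synthetic-data
model, and the numerical choices behind `mitoshape`, in the spirit of a
methods appendix: what is computed, under which assumptions, and what the
passing tests do and do not demonstrate.

## Coordinate and angle conventions

All geometry lives in physical micrometres in a right-handed frame
(x right, y up) with angles counter-clockwise from +x.  Outlines imported
from image-convention sources (y down) are flipped on read; the reader
requires the convention to be declared (`y_convention="math" | "image"`)
and refuses files without it.  Orientation-like quantities are axis-like,
not direction-like: shape orientations are folded to [0, 180), and every
tilt or difference angle (spindle tilt, plate angle, spheroid division
angle) to [0, 90].  Folding makes all angle outputs invariant to swapping
segment endpoints, to the sign of the out-of-plane coordinate, and to
joint rigid rotation of both compared directions.

## Intrinsic-shape comparison

Footprints are simple polygons; overlap is computed on binary rasters.
A pixel is foreground iff its center lies inside the footprint under a
half-open even-odd rule (centers exactly on an edge count on the
lower/left side, implemented by nudging the test point +1e-6 px in x and
y).  The half-open rule keeps abutting shapes tiling without double
counting and avoids the systematic row/column dropout that a strict
interior rule suffers when axis-aligned edges coincide with the pixel
lattice.  The working pixel size defaults to (bounding-circle diameter
of the compared footprints) / 256, so resolution adapts to cell size; at
that pitch raster areas agree with polygon areas to well under 2 %.

Alignment removes up to three nuisance contributions, in a fixed order:

1. **area** — the moving footprint is scaled by √(area_ref / area_mov)
   about its own centroid (areas are exact polygon areas, so the scaled
   areas match exactly);
2. **displacement** — it is translated so the centroids coincide;
3. **orientation** — it is rotated about the common centroid to maximize
   the Jaccard index.

The rotation search evaluates a 2° grid over [0, 360), augmented with the
two candidates implied by the central-moments orientations of the two
shapes (θ_mov − θ_ref and that + 180°), then refines ±2° around the best
candidate at 0.1° steps.  The coarse pass runs at twice the working pixel
size (one quarter of the pixels) for speed; refinement runs at full
resolution.  Ties are broken toward the smallest non-negative angle, so a
shape with an n-fold symmetry reports the smallest equivalent rotation.
All transforms are applied to polygon vertices — exactly, with no raster
interpolation — and rasterization happens once per candidate angle.

The reported `rotation` is the detected misorientation of the moving
footprint relative to the reference: aligning requires rotating the
moving footprint by −rotation, so a copy of the reference rotated by +30°
reports 30°.  The reported dissimilarity is the normalized Jaccard
distance 1 − J; the absolute non-overlap area (µm²) is exposed as a
secondary field for users who want the unnormalized quantity.  The
normalized form is the default because it is comparable across cells of
different sizes, consistent with the area equalization built into the
alignment itself.

Multi-part footprints (the union of two daughter cells) are handled
throughout: areas and centroids come from the exact polygon union, parts
are transformed jointly, and rasters are combined by logical OR — never
by summation, which would double-count overlapping regions.

Shape orientation comes from second-order central moments:
θ = ½·atan2(2µ11, µ20 − µ02).  For outlines the moments are exact polygon
integrals (closed-form shoelace-type sums), for masks they are pixel
moments; the two agree to within rasterization error.  When the principal
moments are nearly equal (eigenvalue gap < 1 % of the trace — discs,
squares) the orientation is degenerate and reported as 0 by convention,
so raster noise cannot inject arbitrary angles into the seeded rotation
candidates.

## Event-anchored exit metrics

The timing convention is explicit because "anaphase onset" is annotated
on discrete 5-min frames.  Under the default `first_elongation`
convention the onset anchor is the first frame with visible anaphase
elongation, the metaphase reference is the frame immediately before it,
and every "+k min" offset counts from the anchor; the alternative
`frame_before` convention shifts the anchor one frame earlier.  Offsets
resolve to the nearest frame and are accepted only within half the frame
interval — no metric silently substitutes a frame outside that window; a
missing frame raises an error naming the offset, and cohort-level code
records the event as censored rather than inventing a value.

Per-event metrics: respread ratio (union daughter area at +10 min /
metaphase area); daughter area ratio (larger/smaller at +20 min, ≥ 1 and
invariant to labelling) with asymmetry iff ratio ≥ 2 (the boundary counts
as asymmetric); metaphase Feret length (maximum caliper distance over
convex-hull vertices); consecutive-frame intrinsic dissimilarity along a
track together with the raw component series (area ratio, centroid
displacement, folded orientation change); and the mother-similarity
series, which aligns the daughters' union footprint onto the mother
reference shape (at NEB − 15 min; when NEB is unknown an explicit opt-in
falls back to 15 min before the metaphase reference and the result is
flagged).  The single-step 15→20 min dissimilarity used for group
comparisons is the individual series step, not a window average; callers
that prefer a window can average the series themselves.

## Division-orientation metrics

Spindle poles are consumed as already-projected planar (x, z)
coordinates; there is no 3-D pole fitting.  Tilt is |atan2(Δz, Δx)|
folded to [0, 90].  The per-track summary reports the tilt at +21 min by
the nearest-frame rule, cumulative tilt change Σ|Δθ| from the first frame
of the track (track start is an upstream curation decision), and a
misorientation flag using a strict > 30° threshold, evaluated at +21 min
when the track reaches it and at the last available frame otherwise.
The threshold is configurable (e.g. for classifying perpendicular
divisions on soft substrates); no numeric cut-off is imposed on
monolayer plate angles, which are reported raw.

The spheroid division angle takes the radial axis literally as the line
from the spheroid centroid through the dividing cell's position (only the
direction matters, so extending it to the boundary changes nothing), and
reports the folded difference between that axis and the chromosome axis.
It is invariant under rigid motion and uniform scaling of the whole
frame.

## Rank-sum test and cohort summaries

U counts pairs (a, b) with a > b plus half the tied pairs.  For
n_a + n_b ≤ 12 with no ties the two-tailed p is exact: the null
distribution of U is built by the classical recurrence
N(u; i, j) = N(u − j; i − 1, j) + N(u; i, j − 1) and the p value is the
null probability of a U at least as far from n_a·n_b/2 as observed.
Larger or tied samples use scipy's tie-corrected normal approximation;
the result records which method ran.  p values are reported raw — no
multiple-testing correction — and any significance stars are a
presentation-time concern, not part of the statistics.

Cohort summaries compute fractions and metric means per independent
experiment first and then mean ± SD across experiments (SD reported as
not-applicable for a single experiment); per-cell distributions are kept
for the rank tests.  Cells with missing metrics are excluded and counted,
and conditions with zero usable cells are flagged rather than dropped.

## Synthetic-data model

The generator is phenomenological: footprints are star-shaped polygons
whose radial profiles (64 boundary vertices) interpolate between
programmed start and end states.  It emulates the study conditions —
5-min footprint cadence, 3-min spindle cadence, a mother observed from
15 min before NEB through rounding to a metaphase disc, daughters
observed to +30 min — with every phenotype parameter explicit:

- **asymmetry_prob** — probability a division is asymmetric; asymmetric
  ratios are drawn uniformly from `asym_ratio_range` (default (2, 4)),
  symmetric ones from `sym_ratio_range` (default (1, 1.8)).
- **respread_gain** — combined daughter area at +10 min relative to the
  metaphase area (default 1.5 control / 1.8 ras-like; the ras-like value
  is higher because accelerated respreading is part of that phenotype).
  The combined-area curve is a saturating exponential (τ = 6 min) pinned
  to the gain at exactly +10 min.
- **memory_fidelity** ∈ [0, 1] — the fraction of daughter respreading
  confined to the mother footprint.  At fidelity 1 the daughter targets
  are the two parts of the mother polygon split perpendicular to the
  division axis, offset so the part areas realize the programmed ratio,
  and shrunk by a 7 % margin so daughters respread just inside the mother
  edge; at fidelity 0 they are displaced random shapes.  Intermediate
  values blend the radial profiles and centers linearly (blends of
  star-shaped profiles stay star-shaped, hence simple).  Post-anaphase
  motility drift scales with (1 − fidelity): full shape memory is
  anchored to the footprint, no memory drifts freely.
- **shape_noise** — per-frame smoothed radial perturbation.  After noise,
  every daughter polygon is rescaled to its exact target area, so the
  programmed daughter ratio is realized exactly at every frame and
  recovery tests measure the pipeline, not generator slack.
- Daughters are kept disjoint by separating them along the division axis
  whenever their polygons intersect (translation preserves the exact
  areas), so the measured union area equals the programmed combined area.
- Infeasible parameter combinations (fidelity 1 with a combined daughter
  area exceeding the mother footprint) raise a configuration error
  instead of silently violating the containment contract.

Spindle tracks realize the folded-angle process
θ_{t+1} = fold₉₀(max(0, θ_t − correction_rate) + noise) as pole
coordinates at a fixed 10 µm pole separation, so the pipeline's angle
measurement inverts the construction exactly (errors ~1e-13°).  Spheroids
are three-lobed perturbations of a circle whose lobe amplitude grows at a
rate set by the circularity drift (strictly decreasing circularity for
negative drift) while the area grows exactly by the programmed per-frame
rate; each frame places a division whose chromosome axis sits at a
programmed angle to the *measured* centroid-periphery axis, so the
pipeline recovers the programmed angles exactly.

Randomness is counter-based: each event draws from
`default_rng([seed, event_id])`, so cohorts are order-independent,
partially regenerable, and byte-identical across runs; the manifest
records every realized ground-truth value.  The two presets differ in
asymmetry probability (0.03 vs 0.37), memory fidelity (0.9 vs 0.3),
respreading gain, shape noise, motility and initial tilt distribution.
These values are motivated by the qualitative contrast between
unperturbed and acutely oncogene-activated epithelial cells; they are
deliberately not calibrated reproductions of any particular dataset, and
cohort-level numbers measured on them characterize the generator, not
real cells.

**What passing tests show.**  On synthetic cohorts the pipeline recovers
programmed daughter ratios to ~1e-13, asymmetric fractions within
binomial sampling error, spindle angles exactly, and mother-similarity
means strictly ordered by memory fidelity.  This validates the
measurement code end to end.  It does not validate segmentation quality,
tracking errors, out-of-focus frames, or cell shapes outside the
star-shaped family the generator produces; real outlines with deep
concavities exercise the same code paths (nothing assumes star
convexity) but are not covered by the generator's ground truth.

## Problem sizes and runtime choices

Default cohort analyses run 200-event cohorts for fraction/ratio
recovery and 15–25 events per condition where each event needs a full
alignment (~0.4 s each at the default 256-pixel resolution).  The
exhaustive-rotation cross-checks run at 128-pixel resolution, where the
pixel-count objective is still within 1 % of the exact polygon value.
These sizes give sampling errors far below the tolerances being checked
while keeping the full suite in a few minutes on one core.

## Known limitations

- The Jaccard maximization is over rotations only, as defined; reflected
  (chiral) shape matches are not searched.
- The rotation objective can plateau: two angles within ~0.005 J of each
  other may both be reported as maximizers by equally valid searches; the
  Jaccard value itself is stable to < 0.005 across such ties.
- Rasterization error grows linearly with pixel size; users overriding
  the default resolution below ~64 px per diameter should expect > 2 %
  overlap error.
- The generator does not model cell–cell contact, retraction-fiber
  mechanics or signalling; it produces controlled geometry, nothing more.
- `mother_similarity` compares the daughter union to a single mother
  reference frame; it does not track mother shape over time.
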