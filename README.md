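# mitoshape

Quantitative shape, respreading and division-orientation analysis for
dividing cells.

When an adherent cell enters mitosis it rounds up, divides, and its two
daughters respread onto the substrate — classically re-occupying the
mother cell's interphase footprint under the guidance of retraction fibers.
Perturbations of actomyosin contractility and substrate adhesion (for
example by acute oncogene signalling) disturb this choreography: daughters
respread asymmetrically, the mitotic spindle tilts out of the substrate
plane, and divisions in monolayers and spheroids lose their normal
orientation.  `mitoshape` measures all of this from tracked cell outlines
— it consumes manual or automated segmentations (polygons), never raw
images.

## What it computes

**Intrinsic-shape Jaccard (dis)similarity.**  Two footprints A and B are
compared by their raster overlap, J = |A∩B| / |A∪B|, after removing the
contributions that are not shape: the moving footprint is scaled by
√(area_ref / area_mov) about its centroid, translated so the centroids
coincide, and rotated about the common centroid to the angle that
maximizes J (2° search grid seeded with the central-moments orientations,
refined to 0.1°).  The residual dissimilarity D = 1 − J then reflects
intrinsic shape change only.  The same machinery compares the union
footprint of two daughters against the mother reference shape (taken
15 min before nuclear envelope breakdown).

**Respreading dynamics.**  All exit metrics are anchored on anaphase
onset: the respread ratio (combined daughter area at +10 min / metaphase
area), per-step shape change between consecutive 5-min frames, the
daughter area ratio (larger/smaller, at +20 min) with symmetry
classification (asymmetric iff ratio ≥ 2), and the metaphase Feret
(maximum caliper) length.

**Division orientation.**  Spindle tilt is the unsigned angle between the
pole–pole axis and the substrate, folded into [0, 90]°; the package
reports per-frame tilt series, the tilt at +21 min, misorientation (> 30°)
and the cumulative tilt change Σ|Δθ|.  For monolayers it measures the
metaphase-plate angle (in-plane division ⇒ plate ⊥ substrate ⇒ ≈ 90°);
for spheroids, the division angle between the chromosome axis and the
centroid-to-periphery axis through the dividing cell, plus spheroid area
and circularity (4π·area / perimeter²).

**Statistics.**  Two-sample comparisons use the two-tailed Mann–Whitney
rank-sum test with exact enumeration for small samples (n_a + n_b ≤ 12,
no ties) and a tie-corrected normal approximation otherwise.  Cohort
summaries follow the per-experiment convention: fractions and means are
computed within each independent experiment, then reported as
mean ± SD across experiments.

**Synthetic data.**  Because measurements of this kind are made on
unpublished time-lapse footage, the package ships a fully deterministic
generator of division events (rounding → division → respreading
footprints), spindle-tilt trajectories and spheroid time-lapses, with
every phenotype parameter controllable (asymmetry probability, daughter
ratio, shape-memory fidelity, respreading gain, tilt dynamics,
circularity drift) and recorded in a sidecar manifest.  Two presets —
`control` and `ras_like` — encode the contrast between unperturbed
epithelial cells and an acute oncogenic-signalling phenotype.

## Worked example

```python
import mitoshape as ms

# a random cell footprint and a scaled/rotated/translated copy of it
shape = ms.generate_shape(48, 0.3, seed=7, radius=20.0)
moved = shape.transformed(scale=1.4, rotation_deg=25.0, translation=(12.0, -8.0))
res = ms.align_intrinsic(shape, moved)
print(f"jaccard        = {res.jaccard:.3f}")
print(f"dissimilarity  = {res.dissimilarity:.3f}")
print(f"scale_factor   = {res.scale_factor:.3f}")
print(f"rotation       = {res.rotation:.1f} deg")
```

```
jaccard        = 1.000
dissimilarity  = 0.000
scale_factor   = 0.714
rotation       = 25.0 deg
```

The copy differs from the original only by a similarity transform, so the
intrinsic comparison recovers it exactly: overlap 1.0 (no shape change),
the scale factor 1/1.4 that equalizes the areas, and the 25° rotation.

```python
import numpy as np
cohort = ms.generate_cohort("ras_like", n=50, seed=1)
ratios = [ms.daughter_area_ratio(ev) for ev in cohort.events]
frac = np.mean([ms.classify_symmetry(r) == "asymmetric" for r in ratios])
print(f"asymmetric fraction = {frac:.2f} (programmed 0.37)")

r = ms.rank_sum_test([1.34, 1.52, 1.48], [1.81, 1.95, 2.10])
print(f"rank-sum U={r.u}, p={r.p:.3f} ({r.method})")
```

```
asymmetric fraction = 0.36 (programmed 0.37)
rank-sum U=0.0, p=0.100 (exact)
```

The measured asymmetric fraction of a 50-event `ras_like` cohort tracks
the programmed asymmetry probability, and the fully separated 3-vs-3
rank-sum example gives the exact two-tailed p of 2/20 = 0.1.

## Command line

```bash
mitoshape simulate ras_like --n 30 --seed 1 --outdir out/
mitoshape respread out/outlines.csv out/events.csv --out out/metrics.csv --condition ras_like
mitoshape spindle out/spindles.csv --out out/spindle.csv --condition ras_like
mitoshape report out/metrics.csv --spindle-metrics out/spindle.csv --out out/summary.json
```

`compare`, `monolayer` and `spheroid` subcommands cover single-pair
alignment, metaphase-plate angles and spheroid morphometrics.  Every run
writes deterministic outputs and a plain-text log.

## Layout

- `mitoshape.geometry` — outlines, masks, rasterization, moments
  orientation, Feret, circularity, Jaccard
- `mitoshape.align` — intrinsic-shape alignment (scale → translate →
  rotate-to-maximize-J)
- `mitoshape.respreading` — event-anchored exit metrics
- `mitoshape.orientation` — spindle, monolayer and spheroid angles
- `mitoshape.synthetic` — ground-truth generators and presets
- `mitoshape.io` — CSV/JSON/TIFF dialects
- `mitoshape.stats` — rank-sum test, cohort summaries
- `mitoshape.pipeline`, `mitoshape.cli` — cohort-level chaining and the
  `mitoshape` command

See `docs/methods.md` for the full description of the measurement
conventions, generator design and numerical choices.
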