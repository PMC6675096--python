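# Methods

## The measurement problem

Internalized peptide–drug conjugates (PDCs) appear in fluorescence
microscopy as punctate vesicular signal that, depending on linker chemistry
and trafficking route, either stays distributed through the endosomal system
or aggregates over time toward a subcellular focus. That focus can be
anywhere in the cell and is usually not fluorescently marked, so generic
readouts referenced to the cell centroid, the nucleus, or the distance from
the membrane do not track the phenotype. spotspread implements a per-cell
statistic referenced to the signal itself.

## The dispersion statistic

For one segmented cell with payload spot mask `S` (a set of pixel centers):

```
c  = (1/|S|) Σ_{x∈S} x                  (unweighted mask centroid)
D  = max_{u,v ∈ cell} ||u − v||          (cell diameter, exact)
d̄  = (1/|S|) Σ_{x∈S} ||x − c|| / D      (dispersion)
```

Properties that the tests verify rather than assume:

* `d̄ ∈ [0, 1]` whenever defined — every cell point is within `D` of the
  centroid, which lies in the convex hull of `S`;
* a single-pixel mask gives exactly 0;
* `d̄` is invariant under translation and rotation (up to pixelation,
  bounded at 2% for cells ≥ 30 px across) and under uniform rescaling up to
  the same pixelation tolerance;
* spots drawn uniformly over a disk give `d̄ → 1/3` as the spot count grows
  (mean distance to the center of a uniform disk is `2R/3`, diameter `2R`).

Decisions where the construction was genuinely open, and why:

* **Points are pixel centers of the binary masks**, not connected-component
  centroids and not intensity-weighted: the statistic operates on the
  thresholded mask, so every mask pixel contributes equally.
* **The centroid is unweighted** for the same reason — thresholding happens
  before geometry.
* **Cell diameter is exact**, computed by reducing the cell's pixel set to
  its convex hull and taking the maximum over hull-vertex pairs (O(h²) on
  h hull vertices, equivalent to rotating calipers and exact). Degenerate
  (e.g. collinear) point sets fall back to the O(n²) maximum. Approximating
  the diameter by, say, twice the equivalent radius would break the [0, 1]
  bound.
* **Undefined, never zero.** Cells with an empty spot mask (or below the
  `min_spot_px` cutoff, default 1) carry NaN dispersion and are excluded
  from aggregation. Imputing 0 would report "no signal" as "fully
  aggregated signal".
* Analysis is strictly 2D per plane; confocal stacks must be reduced
  upstream.

## Membrane-band comparator

The baseline that generic pipelines provide: the Euclidean distance
transform of the cell mask is split into `n_bands` (default 4) equal-width
bands, band 4 adjacent to the membrane and band 1 the deepest interior, and
the spot-pixel-weighted mean band index is reported. It is bounded in
[1, 4] by construction. Equal-width bands of the per-cell EDT range are the
standard construction; because the reference is the membrane rather than
the signal, this measure cannot distinguish aggregation toward an arbitrary
focus from mid-depth occupancy — which is exactly the contrast the
dispersion statistic exists to expose.

## Segmentation

Standard high-content chain, deliberately plain:

* **Nuclei**: Gaussian smoothing (`smooth_sigma`, default 2 px) → global
  Otsu threshold → hole filling → distance-transform watershed with
  shallow-peak suppression (`h_minima_depth`, default 2 px) to split
  touching nuclei → area filter (`min_area` 40 px², `max_area` 10⁵ px²) →
  contiguous relabel. Blank images yield zero objects, not errors.
* **Cells**: marker-controlled watershed over the inverted smoothed
  cell-body intensity, seeded by the nuclei, restricted to the union of the
  body-channel Otsu foreground and the seeds; cell `i` therefore contains
  nucleus `i` entirely and cells partition the seeded foreground.
* **Spots**: Otsu's threshold computed *independently per cell* over that
  cell's own intensities (256-bin histogram spanning the cell's range),
  keeping pixels strictly above the threshold. Per-cell application makes
  the mask invariant to per-cell affine intensity rescaling and independent
  of every other cell's brightness. Cells with constant intensity or fewer
  than `min_cell_pixels` (default 8) pixels get an empty mask: no evidence,
  no spots.

Conventions fixed for reproducibility: 4-connectivity for thresholded
components, 8-connectivity within watershed regions; border-touching cells
are kept but flagged `on_border` (an `exclude_border` option drops them).

## Workflow engine

Modules declare typed input/output slots (`image`, `labels`, `table`) and
their tunable parameters with ranges and defaults; workflows are validated
DAGs over those slots. Execution is cached by digest: a node's key hashes
its name, effective parameters and all upstream digests, so an identical
re-run executes nothing, a parameter change re-executes exactly the
affected subgraph, and requesting an intermediate output runs exactly its
ancestor set. This is what makes interactive parameter tuning cheap (the
CLI `tune` command renders before/after label overlays through exactly this
path). Caching is in-memory per runner (a cache dict can be shared across
runners); nodes are assumed pure. Execution is single-threaded; batch-level
parallelism across images is the intended scaling direction, not node-level
parallelism inside one field's graph.

## Synthetic data: what it emulates, and what it does not

Each field contains non-overlapping disk cells (radius 16–22 px in a
256×256 default frame) with a concentric nuclear disk (0.4× radius), a flat
cell-body stain, and a payload channel of Gaussian-profile spots (amplitude
600, width 1.2 px over background 100, plus additive Gaussian noise σ = 8
and optional Poisson shot noise). Spot centers follow an isotropic Gaussian
around a per-cell focus — drawn anywhere within 35% of the radius, modeling
aggregation toward an unmarked compartment — truncated to the cell
interior. The standard deviation `spread` is the single ground-truth dial
from fully aggregated (0) to near-uniform (≈ radius). A `uniform_spots`
mode samples exactly uniformly (the closed-form reference case), and an
`exclude_frac` option removes a central disk from the support, modeling
cytoplasmic vesicles excluded from the nucleus. Nuclear exclusion matters
quantitatively: a truncated unimodal cloud cannot exceed dispersion ≈ 0.28
for this geometry, and the high dispersion of widely distributed vesicles
in real cells (≈ 0.35) arises precisely because the signal avoids the cell
center. Intensity levels were chosen once to give cleanly bimodal
histograms so that the default segmentation succeeds; fixtures exist to
exercise the pipeline, not to defeat it.

Deliberately not modeled: optics (PSF beyond the Gaussian spot profile,
vignetting), photobleaching, cell shape irregularity, cell crowding and
overlap, and segmentation-hostile contrast. Passing tests therefore
demonstrate the correctness of the measurement chain and its statistical
behavior under known ground truth — not robustness of the segmentation to
difficult real-world imagery, which must be assessed per assay.

All randomness flows from one seed; per-image seeds are spawned
deterministically, and identical parameters plus seed give bit-identical
images.

### The Monte-Carlo oracle

`expected_dispersion_mc` simulates the dispersion statistic at exact
geometry — spot centers as points, cell diameter `2R` — bypassing
rendering, thresholding and segmentation. It is the independent reference
for parameter-recovery checks (measured vs expected per-cell dispersion,
Pearson r > 0.9 across a 10-level spread grid) and is inverted by bisection
(`spread_for_dispersion` / `condition_for_dispersion`) to design conditions
with prescribed expected dispersion. The oracle shares only the spot-center
sampler with the renderer; everything it predicts about the pipeline is
measured through images.

## Aggregation and statistics

Cell-level dispersion is averaged per (well, timepoint), pooling all of a
well's cells by default (`per_image_then_well` averages fields first; the
two coincide when field cell-counts are equal, and both are exposed for
sensitivity checks). Undefined cells are excluded and `n_cells` is
recorded; aggregation conserves the defined-cell count.

Condition comparison uses a mixed repeated-measures ANOVA with wells as
subjects — wells are the independent experimental units of a plate assay —
timepoints as the categorical within-subject factor, and condition as the
between-subject factor. The headline statistic is

```
F = MS_condition / MS_wells-within-condition,
df = (a − 1, N − a)
```

from the standard sum-of-squares partition (the full table with the
within-subject timepoint and interaction effects is also returned).
Requirements: ≥ 2 wells per condition and a balanced timepoint window;
unbalanced input raises with the instruction to restrict the window rather
than silently dropping data. No sphericity correction is applied by default
(the between-subject F does not involve the within-subject error); a
Greenhouse–Geisser epsilon for the within-subject effects is available as
an option. The implementation is the explicit partition, cross-checked in
tests against an independent hand computation and against
`pingouin.mixed_anova`.

Calibration is simulated, not assumed: under a zero-effect random-intercept
null (μ = 0.3, between-well σ = 0.02, residual σ = 0.01 — dispersion-scale
values), the empirical type-I error at α = 0.05 over 500 replicates falls
in the binomial band [0.02, 0.09]; power for separating conditions designed
at expected dispersions 0.15 vs 0.35 (4 wells/condition, 4 timepoints,
30 cells/well) exceeds 95% at α = 0.01 over 100 replicates. Power
replicates draw per-cell dispersions from the generative point model
rather than rendering 100 full plates: the test's subject is the
statistical design, and the fidelity of the imaging chain is established
separately by the parameter-recovery check. One full image-level plate
comparison is still run end to end in the CLI test and the acceptance
script.

## Problem sizes and numerical choices

Default verification sizes: the spread grid uses 10 levels × 5 fields × 10
cells (500 cells through the full pipeline); diameter and threshold oracle
checks use 50 blobs and 10 bimodal samples; the uniform-disk check uses
2000 spots × 200 replicates. These sizes give stable statistics at desk
scale; all are parameters, not constants.

Ties at the flat optimum of the between-class variance are accepted as
equivalent thresholds (agreement is asserted on attained variance, not on
the argmax bin). Dispersion comparisons across rasterizations use a 2%
pixelation tolerance. Degenerate inputs are defined, not special-cased
away: blank images segment to zero objects, constant cells get empty masks,
empty masks give NaN dispersion, and NaN never participates in a mean.

## Known limitations

* 2D only; no z-stacks, no 3D dispersion.
* No cell tracking: timepoints are independent acquisitions, and the
  repeated-measures structure lives at the well level.
* The filename-pattern parser covers generic nested folders; vendor
  metadata (Yokogawa XML, Bio-formats) is out of scope.
* Per-vesicle measures (counts, sizes, colocalization) are not computed;
  the statistic deliberately reduces each cell to one number.
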