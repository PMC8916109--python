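# Methods

This note documents the models and procedures implemented by
`fieldmapper`, the assumptions behind them, the tunable parameters and
their defaults, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the underlying methodology
leaves details open.

## Grids

Three nested geographic grids share one origin: tiles (0.05°), primary
cells (0.005°) and pixels (0.000025°, ≈2.8 m at the equator — the native
resolution of the daily imagery the method targets).  Cells use half-open
intervals `[lo, lo+size)` with the origin at the south-west corner and row
indices increasing northward, so point-in-cell assignment is unambiguous,
every pixel belongs to exactly one primary cell and one tile, and a
default primary cell is exactly 200×200 = 40,000 pixels.  The grid is
plain lon/lat with degree-denominated sizes; no map projection is applied.
Areas are converted to hectares with a latitude-dependent local scaling
(111,194.9 m per degree of arc, longitude scaled by cos φ), which is
accurate to well under 1% at the scales involved.

## Seasonal compositing

Per pixel, band and season the composite is the weighted mean
`B̄ = Σ B_t W1_t W2_t / Σ W1_t W2_t` over valid in-window dates, with

* haze weight `W1_t = 1/blue_t²` — haze and cloud raise blue reflectance,
  so bright-blue dates are suppressed quadratically;
* shadow weight `W2_t = 1/NIR_t⁴` when `NIR_t` is below the pixel's
  in-window median NIR, and 1 otherwise.

Numerical choices: reflectance is unitless surface reflectance on [0, 1]
(scaled-integer inputs must be divided by their scale factor first — both
weights are scale-sensitive); zero reflectance is clamped at ε = 1e-4
before division; the median uses the midpoint convention for even counts
and is computed over valid in-window dates only; pixels with no valid date
are nodata.

The shadow weight deserves a caution it receives nowhere else: taken at
face value, `1/NIR⁴` *increases* the weight of dark (below-median-NIR)
dates, the opposite of suppressing cloud shadow.  The formula is kept in
that form as the default (`shadow_weight_mode="as_printed"`) because it is
the form the method states; a `"dark_downweight"` mode (`W2 = NIR⁴`)
implements the stated intent.  With the default, a pixel shadowed on any
date can be dominated by that date; the haze weight still removes clouds,
which is the numerically dominant artifact.

Composite quality bookkeeping stores four 0–3 grades (cloud, shadow, seam
artifacts, resolution degradation) and the rescaled score (sum/12).  The
grades are human judgments; the package stores and aggregates them, it
does not infer them.

## Synthetic data

The generator produces, from a single seed: a field mosaic, daily scene
stacks, and simulated labellers — always together with the ground truth
(true polygons, clean imagery, cover raster), so every downstream stage
has a parameter-recovery oracle.

*Landscape.* A Poisson point process, thinned by a hard-core rule with
lognormal radii (`size_sigma = 0.45`) to spread field sizes, induces a
Voronoi tessellation clipped to the domain.  Cells are assigned to annual
cropland greedily until the target area fraction (default 0.30) is
reached; remaining cells are natural vegetation or bare ground
(`bare_fraction = 0.25` of non-crop).  Default intensity is 64 fields per
0.05° tile.

*Spectra.* Each cover has a growing- and a dry-season 4-band spectrum.
Cropland and vegetation nearly coincide in the growing season; cropland
and bare ground converge in the dry season — the classes separate mainly
through the seasonal *contrast*, which is the rationale for two-season
features.  Between-season reflectance is interpolated with a cosine in
day-of-year (0 at mid-July, 1 at mid-January).

*Ambiguity.* Each field carries a mixing coefficient toward the opposing
cover.  Fields inside a randomly oriented "ecotone" band (relative width
0.12) take a strong but consistent shift (0.85–1.0 × `max_mix = 0.7`);
background fields take mild Beta(2,5)-distributed mixing (≤ 0.3 ×
`max_mix`).  This concentrates genuinely hard, *learnable* cases in one
region of each landscape — the transition-zone structure on which
uncertainty-guided labelling pays off — while keeping some irreducible
overlap everywhere.  With a flat ambiguity field the demo task is almost
perfectly separable and no selection strategy can matter.

*Atmosphere.* Binary disk masks: clouds add 0.35 to every band plus 0.10
more to blue; shadows multiply NIR by 0.25 and the visible bands by 0.8;
i.i.d. Gaussian noise (default σ = 0.01 per scene; 0.02 at the composite
level in the learning worlds).  This is sufficient to exercise the
compositing weights; it is not radiative transfer, and there is no
phenology curve, sensor PSF, co-registration error or topography.
Consequences: passing tests show the pipeline recovers *this* family of
landscapes; real imagery adds spatially correlated noise, mis-registration
and within-field heterogeneity that the generator does not represent.

*Labellers.* A labeller of skill s ∈ [0,1] vertex-jitters true polygons
(σ = 4(1−s) px), omits each with probability 0.5(1−s), and adds spurious
blobs at rate 0.5(1−s).  Skill 1 reproduces the truth exactly.

## Labelling and consensus

Assignments are rasterized with the pixel-center rule.  The five score
components are defined as:

* **I** — balanced accuracy (mean of sensitivity and specificity) of the
  candidate vs reference mask inside the cell; a class absent from the
  reference contributes 1 if it is also absent from the candidate, else 0;
* **O** — 1 minus the fraction of candidate area outside the cell that is
  unsupported by reference outside-area (1 if nothing spills);
* **F** — min/max of the polygon counts (1 when both are 0, 0 when only
  one is empty);
* **E** — polygons matched one-to-one by greatest IoU; area-weighted mean
  over matched pairs of the IoU of their boundaries dilated by 2 px
  (1 when both sides are empty, 0 when nothing matches);
* **C** — fraction of matched candidate polygons carrying the reference
  class (1 when nothing matched).

Default weights β = (0.3, 0.1, 0.2, 0.2, 0.2): inside-cell agreement
dominates, the remaining components share the rest.  These definitions
and weights are this package's own fixed choices; they are stated here
because the score's published description names the components without
printing their formulas.

Consensus: `p = Σ wᵢyᵢ / Σ wᵢ` (weights are mean QA scores, so the sum is
normalized to make p a probability), class = `p > 0.5` with the tie
falling to non-field (conservative toward the majority class), and Bayes
risk `mean(1 − |2p − 1|)`, which attains 0 exactly at unanimity and 1 at
complete disagreement and is invariant to relabelling.  New labellers
start at prior weight 0.5 until QA history accrues.  The scheduler serves
1 hidden QA task per 5 mapped (every 6th serving), requires 4 distinct
labellers per training cell, and never repeats a training task to the same
labeller.

## Classification and active learning

Features (24 per pixel): the 8 raw bands of the two composites, their
11×11 moving means, and their 5×5 moving population standard deviations,
with reflect padding at edges.  The classifier is a random forest with 60
trees and depth 15, trained on a class-balanced pixel sample (majority
downsampled, seeded); probabilities are hard-vote fractions over trees, so
they are multiples of 1/60; the classification threshold is 0.5.

Cell uncertainty is `Q = Σ (p − 0.5)²` over a seeded random subset of
1,000 pixels per cell (the subset size is this package's choice); low Q
means uncertain.  Each iteration draws the labelling batch uniformly from
the lowest-Q 30% of the pool (ceiling count), which limits spatial
autocorrelation relative to taking the strict minimum.  The loop stops
after `max_iterations` (default 3) or when the validation F1 gain falls
below 0.005 — an explicit stopping rule standing in for the judgment-based
stopping the original campaign used.  F1 is the standard harmonic mean of
precision and recall.

Experiment harness (demo scale): worlds are 2×2 tiles at a 10×-coarsened
pixel (0.00025°), so cells are 20×20 px and a world is 400×400 px; 60
validation cells, 40 training pixels per cell.  The label-quality
experiment trains on 60 cells labelled by four simulated labellers
(skills 1.0/0.7/0.6/0.5) three ways — worst labeller, best labeller,
weighted consensus — and evaluates against truth.  The selection
experiment starts from 16 labelled cells and adds 16 per iteration for 3
iterations, actively or randomly, with truth labels; the lean starter is
deliberate — large starter samples substantially train the model before
selection can matter, diluting the contrast the experiment exists to
measure.  These problem sizes are the package's demo-scale study
conditions; they keep a 10-seed experiment around two minutes.

## Field delineation

Per tile, five steps: (1) min-max scale G, R, NIR to [0,1], mean-shift
filter them (spatial radius 3 px, range radius 0.1, ≤10 iterations — a
local mode-seeking smoother; these parameters are this package's
defaults), and sum the Sobel gradient magnitudes of the three filtered
bands and of the probability map; (2) compact watershed (compactness
0.01) from a regular marker grid — 6,400 segments per full 2000×2000-px
tile, i.e. mean segment ≈0.48 ha, finer than the ≈1 ha expected field
size; demo tiles use 256 segments per 200×200 px, preserving the ≈4×
oversegmentation ratio; (3) greedy region-adjacency-graph merging: edge
weight = Euclidean distance between the regions' mean normalized colours
(the mean-shifted bands), merging the globally smallest edge while it is
below 0.05, with count-weighted mean updates and deterministic
(min-label, max-label) tie-breaking; a final absorption pass merges
regions smaller than half the mean initial segment size into their most
similar neighbour — without it, thin watershed slivers straddling field
boundaries survive thresholding and roughly double the field count;
(4) vectorize regions (exact pixel outlines) and keep those with mean
probability strictly above 0.5; (5) drop interior rings, simplify with
Visvalingam–Whyatt (effective-area tolerance = 0.5 pixel area; a polygon
collapsing below 3 vertices is dropped), and union polygons from
different tiles whose 1-px-buffered geometries intersect (idempotent).
Only the dry-season composite is segmented; boundaries are most visible
then.

## Assessment

The area-proportion error matrix uses map classes as strata:
`p_ij = W_i n_ij / n_i`.  Metrics: overall = trace; user's = row-
conditional diagonal; producer's = column-conditional diagonal.  Variances
use the standard stratified estimators — for overall accuracy
`Σ W_i² U_i(1−U_i)/(n_i−1)`; for user's accuracy the within-stratum
binomial form; for producer's accuracy the two-term estimator that
propagates both the reference-column estimate and the off-diagonal
strata; for an adjusted class proportion
`Σ W_i² q_ik(1−q_ik)/(n_i−1)` with `q_ik = p_ik/W_i`.  Margins are
z = 1.96 × SE.  Adjusted class areas are reference-column sums × total
mapped area and therefore always conserve the total.  Printed matrices
can be ingested directly from percentage cells (renormalized to absorb
printing round-off).  Four-level reference labels ("unsure but likely X")
collapse to their binary parents, with the unsure fraction reported as
metadata.  Field size/count bias is corrected by a per-AOI ratio
estimator: `adjusted = raw × (digitized / segmented)` at validation
cells.

## Pipeline

A single global seed expands into per-stage seeds through
`SeedSequence.spawn`, so stage re-runs reproduce the full run; every
artifact is written with a SHA-256 manifest and double runs at the same
seed are bit-identical.  Rasters are plain TIFFs with JSON bounds
sidecars; vectors are GeoJSON; tables are CSV.

## Known limitations

* The as-printed shadow weight up-weights dark dates (see above); the
  alternative mode exists but is not the default.
* The generator's ambiguity model (per-field mixing plus one ecotone
  band) is a coarse stand-in for real agro-ecological gradients; absolute
  metric levels at demo scale (F1 ≈ 0.86–0.96) are not comparable to
  production values on real imagery (F1 ≈ 0.5), only orderings and
  directions of effects are.
* Segmentation quality is sensitive to the probability map; with an
  uninformative classifier the probability filter passes background
  regions whose mean p hovers above 0.5.
* Bias adjustment assumes validation cells are representative of the
  mapped area; no variance is attached to the ratio estimates.
* No map projections: all geometry is lon/lat with local equal-area
  scaling for hectares.
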