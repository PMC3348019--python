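# Methods

`tractomics` joins three data modalities over a single brain volume: a
multi-fiber orientation field tracked by probabilistic streamlines, a
set of expression samples registered to the same space, and a
protein–protein interaction (PPI) graph. This note records the model,
the conventions the source data formats leave open, the design of the
synthetic phantom the package validates itself on, and the limits of
what those validations show.

## Spatial conventions

Voxel indices are 0-based triples; a voxel `v` owns the half-open box
`[v, v+1)` in continuous voxel space. A world-mm point is assigned to a
voxel by applying the inverse affine and **flooring** each coordinate
(never rounding); points mapping outside the grid are excluded and
counted, not errored. Hemisphere membership (`left` / `right` /
`midline`) is an attribute of each labelled structure, never inferred
from the sign of an x-coordinate, so the "left seed to left target"
restriction is robust to asymmetric geometry.

## Tractography

Each voxel holds up to two fiber populations, each a unit mean axis, a
volume fraction in [0, 1] (summing to ≤ 1 per voxel) and an angular
concentration κ. Streamlines are launched from the center of every
seed-ROI voxel and propagated by Euler steps of `step_size` voxels
(default 0.5). At each step:

1. populations with fraction below `min_fraction` (default 0.05) are
   ineligible; no eligible population terminates the streamline
   (`low-fraction`);
2. with no incoming direction (the seeding step) an eligible population
   is drawn with probability proportional to its volume fraction; during
   propagation the eligible population most parallel to the incoming
   direction is followed. The second rule is what lets streamlines
   transit crossing-fiber regions — per-step fraction-proportional
   choice would re-draw the population every ~0.5 voxels and scatter
   every streamline entering a crossing;
3. the chosen axis is perturbed by an axially symmetric dispersion draw
   (closed-form inverse-CDF sampling of the von Mises–Fisher polar
   angle; κ → ∞ is a delta on the axis, κ = 0 uniform on the sphere),
   then sign-flipped so its dot product with the incoming direction is
   nonnegative — fiber orientations are axial, not polar;
4. a turn exceeding `curvature_deg` (default 80°) terminates the
   streamline (`curvature`).

Propagation is bidirectional: one initial axis is drawn at the seed
point, the two halves follow it and its negation, and are concatenated.
Seeds sit in the interior of a structure, so one-directional tracking
would miss half the connections. A streamline is retained for a
seed→target task iff it enters the target mask; it is truncated on
entry, so voxels past the target never contribute. The visitation map
counts, per voxel, the retained streamlines passing through it (each
once per voxel); the binary pathway mask thresholds it at
`mask_threshold` (default 1) and is monotone in that threshold.

Defaults (step 0.5 voxel, 80°, 100 samples per seed voxel, 2000 max
steps, min fraction 0.05, threshold 1) follow common probabilistic-
tractography practice with the sample count reduced to desk scale; all
are configurable.

**Reproducibility.** Each streamline draws from its own RNG substream
keyed by (master seed, task index, seed-voxel index, sample index) via
`numpy.random.SeedSequence`, so results are byte-identical under a fixed
master seed and independent of execution order.

## Expression mapping

Per-probe z-scores are `(x − μ)/σ` with μ, σ computed across **all**
samples of the matrix (whole-brain reference), not only the pathway
samples: the normalisation precedes spatial selection in the workflow,
and per-sample z-scores are only comparable across pathways under a
global reference. σ is the population (divide-by-n) standard deviation
by default; both the scope and the ddof are configurable because the
underlying convention is not standardised. Probes with σ = 0 produce
missing z-scores and a counted warning — never a division error, never
a silent zero. A gene's z at a sample is the unweighted mean of its
probes' z there, skipping missing values (symmetric and parameter-free;
max-probe and first-probe rules are common alternatives but need a
selection criterion). The per-pathway summary is the arithmetic mean of
a gene's z over the n selected samples with non-missing values; genes
with n = 0 are omitted with a warning, and an empty selection yields a
zero-row summary rather than an error, mirroring pathways that simply
contain no sample.

## Interaction network

The PPI graph is undirected and simple: duplicate and reversed-duplicate
edges collapse, self-loops are dropped and counted. A disease gene's
interaction count is the number of **unique partners** of its mapped
protein (self excluded); source databases contain both duplicate records
and self-interactions, and unique partners is the convention that makes
counts comparable across proteins. The degree filter keeps genes with
strictly more than `min_count` (default 10) partners.

Tiering around a seed protein uses C = {seed} ∪ related, where the
related set is a curated input roster (optionally intersected with the
seed's graph neighbors), not a topological derivation. Every node
outside C adjacent to ≥ 1 member of C is tiered by k(v), its number of
unique neighbors in C: k ≥ 3 → top tier, k = 2 → middle, k = 1 →
peripheral; non-neighbors of C are outside the subnetwork. "At least 3"
is the default reading of the top tier because an exact-3 rule leaves
k > 3 nodes unclassifiable; `tier3_rule="exactly"` is available and
documents that consequence.

## The synthetic phantom

The default phantom is the package's self-contained study condition:

* 48 × 56 × 48 voxel grid, 1 mm isotropic, affine origin
  (−24, −28, −24) mm;
* 15 spherical ROIs: a bilateral hippocampus-analog seed (radius 3),
  six bilateral targets (amygdala-, caudate-, pallidus-, putamen-,
  thalamus- and accumbens-analogs, radii 2.5–3) and a midline
  brainstem-analog;
* 10 fiber tubes (radius 2 voxels, fraction 0.8, κ = 60 ≈ 7° angular
  sd) connecting the seed to five targets per hemisphere along curved
  polylines; **no tube reaches the accumbens-analog**, so exactly 10 of
  the 12 enumerated tasks can produce a pathway;
* one crossing box per hemisphere where the caudate- and thalamus-bound
  tubes intersect (~38° apart); in-tube voxels there carry both tract
  directions at fractions 0.45/0.45. Where tubes overlap outside a
  crossing box (the fan leaving the seed), the two nearest centerlines
  contribute the populations and fractions are rescaled to sum ≤ 1;
* 200 expression samples, 12 per tract forced inside its tube (the rest
  uniform over the grid), 40 genes × 2 probes, baselines N(7, 1) log2
  units with N(0, 0.5) per-cell noise, and three genes planted at
  +3 log2 units in the left seed→thalamus-analog tract;
* a designed PPI graph: seed protein, 6 related proteins (the curated
  related-set size used in practice), 6 three-partner, 6 two-partner
  and 8 one-partner proteins, plus random edges among outside proteins
  that never touch {seed} ∪ related.

Ground-truth in-tube flags are recorded per sample and per tract, so
tests have a geometric oracle independent of the tracker.

**What the phantom does not emulate:** diffusion-weighted signal
formation and its artifacts, realistic anatomy (structures are spheres,
tracts are tubes), registration error, spatially correlated expression
noise, probe-specific biases, and the scale of real atlases (~10³
samples × ~10⁴ probes; ~4 × 10⁴ interactions). Passing tests therefore
demonstrate that the chain of algorithms is correct and reproducible on
data with the assumed structure — not that the pipeline is robust to
the failure modes of real acquisitions.

## Numerical choices and degenerate inputs

* vMF polar-angle sampling uses the exact inverse CDF
  `w = 1 + log(u + (1−u)e^{−2κ})/κ`, clamped to [−1, 1]; κ = 0 falls
  back to a uniform cosine and κ = ∞ to the mean axis.
* Ties in two-population selection (equal |dot| with the incoming
  direction) resolve to the first population; equal fractions at
  seeding resolve by the uniform draw.
* Problem sizes were chosen so a full default run (12 tasks, 100
  streamlines per seed voxel) completes in well under a minute on one
  core; the statistical replication suites use 20 seeded replicates.
* Degenerate inputs are hard errors where silent continuation would
  corrupt results (empty seed-voxel set, planted gene with no probe,
  singular affine, tube leaving the grid, overlapping ROI spheres) and
  counted warnings where exclusion is well-defined (out-of-bounds
  samples, σ = 0 probes, self-loop edges).

## Known limitations

The tracker is a two-population Euler stepper: no posterior over fiber
parameters, no partial-volume model, no anisotropic step correction.
The choose-most-parallel rule at crossings is deterministic given the
perturbed draw and slightly favors the tract a streamline is already
on; fraction-proportional choice at every step is available only as the
seeding behavior. Pathway voxel counts depend on the visitation
threshold, which is reported alongside them rather than fixed by any
external convention.
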