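# Methods

This note documents the models, conventions, and numerical choices behind
`i2g`, and what the synthetic benchmarks do and do not demonstrate.

## Conventions

Axis order is `(z, y, x)` everywhere, matching slice-stacked EM volumes;
coordinates are 0-based, ranges half-open. Label 0 is background (membrane
space in the synthetic scenes) — the de facto segmentation standard.
Annotations follow a minimal RAMON-style model: typed synapse/segment
objects with an extensible string key-value map instead of a closed
ontology; a synapse's "weight"/"type" style metadata travels in `kv` and is
never interpreted by the graph computation.

## Graph comparison

**Line graph.** `l_ij = 1` iff synapses `i != j` have intersecting partner
sets. Dangling synapses (overlapping fewer than two neuron labels)
participate through their single partner and otherwise contribute isolated
nodes. Matrices are binary, symmetric, zero-diagonal; both properties are
enforced at construction.

**Correspondence and augmentation.** Synapse matching is greedy one-to-one
by descending voxel overlap, ties broken by (smaller true id, smaller
estimated id). Greedy rather than optimal assignment: it is deterministic,
near-optimal for compact objects, and identical to the detector's
object-scoring rule, so object F1 and graph F1 are built on the same
matching semantics. The shared augmented index lists matched pairs (by true
id), then unmatched true, then unmatched estimated synapses; a synapse
absent from one graph contributes an all-zero row/column there, which is
why augmentation can only add FP/FN edges, never TP.

**Errors.** The Frobenius error is computed over the full symmetric matrix
(so each discrepant unordered pair contributes √2); TP/FP/FN counts use the
strict upper triangle. Conventions at the boundary: precision 0 when the
test graph has no edges, recall 0 when the truth has none, F1 0 when both
are 0.

**Permutation test.** The null is a random symmetric graph on the same
nodes with each unordered pair an independent Bernoulli(p) edge, p being
the observed line-graph density. "Observed" is read as the graph under
test (the estimated graph); a `density_from="true"` flag switches to the
truth's density. The default statistic is the F1 deficit (1 − F1),
consistent with selecting operating points by graph F1; the Frobenius norm
is available via `statistic="frobenius"`. The p-value is add-one smoothed,
`(1 + #{null ≤ observed}) / (B + 1)`, so it is never exactly 0 and is
uniformly distributed under the null up to discreteness; `smoothed=False`
gives the raw empirical CDF. B defaults to 10,000 in `score_graphs`; the
grid sweep defaults to B = 1,000, a desk-scale setting whose minimum
attainable p (1/1001) still clears the default significance level
α = 0.001. On very small graphs (≲ 8 synapses) the null can tie the
observed error with appreciable probability, so significance is
structurally unreachable there regardless of B — the calibration test and
the selection machinery therefore operate on graphs of 10+ synapses.

## Synapse detector

Vesicle evidence is the normalized cross-correlation of a dark-disc
template (radius 2 px by default, brightness levels matching the rendered
vesicles), computed per 2D slice — EM stacks are strongly anisotropic
(~3×3×30 nm), so in-plane texture is the reliable signal. Correlation over
zero-variance windows is defined as 0.

The ten feature channels are: raw intensity; Gaussian-smoothed intensity at
σ = 1 and 2 (in-plane); in-plane gradient magnitude; uniform local binary
patterns (P = 8, R = 1, on the 8-bit quantized image); structure-tensor
eigenvalue ratio and trace (σ = 1); membrane probability; vesicle
correlation; and vesicle peak density — high-correlation peaks (≥ 0.35)
smoothed with σ = (1, 3, 3), the z-component acknowledging that a vesicle
cluster spans neighboring slices. The named families cover intensity,
gradient, texture, and biological context; the exact parameterization is
this package's choice.

Training and prediction are both restricted to the membrane search region
(membrane probability ≥ 0.5 by default). Restricting *training* as well as
prediction matters: without it the forest spends its capacity separating
membrane from cytoplasm — a distinction the mask already makes — and the
hard synapse-vs-membrane boundary is learned poorly. Classes are subsampled
to ≤ 20,000 voxels each, seeded. The forest uses 100 trees by default
(50 in the test suite), unlimited depth, single-threaded for bit
reproducibility.

Object formation binarizes at the probability threshold, takes 26-connected
3D components, and removes components below the 3D voxel minimum or whose
largest *single-slice* footprint exceeds the 2D maximum (the per-slice
reading of the 2D filter; a summed-footprint reading is plausible but not
used). Full-scale defaults are 0.95 / 1000 voxels / 5000 px. On synthetic
scenes, whose synapses are ~150 voxels, the scene-scale operating point is
0.5 / 10 / 500 — thresholds are operating-point parameters, expected to be
swept per dataset, and the grid evaluation exists precisely to choose them.
Note that raising the probability threshold shrinks the supra-threshold
voxel set (components nest), but the *count* of surviving objects is not
monotone: one merged component can split into several valid ones.

Detection scoring is one-to-one greedy matching by overlap; a single
detection can never claim multiple true synapses (a blanket detection
covering the volume scores near 0, not 1).

## Synthetic scenes

The generator emulates the features the pipeline consumes, not EM physics:
Voronoi neuron regions around seeded points with a membrane gap
(`d₂ − d₁ ≤ w`, w = 2 voxels by default); optional 1-voxel-thick
spine-neck protrusions ending in small heads (targets for the split
operator); synapses as ellipsoids (semi-axes 1×3×3) centered on two-neuron
boundary sites, overlapping both partners and no third neuron; vesicle
discs (radius 2, ≥ 5 px apart) scattered within 5 voxels on the first
partner's side; rendering at interior 0.75, membrane 0.15, cleft 0.10,
vesicles 0.30, plus Gaussian noise σ = 0.02. The cleft renders slightly
darker than plain membrane (postsynaptic-density contrast) — about 1.7 σ of
the noise, so it is not voxel-wise separable and the detector must combine
texture with vesicle context. The membrane probability map is high on
membranes *and* clefts (a membrane detector fires on both).

What this does not capture: real EM texture (mitochondria, microtubules,
staining gradients), segmentation errors correlated with image content,
vesicle appearance variation, and alignment artifacts. Passing benchmarks
here shows the pipeline machinery is correct and well-calibrated, not that
the detector's absolute F1 transfers to tissue. One measured consequence:
on these scenes the smoothed-intensity channels outrank the vesicle
channels in forest importance (the rendered cleft is locally dark), whereas
on real tissue vesicle presence is reported as the dominant cue; the tests
therefore assert the vesicle channels are informative, not top-ranked.

**Corruption operators.** Splits cut a neuron at the minimum-occupancy
plane along its principal axis, restricted to the central 20–80% band (so
a cut always leaves two non-empty parts); with a spine neck present this
severs the neck. Merges fuse adjacent label pairs onto the smaller id.
Both conserve the foreground voxel set exactly. Synapse corruption deletes
true synapses independently, jitters survivors by a rounded Gaussian
offset, and adds spurious membrane blobs; partners are cleared for
re-association. All randomness flows through one `default_rng` per call.

## Grid evaluation

Operating points are materialized payloads (volumes, annotation sets), not
algorithm invocations — the sweep is agnostic to the upstream algorithms,
whose settings travel in the `params` provenance map. Per cell: associate
estimated synapses with the candidate segmentation (mask dilation radius 1
by default, letting membrane-gap synapses reach both neighbors), build the
line graph, match/augment against the truth line graph, score, and test.
Per-cell permutation seeds are derived deterministically from the sweep
seed and the cell index. The segmentation axis is summarized by the
adjusted Rand index over voxels foreground in both volumes; the synapse
axis by object-level detection F1. Selection maximizes graph F1 over
significant cells (α = 0.001), ties broken by higher precision, then lower
Frobenius, then row-major order.

## Block processing

Inscribed regions tile the volume disjointly; padded regions extend them by
the padding, clipped to bounds. Per-block outputs are offset into disjoint
global id ranges (`block_index × stride`, one stride above every per-block
maximum). Seam merging walks faces in a fixed serial order (axis-major,
then block order); for each pair of objects co-occupying voxels of the
shared padded slab, similarity is Jaccard over the two objects' voxels in
the slab (an `overlap_fraction` alternative is available), threshold 0.5 by
default — the metric and threshold are user choices, not canon. Matches are
relabeled to the smaller id immediately, so later seams see merged ids and
no global transitive-closure pass is needed; because merges always map
larger onto smaller resolved ids, the final id of a merged component is its
minimum, independent of seam order. `canonical_relabel` (first-occurrence
scan order) makes partitions comparable across runs.

## Problem sizes

The test suite and the acceptance script run on deliberately small inputs:
default scenes of 12×96×96 voxels with 8 neurons / 6 synapses; detector
benchmarks on 16×160×160 with 14 synapses; the 16 × 116 grid (1856 cells)
on an 8×48×48 scene with B = 50; calibration with 200 replicates at
B = 500. These sizes were chosen so a full run completes in minutes on one
core while every measured property (determinism, calibration, invariances,
recovery) is already stable at that scale.

## Known limitations

* Undirected graphs only; no pre/post-synaptic polarity, no attributed
  graph error.
* Partner cardinality is capped at two (a chemical synapse joins two
  neurons); overlap with a third label is ignored.
* The detector assumes anisotropic data with informative in-plane texture;
  isotropic volumes would want 3D features.
* Seam merging is serial and single-machine; hierarchical merging for very
  large volumes is out of scope.
* The ARI is computed on voxels foreground in both partitions; volumes that
  disagree about foreground extent are compared only where both commit.
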