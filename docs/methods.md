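# Methods

This note documents the model and procedure behind `grnseg`, the
parameters that matter, the numerical conventions, and what the bundled
synthetic data can and cannot establish.

## Pipeline model

The pipeline treats a cohort of EM-reconstructed sensory axons as two
coupled observations per neuron: its arbor geometry (an SWC tree,
internally always in micrometres) and its row/column in a directed
synapse-count matrix. Modality groups are latent; the method recovers
them by clustering a per-neuron feature vector that concatenates
morphological similarity to every other neuron with synaptic output onto
every other neuron.

### Dotprops and NBLAST scoring

Arbors are resampled along each unbranched path at a target spacing
(default 1 µm, endpoints kept) and each resampled point receives a unit
tangent: the first principal axis of the covariance of its k nearest
resampled points (default k = 5, including itself). Tangent sign is
meaningless and never used — scoring takes |u·v|. At branch points the
same kNN-PCA rule applies, so corner tangents interpolate between the
adjacent branch directions.

The raw similarity of query Q to target T matches every query point to
its nearest target point (KD-tree; ties in principle broken toward the
lowest target index, and in practice absent for continuous coordinates)
and sums a kernel f(d, |u·v|). Two kernels are supported:

* parametric (default): f(d, a) = a·exp(−d/σ) with σ = 3 µm, so
  f(0, 1) = 1 and the raw self-score of an n-point cloud is exactly n.
  σ sets the distance scale at which morphological overlap stops
  counting; 3 µm is appropriate for registered whole-brain data where
  corresponding branches of like neurons lie within a few µm.
* a binned log-odds table in the published NBLAST score-matrix format
  (TSV), used verbatim when supplied. Bins are half-open [lo, hi);
  values beyond the last edge use the last bin, which makes lookups
  bit-exactly reproducible.

Normalised scores divide by the query self-score; the symmetric *mean
score* (average of both directions) is what clustering and assignment
consume, because agglomerative clustering needs a symmetric input while
raw NBLAST is directional (a sub-arbor scores higher against its
superset than vice versa). The diagonal of the similarity matrix is set
to exactly 1.

### Feature merge and scaling

Row i of the merged feature matrix is [S(i,·) | C(i,·)]: similarity to
every neuron, then outgoing synapse counts onto every neuron (incoming
or both are options). Min–max scaling maps features into [0, 1]; the
default scope is *per block*, scaling the similarity block and each
connectivity block by their own extrema. A single global min–max would
satisfy the same [0, 1] range but let raw synapse counts (hundreds) dwarf
similarity values (≤1), effectively discarding morphology; per-block
scaling keeps the two signals at comparable scale and is the most
consequential interpretive choice in the pipeline. A constant block (or
column, in per-column scope) maps to all zeros.

### Ward clustering and choosing k

Ward agglomeration on the scaled rows (Euclidean metric — the only one
for which Ward's objective is defined) is delegated to
`scipy.cluster.hierarchy.linkage`. Joining costs are reported as
ΔESS = |A||B|/(|A|+|B|)·‖c_A − c_B‖², i.e. the squared scipy height
divided by two; on two 1-D singletons at 0 and 2 the single merge costs
exactly 2. The profile J(k) is the cost of the merge reducing k+1
clusters to k and is nonincreasing in k.

The group count is chosen at the elbow of J. We take
k* = argmax_{k∈[k_min,k_max]} (J(k−1) − J(k)) / J(k), ties to the
smallest k, defaults k ∈ [2, 12]. The *relative* differential is used
deliberately: Ward joining costs between genuinely distinct groups scale
with |A||B|/(|A|+|B|), so with unequal group sizes the absolute
differential J(k−1) − J(k) grows toward small k and peaks at k = 2 even
when the partition structure is obvious — on cohorts with groups of
7–23 neurons the absolute rule reliably returns 2 while the dendrogram
itself is perfect. Dividing by the post-drop cost asks "how many times
more expensive is the next merge than this one", which is
size-invariant; the absolute rule remains available
(`select_k(..., criterion="absolute")`). Cutting at k relabels groups
1..k by dendrogram left-to-right leaf order, so group numbering is
deterministic and matches a plotted tree.

### Modality assignment

Each group's members are concatenated into a composite point cloud
(optionally subsampled with a recorded seed) and scored with the mean
NBLAST score against every entry of a labelled template library; the
group takes the class of the top-scoring template. Exact ties go to the
lexicographically smallest template id and are flagged. Per-class mean
scores over the library's exemplars are reported alongside the single
top hit. Composites here are point clouds, not voxel images: if
templates come from a different modality (e.g. summed confocal stacks),
class *ranks* are expected to be robust but absolute score values are
representation-dependent and should not be compared across pipelines.

### Connectivity accounting

Within/between-group segregation is quantified on synapse counts:
block_sums[g,h] sums Cᵢⱼ over i∈g, j∈h, the within fraction is
trace/total, and grouping conserves the matrix total by construction.
An edge-weighted variant (share of nonzero neuron pairs) is reported
alongside, since "X% of connections" is ambiguous between the two
readings; the synapse-weighted number is the headline. Thresholding at
m synapses zeroes entries below m (default report shows m = 1 and the
conventional high-confidence m = 5) and is monotone in m. Per-neuron
statistics divide the in-cohort column sum by the neuron's total
postsynaptic site count (from a totals table that includes non-cohort
partners); if no totals are supplied the fractions degenerate to 1 and
the output is flagged accordingly. Autapses are rejected by default —
they are not meaningful for axo-axonal analysis.

## Synthetic cohorts

The generator emulates the relevant structure of labellar GRN anatomy:
axons enter via a common tract (biased random walk from a shared entry
point), terminate in group-specific zones (recursive binary arbors of
depth 3 whose branch targets scatter with s.d. `zone_spread` = 4 µm
around the zone centre), and synapse according to a planted block model:
each ordered pair connects with probability p_within (same group) or
p_between, and a connected pair carries 1 + Poisson(λ − 1) synapses.
Synapse sites are placed at terminal nodes of the presynaptic arbor so
the emitted CSV matches real connector exports. One RNG stream is
consumed in a fixed order (neuron geometry, template geometry, edges,
totals), so a seed pins every output byte.

`preset_labellar()` is the study-scale configuration: 87 axons in six
groups of 7, 10, 12, 15, 20, 23; six zone centres in a ~100 µm field
with pairwise separation ≥ ~39 µm (≈10× the arbor spread);
p_within = 0.5, λ_within = 6.6, p_between = 0.1, λ_between = 1.95, chosen
so the analytic synapse-weighted within-group fraction is 0.790 and the
mean in-cohort input is ~65 synapses/neuron; external (non-cohort)
partner rates of 109.7 presynaptic and 102.7 postsynaptic sites per
neuron then give mean totals of ~175 and ~168 sites and a mean
within-cohort input fraction of ~0.39. `expected_block_totals(config,
threshold)` gives the closed-form expectation and delta-method standard
error of the within fraction at any threshold (using the truncated
moments E[T·1{T≥t}] of the zero-truncated Poisson), and is the oracle
the calibration tests check realized cohorts against (3 SE).

What the generator does *not* emulate: reconstruction errors and missing
arbors, polyadic synapses, spatially correlated connectivity (here edge
probability depends only on group identity, not on arbor proximity),
hemisphere asymmetries, and heavy-tailed between-group synapse counts.
The last point matters for thresholded summaries: under the truncated
Poisson with λ_between ≈ 2, almost no between-group pair reaches 5
synapses, so the ≥5-threshold between-group share collapses to ~1%,
whereas real EM data retain a noticeably larger share — real
between-group counts are more dispersed than Poisson. Passing tests
therefore demonstrate correctness of the accounting, not the realism of
the thresholded tail. Likewise, perfect recovery (k* = 6, ARI = 1) on
synthetic cohorts shows the pipeline finds planted structure under
realistic separation and noise; real cohorts with overlapping zones
(e.g. anatomically similar sugar/high-salt classes) will sit closer to
the decision boundary.

## Numerical choices and degenerate inputs

* All lengths in µm; nm inputs are converted once at read time.
* Single-node skeletons are rejected by dotprops conversion unless
  explicitly allowed (tangent then defaults to +x); a skeleton shorter
  than the sampling interval yields one point with the tangent of its
  only edge.
* Tangents at points whose kNN neighbourhood has near-tied distances are
  sensitive to coordinate perturbations (including rigid motions in
  floating point); this affects a few per mille of points at branch
  junctions and is inherent to kNN-PCA.
* Zero query self-score (possible only with a pathological score table)
  raises rather than returning an undefined normalised score.
* `cut` uses the first n−k merges (scipy `cut_tree`), not a height
  threshold, so tied heights cannot produce fewer than k groups.
* The pipeline itself has no randomness; only the generator and optional
  composite subsampling consume seeds.

## Problem sizes

Default verification runs use cohorts of 87 neurons (~150–250 dotprops
points per neuron), 100 simulated cohorts for recovery/assignment rates,
500 random instances (n ≤ 8) for the Ward oracle comparison, and 1000
random cloud pairs (≤ 20 points) for the NBLAST oracle comparison; a
10×-sized cohort (870 neurons) checks law-of-large-numbers convergence
of the block sums. These sizes make the full suite run in a few minutes
on one CPU while keeping every statistical tolerance at 3 SE or tighter.

## Known limitations

* The elbow rule, like any single-number model-selection heuristic, can
  be ambiguous when J(k) decays smoothly (e.g. nested or hierarchically
  similar groups); inspect `joining_cost_profile` before trusting k*.
* Min–max scaling ties the connectivity block's scale to its single
  largest count; one hub pair compresses all other connectivity
  features. Per-column scaling is available but makes columns of mostly
  zeros noisy.
* NBLAST on point clouds assumes inputs are registered to a common
  space; the package performs no registration.
* Score values depend on the kernel; only comparisons under the same
  kernel are meaningful.
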