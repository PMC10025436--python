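# Methods

## Model and procedure

The package clusters a collection of whole graphs and attaches a
significance statement to every split it keeps.  The pipeline is: pairwise
distances → agglomerative dendrogram → recursive split testing → final
clusters.  The split test is a distance-wise one-way ANOVA.  By the
interpoint identity, the sum of squared deviations of points from their
centroid equals the sum of squared interpoint distances divided by the
number of points, so SST, SSW and SSA — and the pseudo-F ratio
(SSA/(k−1))/(SSW/(N−k)) — can be computed from the distance matrix alone,
with no notion of an average graph.  For Euclidean point clouds this
reproduces classical one-way ANOVA exactly (tested to 1e-10 relative
tolerance).

Because the two tested groups were produced by clustering the same
distances, permuting group labels would be anti-conservative.  The null is
instead built by shuffling a fraction (default 20 %) of the
upper-triangular distance entries among themselves, mirroring, re-running
the agglomerative clustering on the shuffled matrix, cutting into two
groups, and recording that replicate's F when both groups reach the minimum
group size `t`; undersized replicates are discarded and re-drawn up to
10 × n_perm attempts, and the p-value denominator counts valid replicates
only.  Shuffled matrices generally violate the triangle inequality, so only
linkages that need symmetry and nonnegativity are offered (complete,
average).

A split is kept when its adjusted p-value is strictly below α.  With the
default 99 replicates the permutation p is discrete with step 1/100, so
strict rejection at α = 0.05 has probability exactly 4/100 under a uniform
null — this convention is what the workflow's null calibration (~4 %
rejection) reflects; non-strict rejection would give 5/100.

### Tree traversal

Each node's two branches come from cutting its sub-dendrogram at the top
merge.  Three cases:

* both branches ≥ `t`: test; if significant, recurse into both with the
  test depth incremented, otherwise the node is a final cluster;
* both branches < `t`: the node is a final cluster;
* exactly one branch < `t`: the split is *not* tested and the depth *not*
  incremented; the walk descends into the larger branch and tests its own
  split.  If that split is significant the small branch is declared an
  outlying, independent group; otherwise the whole node stays one cluster.
  The bypass rule applies recursively if the larger branch's split is
  itself blocked by an undersized branch.  Internal nodes created this way
  carry the status `untested_bypass`; their leaves use the regular
  statuses.

Multiple-testing control: `depth` multiplies the raw p by the test depth
(root depth 1, i.e. uncorrected; capped at 1); `meinshausen` compares the
raw p against α·(N_j−1)/(N−1) where N_j is the size of the node actually
tested; `none` disables correction.  Depth-based correction is the default
— in the 10-group power study it keeps ~9 of 10 groups versus ~6 for the
Meinshausen threshold, which shrinks fast away from the root.

## Distance and similarity measures

Nine measures are provided; five require a known node correspondence
(identical ordered node sets): edge difference (Frobenius norm of the
adjacency difference), the node-identified random-walk kernel, DeltaCon,
GTOM and the Gaussian kernel on vectorised adjacencies.  Hamming,
shortest-path kernel, k-step random-walk kernel and the graph diffusion
distance do not require an a-priori mapping, though Hamming and diffusion
still compare aligned matrix entries and therefore need equal node counts.
Kernels become distances via d = K₁₁ + K₂₂ − 2K₁₂ (the squared
feature-space distance; no square root), with an optional cosine
normalisation (`normalize=True`) applied first.

Notable design choices:

* **Kernels honour node identity when it exists.**  The Dirac base kernels
  of the shortest-path and random-walk kernels compare node labels; when
  the compared graphs share one ordered node set (the intended use case —
  e.g. one network per patient over the same genes), the shortest-path
  kernel counts node pairs whose shortest-path length agrees in both
  graphs, and the random-walk kernel's direct product pairs only
  identically labelled nodes (elementwise topology product).  This matters:
  degree-preserving rewiring exactly preserves the first three walk-count
  sums 1'Aⁱ1, so the label-free Kronecker kernel collapses to a 1-D
  heavy-tailed statistic with no usable signal under the simulation's null
  and alternative alike.  `ignore_node_ids=True` restores the pure
  topological variants (which are invariant under node relabelling).
* **`random_walk_kernel_knc`** runs the same node-identified series on the
  elementwise *weight* product A₁⊙A₂, so it coincides with the base kernel
  on binary graphs and differs on weighted ones.  Random-walk defaults:
  k = 3, unit step coefficients.
* **DeltaCon** uses the exact dense solve of S = [I + ε²D − εA]⁻¹ (graphs
  here are at most a few hundred nodes) and the Matusita (root-Euclidean)
  distance between affinity matrices.  The pairwise driver uses one global
  ε = 1/(1 + max degree over the whole collection) so that all pairs live
  on the same affinity scale and each graph's S is computed once; the
  two-graph function defaults to the per-pair 1/(1 + max degree).
* **Diffusion distance** maximises ‖exp(−tL₁) − exp(−tL₂)‖_F over a
  50-point log-spaced grid on [1e-2, 1e2] with one local refinement around
  the coarse maximiser.  It is evaluated through the eigendecomposition of
  each Laplacian and the trace identity for the cross term, which is
  mathematically identical to forming the matrix exponentials (verified
  against a scipy `expm` brute force) but lets the all-pairs driver reuse
  per-graph spectra.  Distances between identical graphs carry ~1e-8
  cancellation noise.
* **GTOM** uses overlap order m = 1 by default; the between-graph distance
  is the Frobenius norm of the difference of the two overlap matrices.
  m ≥ 2 widens the neighbourhoods via boolean reachability.
* **Gaussian kernel** σ defaults to the median of the pairwise vectorised
  adjacency distances over the input collection (median heuristic).
* Hamming and GTOM are undefined for weighted graphs and raise rather than
  silently binarise.

## Synthetic-data generator

The generator emulates a two-level population of networks: an original
Erdős–Rényi graph (defaults: 100 nodes, density 0.05, binary) is perturbed
into group networks, each perturbed again into individual networks.
Perturbations: degree-preserving rewiring (round(fraction·|E|) double-edge-
swap *attempts*, each replacing edges (a,b),(c,d) with (a,d),(c,b) when
neither exists; failed attempts are consumed), plus add / remove / switch
of round(fraction·|E|) edges (switch relocates edges and does not preserve
degrees).  The default perturbation fraction is 0.40 at both levels.
Weighted variants draw N(0.5, 0.25²) values for present edges after the
topology perturbation and min–max scale them with one global min and max
across all graphs; a degenerate constant range maps to 0.5.  Alternative
originals: Barabási–Albert (attachment count chosen to match the target
density) and a planted-cluster model (4 equal blocks, within-block edge
probability 5× the between-block one, calibrated to the target density —
the block layout is this package's choice).

The type-I study simulates one homogeneous population of 50 rewired graphs
per replicate and reports the fraction of replicates in which ≥ 2 clusters
are detected.  The power study simulates 10 groups × 10 individuals and
scores recovery with the pairwise co-membership Jaccard index
n₁₁/(n₁₁+n₁₀+n₀₁) (computed from the contingency table).  Replicate-level
randomness comes from per-replicate child streams spawned from one seed, so
results are reproducible and independent of evaluation order.

What the generator does *not* emulate: real biological networks have
heterogeneous degree distributions, hub persistence, modular structure and
correlated edge noise; the rewiring model holds degrees fixed exactly and
perturbs edges independently.  Passing the simulation checks therefore
demonstrates calibration and recovery under these stylised conditions, not
performance on any particular biological data type.

## Numerical choices

* Agglomeration delegates to `scipy.cluster.hierarchy`; exact ties in merge
  heights are resolved by scipy's deterministic ordering (random distances
  are tie-free almost surely), and the two-group cut falls back to reading
  the top merge directly if `fcluster` ever returns a single group.
* SSW = 0 with SSA > 0 yields F = +inf (perfect separation always rejects);
  the fully degenerate all-zero case reports F = 0 with a warning.
* On shuffled (non-metric) matrices SSA may be negative; the permuted F may
  then be negative, which is correct behaviour for the null comparison.
* Kernel matrices that are not positive semi-definite produce clipped
  (≥ 0) distances with a warning.
* All randomness flows through `numpy.random.Generator`; a fit's
  permutation streams are consumed in deterministic pre-order traversal, so
  one seed fixes the whole tree.

## Problem sizes in the bundled checks

The reported studies used 1000 (type I) and 800 (power) replicates.  The
acceptance script re-runs them at 400 replicates for the edge-difference,
Hamming and average-linkage null rates, 300 for DeltaCon, 100 for the
diffusion distance, and 24 / 36 / 10 replicates for the baseline,
GTOM-removal and scale-free power scenarios — sizes chosen so the whole
recomputation fits a single CPU comfortably.  At 400 replicates a true 4 %
rate is estimated with a ±1 % standard error; the power means carry
standard errors of roughly 0.01–0.03.  The test suite uses 150/60-replicate
null runs with 3-standard-error bands and 10–20-replicate power runs.

## Known limitations

* The GTOM between-graph distance (Frobenius difference of overlap
  matrices) retains strong discriminative power under edge-removal
  perturbation; reports of GTOM collapsing in that setting are not
  reproduced by this formulation (see the acceptance output for the
  measured value).
* The exact form of the customised known-node-correspondence random-walk
  kernel in the original description is not fully specified; the weight-
  product interpretation implemented here coincides with the base kernel on
  binary graphs.
* Attributed-node kernels, graph edit distance, spectral and
  graphlet-based distances are out of scope, as are fixed-k dendrogram
  cuts.
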