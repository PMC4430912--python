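# Methods

This note documents the model implemented in `aphseg`, the defaults and the
design choices made where the method left room, and what the synthetic
phantoms do and do not establish.

## Statistical region merging

SRM treats segmentation as hypothesis testing on region means: two regions
merge when their observed mean difference is within the statistical
fluctuation expected of homogeneous regions. The implementation sorts all
4-adjacent pixel couples by gradient |I_p − I_p′| (stable sort; ties broken
by raster position, right-neighbour edge before down-neighbour edge, so
results are bit-reproducible) and traverses them once with a union-find
carrying pooled counts and means.

Two merging bounds are available:

* `bound="simple"` (default): b(R) = g·√(ln(1/δ)/(2Q|R|)), δ = 1/(6|I|²).
* `bound="full"`: adds the size-dependent term min(g,|R|)·ln(1+|R|) inside
  the square root, the bound of the original SRM derivation.

The full bound is very loose for regions smaller than g pixels: on a 16×16
two-level test image at Q = 1 it merges the two halves (b(128) ≈ 403
against a contrast of 255), collapsing the image to one region. The simple
bound keeps high-contrast structures separate at every Q ≥ 1 while merging
homogeneous areas, which matches the intended coarse-to-fine behaviour of
the Q ladder; it is therefore the default. Both are exposed via
`SrmParams.bound`.

Connectivity is 4-adjacency throughout; boundaries live on the interpixel
grid between 4-adjacent pixel centers, which keeps "contour" unambiguous
for the UCM. Intensities are used as given; non-8-bit input is min-max
rescaled to [0, 255] at load time with the mapping recorded in metadata.

## Nested hierarchy, tree and UCM

Running SRM independently per Q does not guarantee nested partitions. The
ladder is therefore built hierarchically: pixel-level SRM at the largest Q
(finest), then for each smaller Q one pass of the same merging predicate
over the region-adjacency graph of the previous level (couples sorted by
mean difference, ties by region-id couple). Nesting — the strong-causality
axiom that finer boundary sets contain coarser ones — then holds by
construction, and a root level that merges everything is always appended
so all inner contours vanish at finite scale.

Scale is the integer level index λ (0 = finest, λ₁ = root); with finitely
many levels nothing is gained from a continuous scale parameter. The tree
allocates one node per maximal region over its lifetime: a region that
persists unchanged across levels is a single node with birth/death level
indices. UCM saliency of an interpixel edge is the smallest λ at which its
two sides share a region; thresholding at λ (keeping edges with saliency
> λ as boundaries) reproduces the ladder partition at λ exactly, which the
tests assert level by level, together with the ultrametric triple
inequality of the induced separation levels.

## Seeds and histogram models

Seed scribbles carry purely photometric information: per class, a histogram
of seed-pixel gray values over B = 64 equal-width bins on [0, 255],
add-epsilon smoothed (ε = 1e−6) and renormalized, so log-likelihoods are
always finite. B and ε are configurable; 64 bins resolve 4-gray-level
steps, comfortably below the class contrasts of interest, and the defaults
follow common scribble-segmentation practice.

Seeds are soft by default — they shape the histograms only. With
`hard_seeds=True`, any finest-level segment containing seeds of class k is
additionally pinned to k by a dominating finite penalty on the other
labels (a segment seeded by two classes stays free). Hard pinning is the
stricter reading of "seeds as prior information"; both are supported since
the method itself does not dictate one.

## Anatomy packing

The segment pool is the node set of the tree. A labelling assigns each node
0 (not selected) or a class in 1..K such that the selected nodes form an
antichain covering every pixel exactly once. The unary cost of selecting
node q with class k is the per-pixel product likelihood
Σ_{p∈q} −log h(bin(I_p); k). This reading makes unaries additive over the
tree (a prerequisite of the chain construction below) and weights segments
by their size. A per-segment alternative — scoring the segment's own
histogram against the class model — is available via `unary_mode` but is
not additive and is provided for comparison only. The pairwise term is
contrast-sensitive Potts over 4-adjacent pixel couples,
γ·exp(−β(I_i − I_j)²) for unequal labels; since labels are constant within
a leaf segment it aggregates exactly to a Potts term over adjacent leaf
couples. Defaults: γ = 50 and β = 1/(2·mean((I_i−I_j)²)), the standard
contrast-normalized choice; both configurable and recorded in the run
manifest.

### Exact binary inference

For K = 2 the constrained minimization reduces to one min-cut. Each tree
node i contributes two chain vertices: the label-1 chains follow the tree
root-to-leaf, the label-2 chains leaf-to-root, with the selection cost of
(i, label) as the capacity of the corresponding chain edge and an infinite
bridge joining both chains at each leaf. Infinite reverse edges make the
cut variables monotone along every path, and an infinite edge between a
node's two vertices forbids it from sitting on the selected side of both
chains, which (through the monotonicity) rules out a label-2 selection
above a label-1 switch on the same path. Every valid labelling then maps
to a finite cut of equal cost and every finite cut decodes (at the chain
switch positions) to a valid labelling of exactly the cut's cost, so the
minimum cut attains the global energy minimum — for arbitrary non-negative
node costs, not only additive ones. The test suite verifies exact
agreement with exhaustive enumeration on 100 random trees with random
unary and pairwise costs.

Max flow is computed with scipy's solver, which requires integer
capacities within int32 range; real capacities are converted by adaptive
fixed-point scaling (scale chosen so the total finite capacity stays below
2³⁰, structural infinities encoded as 2³⁰). The resulting rounding is at
most ~1e−6 relative at test problem sizes and only affects tie-breaking
between near-equal optima.

### Alpha-expansion

For K > 2, the state is the per-leaf label vector, initialized to the
globally cheapest single label (ties toward the smaller label id). Sweeps
over α = 1..K solve a binary keep-vs-α problem with the same chain
construction — keep costs are the current per-leaf unaries aggregated per
node, and the pairwise move table (submodular, since Potts satisfies the
triangle inequality) is decomposed into edge and terminal capacities. A
move is accepted only if the total energy strictly decreases, so the trace
is strictly decreasing and termination within `max_sweeps` (default 10) is
guaranteed; in practice phantom runs converge in 2–3 sweeps. The final
antichain labelling selects the maximal tree nodes with constant leaf
label, which realizes the same pixel labelling and energy.

## Agreement metrics

AD(X, Y) is the symmetric mean closest-point distance between boundary
point sets (Euclidean, pixel units). The Williams index divides the mean of
1/AD(C, O_j) by a normalized inter-observer mean of 1/AD. Two denominator
normalizations are implemented: the printed form 2/(n(n−2)) with the
ordered double sum, and the classical form 2/(n(n−1)) over unordered
observer pairs. For n = 4 exchangeable curves the printed form concentrates
near 1/3 (its denominator is 2(n−1)/(n−2) = 3 times the unordered mean),
so only the classical form supports the interpretation "WI ≥ 1 means
computer-observer agreement comparable to inter-observer agreement"; the
self-consistency check and the worked example therefore use
`denominator_form="standard"`, while `"printed"` remains the default of
`williams_index` so both conventions stay reproducible.

The overlapping and difference ratios are normalized by the union area,
OR = |A∩B|/|A∪B| and DR = |AΔB|/|A∪B|, which makes OR + DR = 1 an exact
identity, so either ratio determines the other in any reported table.
The "average" manual region is the majority-vote region (pixels
covered by at least ⌈n/2⌉ observers); boundary curves are pixel centers of
the 8-connected outer contour obtained by Moore tracing.

## Phantoms and the observer model

The nodule phantom emulates a part-solid-nodule ROI after 8-bit rescale:
parenchyma 30, GGO halo 110, vessel 180, wall band 220, solid core 240,
with additive Gaussian noise (σ = 8 by default) clipped to [0, 255]. The
five structure intensities are pairwise distinct so that each of the four
semantic classes is identifiable from gray values alone (class 3,
vessel + GGO, is deliberately bimodal). Seed strokes are short interior
lines with a safety margin to every class boundary; class 3 gets one
stroke per connected structure. Geometry, intensities, noise and seed are
all part of `PhantomSpec`, and generation is a pure function of the spec.

Simulated observers displace the ground-truth radial contour by a smooth
zero-mean random field (6 random Fourier harmonics, RMS amplitude 2 px,
360 contour points, 4 observers), standing in for independent manual
delineations. The Williams-index self-consistency statistic is the mean
over 25 simulated nodules, mirroring how such indices are reported as
dataset means; a single-nodule WI has sampling sd ≈ 0.14 under this model,
too noisy to support a statement about the index itself.

What the phantoms do not emulate: CT acquisition physics (beam hardening,
reconstruction kernels), partial-volume blur at tissue interfaces,
spatially correlated noise, irregular nodule shapes (regions are
star-shaped, as the radial observer model requires), and juxta-pleural or
vessel-attached nodules. Passing phantom recovery therefore demonstrates
the correctness of the machinery — hierarchy construction, exact and
approximate inference, metric arithmetic — not clinical-grade accuracy on
real CT, where class histograms overlap far more.

## Problem sizes and numerical choices

Default experiments use 128×128 ROIs, the Q ladder 1…256 (presets 32, 128,
512 reproduce the coarser/finer ranges), 100 random trees with ≤ 12 leaves
for the exactness check, and 6–25 phantom nodules for the agreement
statistics; at these sizes the full pipeline runs in well under a second
per ROI and the complete acceptance script in a few seconds. Degenerate
inputs are rejected explicitly: empty images, empty seed classes, labels
violating completeness/non-overlap, coinciding observers (the
inter-observer 1/AD is undefined), observer amplitudes exceeding the
region inradius, and non-nested ladders.

## Known limitations

* The region-level coarsening pass evaluates couples by current pooled
  means in a fixed sorted order; like all greedy SRM variants it has no
  optimality guarantee for the partition itself (the guarantees here
  concern nesting, the UCM round-trip and the CRF optimum given the tree).
* With per-pixel (additive) unaries, the tree constrains the *support* of
  labellings but not the attainable pixel labellings: any leaf-constant
  label map is realizable, so the optimum coincides with a flat CRF over
  the leaf graph. The hierarchy still determines the leaves and provides
  the multi-scale analysis; per-segment unaries (where the tree genuinely
  matters) are available but non-additive and outside the exactness
  guarantee.
* Automatic selection of Q is out of scope — the ladder range is a user
  choice, as in the underlying method.
* All processing is 2-D; no volumetric segmentation or 3-D metrics.
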