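# aphseg

Seed-driven multi-label segmentation of pulmonary-nodule ROIs in CT slices,
built on a hierarchy of statistical-region-merging partitions and a
tree-constrained conditional random field solved by graph cuts.

Part-solid lung nodules mix a bright solid core with a hazy ground-glass
(GGO) halo, often near vessels and the pleural wall; single-scale,
intensity-only methods delineate them inconsistently. `aphseg` segments a
user-selected ROI into K anatomy classes (parenchyma, lung wall, vessel/GGO,
solid nodule) from a few scribbles, and ships the boundary-agreement
statistics used to compare computer boundaries against multiple manual
delineations, plus a phantom generator so everything is testable without
clinical data.

## Method

1. **Statistical region merging (SRM).** All 4-adjacent pixel couples are
   sorted by |I_p − I_p′| and traversed once; regions R, R′ merge when
   |mean(R) − mean(R′)| ≤ √(b²(R) + b²(R′)) with
   b(R) = g·√(ln(1/δ) / (2 Q |R|)), δ = 1/(6|I|²). The complexity parameter
   Q sets the coarseness: large Q resolves fine structure.
2. **Nested hierarchy and ultrametric contour map (UCM).** Pixel-level SRM
   at the largest Q of the ladder (powers of two, 1…256 by default) gives
   the finest partition; each smaller Q coarsens it by region-level merging,
   so the family is nested by construction and condenses into a tree of
   regions ordered by inclusion (leaves = finest regions, root = whole ROI).
   Each interpixel contour carries the scale index at which it vanishes;
   thresholding this UCM at level λ recovers the partition at that level.
3. **Anatomy packing.** Scribbles for K classes yield smoothed gray-value
   histograms h(·; k). Labelling the tree's segment pool minimizes
   E(Y) = Σ_selected Σ_{p∈q} −log h(I_p; y) + γ Σ_{(i,j)} [y_i ≠ y_j]
   exp(−β (I_i − I_j)²), subject to every pixel being covered by exactly one
   selected segment and no two nested segments both selected. For K = 2 the
   minimum is found exactly by a single min-cut on a pylon-style graph; for
   K > 2, alpha-expansion sweeps of such binary cuts with strict-descent
   acceptance.
4. **Evaluation.** Average symmetric boundary distance (AD), modified
   Williams index, percentage statistic, and union-normalized overlapping /
   difference ratios (OR + DR = 1) against n ≥ 3 manual delineations.

## Worked example

Generate a 128×128 part-solid-nodule phantom (noise σ = 8) with seeds and
four simulated observers, segment it, and score the nodule boundary:

```sh
aphs phantom --kind nodule --noise 8 --seed 1 --out phantom
aphs segment --roi phantom/image.png --seeds phantom/seeds.png \
             --out seg --q-max 256
aphs eval --pred seg/labelmap_raw.png --observers phantom \
          --nodule-row 64 --nodule-col 64 \
          --denominator-form standard --out report.json
```

which prints

```
segments: 7 nodes (6 leaves), final energy 52219.6; artifacts in seg
{
  "williams_index": 1.3870269970180746,
  "percentage_statistic": 100.0,
  "overlapping_ratio": 0.9433606041535557,
  "difference_ratio": 0.056639395846444306
}
```

The hierarchy condenses the noisy phantom into 6 leaf segments (the five
anatomic structures plus background detail); alpha-expansion reduces the
CRF energy to 52 220 over its accepted moves. A Williams index above 1
means the computer boundary is closer to the simulated observers than they
are to each other; 94% of the nodule area overlaps the majority-vote
observer region, and every computer-to-observer distance stays within the
corresponding maximum inter-observer distance (percentage statistic 100%).

The same pipeline is available as a library:

```python
import aphseg

spec = aphseg.PhantomSpec(noise_sigma=8.0, rng_seed=0)
img, gt, seeds = aphseg.make_nodule_phantom(spec)
res = aphseg.run_pipeline(img, seeds, aphseg.RunConfig())
print((res.labelmap == gt).mean())   # 1.0
```

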