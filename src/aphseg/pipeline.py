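"""End-to-end segmentation pipeline and run evaluation.

The pipeline executes the five algorithm stages in order: (1) take the ROI
image, (2) build the nested multi-scale family of SRM partitions over the
``Q`` ladder, (3) condense it into the segmentation tree and its
ultrametric contour map, (4) turn the seed scribbles into per-class
histogram models, (5) minimize the tree-constrained CRF energy by graph
cut / alpha-expansion and realize the selected segments as a pixel label
map.  Everything is deterministic for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hierarchy import (ScaleLadder, SegmentationTree, UCMap,
                        build_nested_ladder, build_tree, compute_ucm,
                        default_q_ladder)
from .metrics import (DelineationSet, MetricsReport, evaluate_delineations,
                      trace_boundary)
from .packing import (EnergyParams, Labeling, labeling_to_pixelmap,
                      solve_multilabel)
from .seeding import build_histograms, seeds_from_raster
from .srm import SrmParams

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "evaluate_run",
           "nodule_mask_from_labels"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one segmentation run.

    ``q_max`` bounds the power-of-two ladder 1, 2, ..., q_max (256 by
    default; 32/128/512 reproduce the coarser/finer presets).  ``beta`` may
    be the string ``"auto"`` for contrast normalization.
    """

    n_labels: int = 4
    q_max: int = 256
    gamma: float = 50.0
    beta: float | str = "auto"
    bins: int = 64
    epsilon: float = 1e-6
    hard_seeds: bool = False
    max_sweeps: int = 10
    merge_bound: str = "simple"
    unary_mode: str = "per_pixel"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.q_max < 1:
            raise ValueError("q_max must be >= 1")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")

    @property
    def q_values(self) -> list[int]:
        return default_q_ladder(self.q_max)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    labelmap: np.ndarray
    labeling: Labeling
    tree: SegmentationTree
    ladder: ScaleLadder
    ucm: UCMap
    energy_trace: list[float]
    config: RunConfig
    manifest: dict = field(default_factory=dict)


def run_pipeline(img: np.ndarray, seed_raster: np.ndarray,
                 config: RunConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full segmentation on an 8-bit ROI with a seed raster.

    When ``out_dir`` is given, all intermediates (label map, UCM, tree,
    finest partition, manifest) are written there.
    """
    if config is None:
        config = RunConfig()
    arr = np.asarray(img)
    seeds_arr = np.asarray(seed_raster)
    if arr.shape != seeds_arr.shape:
        raise ValueError("ROI and seed raster shapes differ")

    srm_params = SrmParams(q=float(config.q_max), bound=config.merge_bound)
    ladder = build_nested_ladder(arr, config.q_values, params=srm_params)
    tree = build_tree(ladder)
    ucm = compute_ucm(ladder)

    seeds = seeds_from_raster(seeds_arr, n_labels=config.n_labels)
    model = build_histograms(arr, seeds, bins=config.bins,
                             epsilon=config.epsilon)
    params = EnergyParams(n_labels=config.n_labels, gamma=config.gamma,
                          beta=config.beta)

    pins = None
    if config.hard_seeds:
        pins = np.zeros(tree.n_leaves, dtype=np.int64)
        leaf_lab = ladder.levels[0].labels
        for k, rc in enumerate(seeds.coords, start=1):
            for leaf in np.unique(leaf_lab[rc[:, 0], rc[:, 1]]):
                # a leaf seeded by several classes stays free
                pins[leaf] = 0 if pins[leaf] not in (0, k) else k

    labeling, trace = solve_multilabel(tree, arr, model, params,
                                       max_sweeps=config.max_sweeps,
                                       pins=pins, return_trace=True)
    labelmap = labeling_to_pixelmap(tree, labeling)

    result = PipelineResult(labelmap=labelmap, labeling=labeling, tree=tree,
                            ladder=ladder, ucm=ucm, energy_trace=trace,
                            config=config)
    if out_dir is not None:
        from . import io as aio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        aio.save_labelmap(out / "labelmap.png", labelmap,
                          raster_path=out / "labelmap_raw.png")
        aio.save_partition(out / "finest_partition.png",
                           out / "finest_partition.json", ladder.levels[0])
        aio.save_ucm_png(out / "ucm.png", ucm)
        aio.save_ucm_edges(out / "ucm_edges.csv", ucm)
        aio.save_tree(out / "tree.json", tree)
        aio.write_manifest(out / "manifest.json", config.to_dict(),
                           extra={"energy_trace": trace})
        result.manifest = {"out_dir": str(out)}
    return result


def nodule_mask_from_labels(labelmap: np.ndarray,
                            around: tuple[int, int]) -> np.ndarray:
    """Nodule region (GGO halo + solid core) from a 4-class label map.

    Takes the connected component of classes {3, 4} containing ``around``
    (row, col), which excludes the vessel — also class 3, but spatially
    separate.
    """
    from scipy import ndimage

    mask = np.isin(labelmap, (3, 4))
    lab, _ = ndimage.label(mask)
    comp = lab[around]
    if comp == 0:
        raise ValueError("no nodule tissue at the given position")
    return lab == comp


def evaluate_run(computer_mask: np.ndarray,
                 observer_curves: list[np.ndarray],
                 denominator_form: str = "printed") -> MetricsReport:
    """Score one computer region against observer delineation curves."""
    if len(observer_curves) < 3:
        raise ValueError("at least three observer delineations are required")
    ds = DelineationSet(computer=trace_boundary(computer_mask),
                        observers=observer_curves)
    return evaluate_delineations([ds], shape=np.asarray(computer_mask).shape,
                                 denominator_form=denominator_form)
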