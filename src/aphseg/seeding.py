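"""Seed scribbles and per-class intensity histogram models.

User scribbles (or generated phantom strokes) mark K semantic classes —
typically parenchyma, lung wall, vessel/GGO and solid nodule.  The prior
carried into the inference is purely photometric: one smoothed, normalized
gray-value histogram per class, estimated from the seed pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SeedSet", "HistogramModel", "seeds_from_raster", "build_histograms"]


@dataclass
class SeedSet:
    """Per-class seed pixel coordinates.

    ``coords[k-1]`` is an ``(m_k, 2)`` array of (row, col) positions for
    class ``k`` in ``1..K``.  Classes are disjoint by construction (a raster
    can carry one label per pixel) and every class has at least one seed.
    """

    n_labels: int
    coords: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.n_labels < 2:
            raise ValueError("at least two semantic classes are required")
        if len(self.coords) != self.n_labels:
            raise ValueError("one coordinate set per class is required")
        for k, c in enumerate(self.coords, start=1):
            if c.shape[0] == 0:
                raise ValueError(f"class {k} has no seed pixels")


def seeds_from_raster(seed_img: np.ndarray, n_labels: int | None = None) -> SeedSet:
    """Convert an integer seed raster (0 = unlabeled, k = class k) to a SeedSet."""
    arr = np.asarray(seed_img)
    if arr.ndim != 2:
        raise ValueError("seed raster must be 2-D")
    if arr.min() < 0:
        raise ValueError("seed raster must be non-negative")
    k_max = int(arr.max())
    if k_max == 0:
        raise ValueError("seed raster contains no seeds")
    k = n_labels if n_labels is not None else k_max
    coords = []
    for label in range(1, k + 1):
        rc = np.argwhere(arr == label)
        if rc.shape[0] == 0:
            raise ValueError(f"class {label} has no seed pixels")
        coords.append(rc)
    return SeedSet(n_labels=k, coords=coords)


@dataclass
class HistogramModel:
    """Smoothed per-class gray-value histograms over ``bins`` equal-width bins.

    ``h[k-1]`` sums to 1 and is everywhere positive (add-epsilon smoothing),
    so histogram log-likelihood costs are always finite.
    """

    bins: int
    h: np.ndarray          # (K, bins)
    epsilon: float
    g: int = 256

    @property
    def n_labels(self) -> int:
        return int(self.h.shape[0])

    def bin_of(self, intensities: np.ndarray) -> np.ndarray:
        """Bin index of each intensity on the equal-width grid over [0, g-1]."""
        idx = (np.asarray(intensities, dtype=np.int64) * self.bins) // self.g
        return np.minimum(idx, self.bins - 1)


def build_histograms(img: np.ndarray, seeds: SeedSet, bins: int = 64,
                     epsilon: float = 1e-6, g: int = 256) -> HistogramModel:
    """Estimate the per-class histogram model from seed-pixel intensities.

    Each class histogram is ``(counts + eps) / (n_k + bins * eps)``: proper,
    strictly positive, and invariant to the ordering of seed pixels.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    arr = np.asarray(img)
    model = np.empty((seeds.n_labels, bins), dtype=np.float64)
    tmp = HistogramModel(bins=bins, h=model, epsilon=epsilon, g=g)
    for k, rc in enumerate(seeds.coords):
        vals = arr[rc[:, 0], rc[:, 1]]
        counts = np.bincount(tmp.bin_of(vals), minlength=bins).astype(np.float64)
        model[k] = (counts + epsilon) / (vals.size + bins * epsilon)
    return tmp
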