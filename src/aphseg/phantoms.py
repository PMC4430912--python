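"""Synthetic phantom images for testing without clinical data.

Two image families are generated, both pure functions of their
specification and seed:

* *nested-intensity phantoms* — concentric disks of distinct gray levels on
  a background, for exercising region merging and hierarchy construction;
* *lung-ROI nodule phantoms* — a dark parenchyma background, a bright lung
  wall band along one edge, a part-solid nodule (bright solid core inside an
  intermediate-intensity ground-glass halo), and a thin bright vessel, with
  additive Gaussian noise.  Ground truth uses K = 4 semantic classes:
  1 parenchyma, 2 wall, 3 vessel + GGO, 4 solid core.

The module also simulates manual "observers": closed boundary curves
obtained by displacing the ground-truth contour radially with a smooth
zero-mean random field (a small number of random Fourier harmonics), which
stands in for independent human delineations of the same nodule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .srm import Partition, _canonical_partition

__all__ = [
    "PhantomSpec",
    "ObserverModel",
    "make_nested_phantom",
    "make_nodule_phantom",
    "nodule_gt_mask",
    "simulate_observers",
    "radial_contour",
]

#: default structure gray levels after [0, 255] CT rescale; chosen to order
#: the tissues plausibly (parenchyma << GGO < vessel < wall < solid) with
#: every structure separable by intensity
DEFAULT_MEANS = {
    "parenchyma": 30,
    "ggo": 110,
    "vessel": 180,
    "wall": 220,
    "solid": 240,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of the 4-class lung-ROI phantom."""

    size: tuple[int, int] = (128, 128)
    wall_width: int = 12
    core_center: tuple[int, int] = (64, 64)     # (row, col)
    core_radius: float = 10.0
    halo_radius: float = 22.0
    vessel_col: int = 104
    vessel_width: int = 3
    means: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    noise_sigma: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        r, c = self.core_center
        if self.core_radius >= self.halo_radius:
            raise ValueError("solid core must fit inside the GGO halo")
        if (r - self.halo_radius < 0 or r + self.halo_radius >= h
                or c - self.halo_radius <= self.wall_width
                or c + self.halo_radius >= self.vessel_col - self.vessel_width):
            raise ValueError("nodule geometry overflows the ROI interior")
        if self.vessel_col + self.vessel_width > w:
            raise ValueError("vessel overflows the ROI")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(set(self.means.values())) != len(self.means):
            raise ValueError("structure mean intensities must be distinct")


@dataclass(frozen=True)
class ObserverModel:
    """Radial-perturbation model of independent manual delineations."""

    n_observers: int = 4
    amplitude: float = 2.0
    n_harmonics: int = 6
    n_points: int = 360
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_observers < 3:
            raise ValueError("at least three observers are required")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.n_harmonics < 1:
            raise ValueError("at least one harmonic is required")


def make_nested_phantom(levels: list[int],
                        size: tuple[int, int] = (64, 64)
                        ) -> tuple[np.ndarray, Partition]:
    """Concentric-disk phantom with the given intensities, outermost first.

    ``levels[0]`` fills the background; each subsequent intensity fills a
    concentric disk of shrinking radius.  Returns the image and the
    ground-truth partition (one region per intensity band).
    """
    if len(levels) < 2:
        raise ValueError("at least two intensity levels are required")
    if len(set(levels)) != len(levels):
        raise ValueError("intensity levels must be distinct")
    h, w = size
    rr, cc = np.mgrid[0:h, 0:w]
    dist = np.sqrt((rr - (h - 1) / 2.0) ** 2 + (cc - (w - 1) / 2.0) ** 2)
    img = np.full(size, levels[0], dtype=np.uint8)
    region = np.zeros(size, dtype=np.int64)
    r_max = min(h, w) / 2.0 - 2.0
    n_disks = len(levels) - 1
    for i, val in enumerate(levels[1:], start=1):
        radius = r_max * (n_disks - i + 1) / n_disks
        inside = dist <= radius
        img[inside] = val
        region[inside] = i
    return img, _canonical_partition(region, img.astype(np.float64))


def make_nodule_phantom(spec: PhantomSpec
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Part-solid-nodule ROI phantom.

    Returns ``(image, ground_truth, seed_raster)``: an 8-bit image, the
    per-pixel class map in 1..4, and a seed raster with one interior stroke
    per structure (class 3 receives one stroke in the GGO halo and one in
    the vessel, since its two structures are disjoint).  Deterministic for a
    fixed ``spec.rng_seed``.
    """
    h, w = spec.size
    rr, cc = np.mgrid[0:h, 0:w]
    r0, c0 = spec.core_center
    dist = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)

    clean = np.full(spec.size, spec.means["parenchyma"], dtype=np.float64)
    gt = np.ones(spec.size, dtype=np.int64)

    wall = cc < spec.wall_width
    clean[wall] = spec.means["wall"]
    gt[wall] = 2

    vessel = (cc >= spec.vessel_col) & (cc < spec.vessel_col + spec.vessel_width)
    clean[vessel] = spec.means["vessel"]
    gt[vessel] = 3

    halo = dist <= spec.halo_radius
    clean[halo] = spec.means["ggo"]
    gt[halo] = 3

    core = dist <= spec.core_radius
    clean[core] = spec.means["solid"]
    gt[core] = 4

    rng = np.random.default_rng(spec.rng_seed)
    noisy = clean + rng.normal(0.0, spec.noise_sigma, size=spec.size)
    img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    seeds = np.zeros(spec.size, dtype=np.int64)
    seeds[10, 20:41] = 1                                   # parenchyma stroke
    seeds[h // 4: 3 * h // 4, spec.wall_width // 2] = 2    # wall stroke
    ggo_col = int(c0 + spec.core_radius + 3)
    seeds[r0 - 5: r0 + 6, ggo_col] = 3                     # GGO stroke
    seeds[h // 4: h // 2, spec.vessel_col + spec.vessel_width // 2] = 3
    seeds[r0 - 4: r0 + 5, c0] = 4                          # solid-core stroke

    for k in range(1, 5):
        stroke = seeds == k
        if not np.all(gt[stroke] == k):
            raise AssertionError(f"seed stroke for class {k} leaves its region")
    return img, gt, seeds


def nodule_gt_mask(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth nodule region (GGO halo + solid core) of a phantom."""
    h, w = spec.size
    rr, cc = np.mgrid[0:h, 0:w]
    r0, c0 = spec.core_center
    return np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2) <= spec.halo_radius


def radial_contour(mask: np.ndarray, n_points: int = 360,
                   center: tuple[float, float] | None = None
                   ) -> tuple[tuple[float, float], np.ndarray, np.ndarray]:
    """Polar boundary representation of a (star-shaped) region.

    Returns ``(center (row, col), angles, radii)`` where ``radii[i]`` is the
    largest radius along ``angles[i]`` still inside the region.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty region")
    rows, cols = np.nonzero(m)
    if center is None:
        center = (float(rows.mean()), float(cols.mean()))
    r0, c0 = center
    angles = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r_max = float(np.hypot(m.shape[0], m.shape[1]))
    steps = np.arange(0.0, r_max, 0.25)
    rr = np.clip(np.rint(r0 + np.outer(np.sin(angles), steps)), 0, m.shape[0] - 1)
    cc = np.clip(np.rint(c0 + np.outer(np.cos(angles), steps)), 0, m.shape[1] - 1)
    inside = m[rr.astype(int), cc.astype(int)]
    # last inside step before the first outside step along each ray
    first_out = np.argmin(inside, axis=1)
    first_out[inside.all(axis=1)] = steps.size
    radii = steps[np.maximum(first_out - 1, 0)]
    return center, angles, radii


def simulate_observers(gt_mask: np.ndarray, model: ObserverModel,
                       rng: np.random.Generator | None = None,
                       n_curves: int | None = None) -> list[np.ndarray]:
    """Simulated manual delineations of one region.

    Each observer displaces the ground-truth radial contour by a smooth
    zero-mean random field ``dr(theta) = sum_h a_h cos(h theta) + b_h
    sin(h theta)`` whose coefficients are scaled so the field's RMS
    amplitude equals ``model.amplitude`` pixels.  Returns ``n_observers``
    (or ``n_curves``) closed (x, y) curves; fixed seed, fixed output.
    """
    if rng is None:
        rng = np.random.default_rng(model.rng_seed)
    (r0, c0), angles, radii = radial_contour(gt_mask, model.n_points)
    inradius = float(radii.min())
    if model.amplitude >= inradius:
        raise ValueError(
            f"amplitude {model.amplitude} exceeds the region inradius "
            f"{inradius:.2f}")
    n = model.n_observers if n_curves is None else n_curves
    sigma = model.amplitude / np.sqrt(model.n_harmonics)
    curves = []
    for _ in range(n):
        dr = np.zeros_like(angles)
        for harm in range(1, model.n_harmonics + 1):
            a, b = rng.normal(0.0, sigma, size=2)
            dr += a * np.cos(harm * angles) + b * np.sin(harm * angles)
        r = np.maximum(radii + dr, 0.5)
        x = c0 + r * np.cos(angles)
        y = r0 + r * np.sin(angles)
        curves.append(np.stack([x, y], axis=1))
    return curves
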