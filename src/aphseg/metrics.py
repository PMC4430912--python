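"""Boundary-agreement metrics against multiple manual delineations.

Four statistics compare one computer-generated boundary with ``n`` manual
delineations of the same nodule:

* the *average distance* ``AD(X, Y)`` — the symmetric mean closest-point
  distance between two boundary point sets;
* the *modified Williams index* — the ratio of computer-to-observer
  agreement (harmonic-type mean of ``1/AD``) to inter-observer agreement;
  a value near or above 1 means the computer boundary is as close to the
  observers as they are to each other;
* the *percentage statistic* — the percentage of computer-to-observer
  distances not exceeding the corresponding maximum inter-observer
  distance;
* the *overlapping/difference ratios* of the computer region against an
  average (majority-vote) manual region.  These are normalized by the union
  area so that ``OR + DR = 1`` holds identically.

Two Williams-index denominator normalizations are provided:
``"printed"``, ``2/(n(n-2))`` with the full ordered double sum, and
``"standard"``, the classical ``2/(n(n-1))`` over unordered observer pairs.
Only the standard form equals 1 when all curves are exchangeable; the
printed form is kept selectable (and default) for fidelity, but
self-consistency statements use the standard form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DelineationSet",
    "MetricsReport",
    "DegenerateObserversError",
    "average_distance",
    "williams_index",
    "percentage_statistic",
    "overlap_difference",
    "mean_manual_region",
    "trace_boundary",
    "curve_to_mask",
    "evaluate_delineations",
]


class DegenerateObserversError(ValueError):
    """Two observer boundaries coincide; ``1/AD`` is undefined."""


def _as_curve(points: np.ndarray) -> np.ndarray:
    arr = np.asarray(points, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("a boundary curve must be a non-empty (N, 2) array")
    return arr


@dataclass
class DelineationSet:
    """One computer boundary plus ``n >= 3`` observer boundaries.

    Curves are ``(N, 2)`` arrays of (x=col, y=row) pixel-center
    coordinates, ordered along the closed contour.
    """

    computer: np.ndarray
    observers: list[np.ndarray]

    def __post_init__(self) -> None:
        self.computer = _as_curve(self.computer)
        self.observers = [_as_curve(o) for o in self.observers]

    @property
    def n_observers(self) -> int:
        return len(self.observers)


@dataclass
class MetricsReport:
    """The four agreement statistics for one computer boundary."""

    williams_index: float
    percentage_statistic: float
    overlapping_ratio: float
    difference_ratio: float

    def to_dict(self) -> dict:
        return {
            "williams_index": self.williams_index,
            "percentage_statistic": self.percentage_statistic,
            "overlapping_ratio": self.overlapping_ratio,
            "difference_ratio": self.difference_ratio,
        }


def average_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric mean closest-point distance between two boundaries.

    ``AD = 1/2 (mean_i min_j |y_j - x_i| + mean_j min_i |x_i - y_j|)``,
    Euclidean in pixel units.  Non-negative, symmetric, and zero iff the two
    point sets coincide.
    """
    xc, yc = _as_curve(x), _as_curve(y)
    d_xy = cKDTree(yc).query(xc)[0].mean()
    d_yx = cKDTree(xc).query(yc)[0].mean()
    return 0.5 * float(d_xy + d_yx)


def williams_index(ds: DelineationSet,
                   denominator_form: str = "printed") -> float:
    """Modified Williams index of the computer boundary.

    Numerator: mean of ``1/AD(C, O_j)`` over the ``n`` observers.
    Denominator: normalized sum of inter-observer ``1/AD``; see the module
    docstring for the two selectable normalizations.
    """
    if denominator_form not in ("printed", "standard"):
        raise ValueError(f"unknown denominator form: {denominator_form!r}")
    n = ds.n_observers
    if n < 3:
        raise ValueError("the Williams index needs at least three observers")

    ad_obs = np.zeros((n, n))
    for k in range(n):
        for j in range(k + 1, n):
            ad = average_distance(ds.observers[k], ds.observers[j])
            if ad == 0.0:
                raise DegenerateObserversError(
                    f"observers {k} and {j} coincide; inter-observer 1/AD "
                    "is undefined")
            ad_obs[k, j] = ad_obs[j, k] = ad

    num = np.mean([1.0 / average_distance(ds.computer, o)
                   for o in ds.observers])
    if denominator_form == "printed":
        total = sum(1.0 / ad_obs[k, j]
                    for k in range(n) for j in range(n) if j != k)
        den = 2.0 / (n * (n - 2)) * total
    else:
        total = sum(1.0 / ad_obs[k, j]
                    for k in range(n) for j in range(k + 1, n))
        den = 2.0 / (n * (n - 1)) * total
    return float(num / den)


def percentage_statistic(ds_list: list[DelineationSet]) -> float:
    """Percentage of computer-to-observer distances within the maximum
    inter-observer distance of the same reference observer.

    Pooled over every (nodule, reference observer) couple; invariant to
    observer ordering.
    """
    if not ds_list:
        raise ValueError("at least one delineation set is required")
    hits = 0
    total = 0
    for ds in ds_list:
        n = ds.n_observers
        if n < 2:
            raise ValueError("the percentage statistic needs >= 2 observers")
        ad_obs = np.zeros((n, n))
        for k in range(n):
            for j in range(k + 1, n):
                ad_obs[k, j] = ad_obs[j, k] = average_distance(
                    ds.observers[k], ds.observers[j])
        for j in range(n):
            ad_cj = average_distance(ds.computer, ds.observers[j])
            max_inter = max(ad_obs[j, k] for k in range(n) if k != j)
            hits += ad_cj <= max_inter
            total += 1
    return 100.0 * hits / total


def overlap_difference(computer_region: np.ndarray,
                       manual_region: np.ndarray) -> tuple[float, float]:
    """Overlapping and difference ratios of two binary regions.

    ``OR = |A ∩ B| / |A ∪ B|`` and ``DR = |A Δ B| / |A ∪ B|``; the union
    normalization makes ``OR + DR = 1`` hold exactly.
    """
    a = np.asarray(computer_region, dtype=bool)
    b = np.asarray(manual_region, dtype=bool)
    if not a.any() or not b.any():
        raise ValueError("regions must be non-empty")
    union = np.logical_or(a, b).sum()
    inter = np.logical_and(a, b).sum()
    return float(inter / union), float((union - inter) / union)


def mean_manual_region(observer_regions: list[np.ndarray]) -> np.ndarray:
    """Majority-vote average region: pixels covered by >= ceil(n/2) observers."""
    if not observer_regions:
        raise ValueError("at least one observer region is required")
    stack = np.stack([np.asarray(m, dtype=bool) for m in observer_regions])
    need = -(-stack.shape[0] // 2)  # ceil(n/2)
    return stack.sum(axis=0) >= need


# ---------------------------------------------------------------------------
# curve <-> region helpers
# ---------------------------------------------------------------------------

# Moore neighbourhood in clockwise order starting from west
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered closed contour of a connected region, as pixel centers.

    Moore-neighbour tracing of the 8-connected outer boundary, returned as
    an ``(N, 2)`` array of (x=col, y=row) coordinates.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty region has no boundary")
    rows, cols = np.nonzero(m)
    start = (int(rows[0]), int(cols[np.argmin(cols[rows == rows[0]])]))

    def fg(r: int, c: int) -> bool:
        return 0 <= r < m.shape[0] and 0 <= c < m.shape[1] and m[r, c]

    contour = [start]
    # backtrack: the background neighbour we entered from (west of start)
    back = (start[0], start[1] - 1)
    cur = start
    first_next = None
    for _ in range(8 * m.size):
        dr, dc = back[0] - cur[0], back[1] - cur[1]
        k0 = _MOORE.index((dr, dc))
        nxt = None
        for step in range(1, 9):
            dr, dc = _MOORE[(k0 + step) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if fg(*cand):
                nxt = cand
                break
            back = cand
        if nxt is None:          # isolated pixel
            break
        if nxt == start:
            if first_next is None or contour[1] == first_next:
                break
        if first_next is None and len(contour) == 1:
            first_next = nxt
        contour.append(nxt)
        cur = nxt
        if nxt == start:
            contour.pop()
            break
    pts = np.array([(c, r) for r, c in contour], dtype=np.float64)
    return pts


def curve_to_mask(curve: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed (x, y) polygon to the region it encloses."""
    from skimage.draw import polygon

    c = _as_curve(curve)
    rr, cc = polygon(c[:, 1], c[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def evaluate_delineations(ds_list: list[DelineationSet],
                          shape: tuple[int, int],
                          denominator_form: str = "printed") -> MetricsReport:
    """All four statistics, averaged over a list of delineation sets."""
    wis, ors, drs = [], [], []
    for ds in ds_list:
        wis.append(williams_index(ds, denominator_form))
        comp = curve_to_mask(ds.computer, shape)
        manual = mean_manual_region([curve_to_mask(o, shape)
                                     for o in ds.observers])
        o, d = overlap_difference(comp, manual)
        ors.append(o)
        drs.append(d)
    return MetricsReport(
        williams_index=float(np.mean(wis)),
        percentage_statistic=percentage_statistic(ds_list),
        overlapping_ratio=float(np.mean(ors)),
        difference_ratio=float(np.mean(drs)),
    )
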