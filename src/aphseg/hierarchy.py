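"""Multi-scale segment hierarchy and ultrametric contour map (UCM).

A *scale ladder* is a family of strictly nested partitions: the finest level
is pixel-level SRM at the largest ``Q``; each coarser level re-applies the
SRM merging predicate at a smaller ``Q`` to adjacent region couples of the
previous level (region-level merging on the region-adjacency graph, couples
sorted by mean-intensity difference).  Running SRM independently per ``Q``
would not guarantee nesting; deriving each level from the previous one makes
the strong-causality axiom (finer boundary sets contain coarser ones) true by
construction.  A final root level always merges the whole ROI.

The hierarchy is represented two ways:

* a :class:`SegmentationTree` of regions ordered by inclusion — one node per
  maximal region over its lifetime, leaves at the finest level, whole image
  at the root;
* a :class:`UCMap`, which stores for every interpixel edge the *level index*
  at which the contour separating its two sides vanishes.  Thresholding the
  map at level ``lam`` recovers exactly the ladder partition at that level.

Scale is discrete here: level 0 is the finest partition and level ``lam1``
(the last) is the root; the continuous scale parameter of ultrametric
hierarchies is not needed with finitely many levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .srm import Partition, SrmParams, _canonical_partition, merge_predicate

__all__ = [
    "ScaleLadder",
    "SegmentationTree",
    "UCMap",
    "default_q_ladder",
    "build_nested_ladder",
    "build_tree",
    "tree_from_parents",
    "compute_ucm",
    "threshold_ucm",
]


def default_q_ladder(q_max: int = 256) -> list[int]:
    """Powers of two from 1 up to (and including) ``q_max``."""
    if q_max < 1:
        raise ValueError("q_max must be >= 1")
    qs = []
    q = 1
    while q <= q_max:
        qs.append(q)
        q *= 2
    return qs


@dataclass
class ScaleLadder:
    """Nested partitions from fine (level 0) to the one-region root level.

    ``levels[k]`` is the partition at level index ``k``; ``level_q[k]`` is
    the SRM complexity used there (``None`` for the forced root level).
    ``maps[k]`` sends region ids of ``levels[k]`` to region ids of
    ``levels[k+1]`` (containment).
    """

    q_values: list[int]
    levels: list[Partition]
    level_q: list[int | None]
    maps: list[np.ndarray] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        """Index of the top (root) level, i.e. ``lam1``."""
        return len(self.levels) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.levels[0].shape


def _region_adjacency(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique adjacent region-id couples (a < b) of a label image."""
    pairs = []
    for u, v in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        m = u != v
        pairs.append(np.stack([np.minimum(u[m], v[m]), np.maximum(u[m], v[m])], axis=1))
    if not pairs:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ab = np.unique(np.concatenate(pairs, axis=0), axis=0)
    return ab[:, 0].astype(np.int64), ab[:, 1].astype(np.int64)


def _merge_regions(part: Partition, params: SrmParams, n_pixels: int,
                   img: np.ndarray) -> tuple[Partition, np.ndarray]:
    """One region-level SRM pass over the region-adjacency graph.

    Couples are traversed in increasing order of ``|mean(R) - mean(R')|``,
    ties broken by the (smaller id, larger id) couple, each couple once.
    Returns the coarser partition and the old-id -> new-id map.
    """
    from .srm import _UnionFind

    a, b = _region_adjacency(part.labels)
    f = np.abs(part.means[a] - part.means[b])
    order = np.lexsort((b, a, f))
    uf = _UnionFind(part.sizes, part.means * part.sizes)
    for i in order.tolist():
        ra, rb = uf.find(int(a[i])), uf.find(int(b[i]))
        if ra == rb:
            continue
        if merge_predicate(int(uf.size[ra]), uf.mean(ra),
                           int(uf.size[rb]), uf.mean(rb), params, n_pixels):
            uf.union(ra, rb)
    root_of_region = np.fromiter((uf.find(i) for i in range(part.n_regions)),
                                 dtype=np.int64, count=part.n_regions)
    coarse = _canonical_partition(root_of_region[part.labels], img)
    # containment map: any pixel of each old region tells the new id
    mapping = np.empty(part.n_regions, dtype=np.int64)
    flat_old = part.labels.ravel()
    flat_new = coarse.labels.ravel()
    mapping[flat_old] = flat_new
    return coarse, mapping


def build_nested_ladder(img: np.ndarray, q_values: list[int] | None = None,
                        params: SrmParams | None = None) -> ScaleLadder:
    """Build the nested multi-scale family of partitions of ``img``.

    ``q_values`` must be ascending; the finest level is pixel-level SRM at
    ``max(q_values)`` and each smaller ``Q`` produces one coarser level by
    region merging.  A root level (single region) is always appended.
    """
    from .srm import run_srm

    if q_values is None:
        q_values = default_q_ladder()
    if len(q_values) == 0:
        raise ValueError("q_values must contain at least one entry")
    if any(q2 <= q1 for q1, q2 in zip(q_values, q_values[1:])):
        raise ValueError("q_values must be strictly ascending")
    base = params if params is not None else SrmParams(q=q_values[-1])

    arr = np.asarray(img)
    n_pixels = arr.size
    finest = run_srm(arr, SrmParams(q=float(q_values[-1]), g=base.g,
                                    delta=base.delta, bound=base.bound))
    levels = [finest]
    level_q: list[int | None] = [q_values[-1]]
    maps: list[np.ndarray] = []
    for q in reversed(q_values[:-1]):
        p = SrmParams(q=float(q), g=base.g, delta=base.delta, bound=base.bound)
        coarse, mapping = _merge_regions(levels[-1], p, n_pixels, arr)
        levels.append(coarse)
        level_q.append(q)
        maps.append(mapping)

    # forced root level: the whole ROI as a single region
    prev = levels[-1]
    root_labels = np.zeros_like(prev.labels)
    root = Partition(labels=root_labels,
                     sizes=np.array([n_pixels]),
                     means=np.array([float(np.asarray(img, dtype=float).mean())]))
    levels.append(root)
    level_q.append(None)
    maps.append(np.zeros(prev.n_regions, dtype=np.int64))
    return ScaleLadder(q_values=list(q_values), levels=levels,
                       level_q=level_q, maps=maps)


@dataclass
class SegmentationTree:
    """Tree of image regions ordered by inclusion.

    One node per maximal region over its lifetime: a region that persists
    unchanged over several ladder levels is a single node whose
    ``birth_level``/``death_level`` record that span.  Nodes
    ``0 .. n_leaves-1`` are the finest-level regions (leaf node id equals
    finest region id); the root covers the whole ROI.
    """

    parent: np.ndarray             # (N,) parent node id, -1 at the root
    children: list[list[int]]
    birth_level: np.ndarray
    death_level: np.ndarray
    sizes: np.ndarray
    leaf_sets: list[np.ndarray]    # per node, sorted finest-region ids
    root: int
    n_levels: int                  # lam1 of the source ladder
    leaf_labels: np.ndarray | None = None   # (H,W) finest partition labels

    @property
    def n_nodes(self) -> int:
        return int(self.parent.size)

    @property
    def n_leaves(self) -> int:
        return len([c for c in self.children if not c])

    @property
    def leaves(self) -> list[int]:
        return [i for i, c in enumerate(self.children) if not c]

    def ancestors(self, node: int) -> list[int]:
        """Path from ``node`` (inclusive) up to the root."""
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def node_histogram(self, img: np.ndarray, node: int, bins: int = 256,
                       g: int = 256) -> np.ndarray:
        """Intensity histogram of the pixels covered by ``node``."""
        if self.leaf_labels is None:
            raise ValueError("tree carries no pixel-level leaf labels")
        mask = np.isin(self.leaf_labels, self.leaf_sets[node])
        idx = np.minimum((np.asarray(img)[mask].astype(np.int64) * bins) // g,
                         bins - 1)
        return np.bincount(idx, minlength=bins)


def tree_from_parents(parents: list[int], n_levels: int = 1) -> SegmentationTree:
    """Build a bare :class:`SegmentationTree` from a parent list.

    Intended for constructing small synthetic trees (solver tests).  Leaves
    are the nodes without children; each leaf is assigned one synthetic
    finest-region id in node order.
    """
    n = len(parents)
    parent = np.asarray(parents, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    roots = [i for i in range(n) if parent[i] < 0]
    if len(roots) != 1:
        raise ValueError("exactly one root required")
    for i in range(n):
        if parent[i] >= 0:
            children[int(parent[i])].append(i)
    leaves = [i for i in range(n) if not children[i]]
    leaf_rank = {node: k for k, node in enumerate(leaves)}
    leaf_sets: list[np.ndarray] = [np.empty(0, np.int64)] * n
    for i in range(n):
        if not children[i]:
            leaf_sets[i] = np.array([leaf_rank[i]], dtype=np.int64)
    # fill internal nodes bottom-up
    done = [not children[i] for i in range(n)]
    while not all(done):
        for i in range(n):
            if not done[i] and all(done[c] for c in children[i]):
                leaf_sets[i] = np.sort(np.concatenate([leaf_sets[c] for c in children[i]]))
                done[i] = True
    sizes = np.array([leaf_sets[i].size for i in range(n)], dtype=np.int64)
    return SegmentationTree(parent=parent, children=children,
                            birth_level=np.zeros(n, np.int64),
                            death_level=np.zeros(n, np.int64),
                            sizes=sizes, leaf_sets=leaf_sets,
                            root=roots[0], n_levels=n_levels)


def _subtree(children: list[list[int]], i: int) -> list[int]:
    out, stack = [], [i]
    while stack:
        j = stack.pop()
        out.append(j)
        stack.extend(children[j])
    return out


def _check_nested(fine: Partition, coarse: Partition) -> np.ndarray:
    """Containment map fine-region -> coarse-region; raises if not nested."""
    flat_f = fine.labels.ravel()
    flat_c = coarse.labels.ravel()
    pairs = np.unique(np.stack([flat_f, flat_c], axis=1), axis=0)
    if pairs.shape[0] != fine.n_regions:
        raise ValueError("ladder is not nested: a fine region spans several "
                         "coarse regions")
    mapping = np.empty(fine.n_regions, dtype=np.int64)
    mapping[pairs[:, 0]] = pairs[:, 1]
    return mapping


def build_tree(ladder: ScaleLadder) -> SegmentationTree:
    """Condense a nested ladder into a tree of regions ordered by inclusion."""
    lam1 = ladder.n_levels
    n0 = ladder.levels[0].n_regions
    parent: list[int] = [-1] * n0
    children: list[list[int]] = [[] for _ in range(n0)]
    birth: list[int] = [0] * n0
    death: list[int] = [0] * n0
    sizes: list[int] = ladder.levels[0].sizes.tolist()
    leaf_sets: list[np.ndarray] = [np.array([i], dtype=np.int64) for i in range(n0)]

    node_of_region = np.arange(n0, dtype=np.int64)
    for lam in range(1, lam1 + 1):
        mapping = _check_nested(ladder.levels[lam - 1], ladder.levels[lam])
        n_coarse = ladder.levels[lam].n_regions
        new_node_of_region = np.empty(n_coarse, dtype=np.int64)
        for r in range(n_coarse):
            member_regions = np.nonzero(mapping == r)[0]
            member_nodes = sorted({int(node_of_region[m]) for m in member_regions})
            if len(member_nodes) == 1:
                node = member_nodes[0]
                death[node] = lam
            else:
                node = len(parent)
                parent.append(-1)
                children.append(member_nodes)
                birth.append(lam)
                death.append(lam)
                sizes.append(int(ladder.levels[lam].sizes[r]))
                leaf_sets.append(np.sort(np.concatenate([leaf_sets[m] for m in member_nodes])))
                for m in member_nodes:
                    parent[m] = node
            new_node_of_region[r] = node
        node_of_region = new_node_of_region

    root = int(node_of_region[0])
    return SegmentationTree(parent=np.asarray(parent, dtype=np.int64),
                            children=children,
                            birth_level=np.asarray(birth, dtype=np.int64),
                            death_level=np.asarray(death, dtype=np.int64),
                            sizes=np.asarray(sizes, dtype=np.int64),
                            leaf_sets=leaf_sets, root=root, n_levels=lam1,
                            leaf_labels=ladder.levels[0].labels.copy())


@dataclass
class UCMap:
    """Per-interpixel-edge contour saliency.

    ``horiz[r, c]`` is the saliency of the edge between pixels ``(r, c)`` and
    ``(r, c+1)``; ``vert[r, c]`` between ``(r, c)`` and ``(r+1, c)``.
    Saliency is the smallest ladder level at which the two sides fall into
    the same region (0 inside a finest region), so thresholding at level
    ``lam`` — keeping edges with saliency > ``lam`` as boundaries —
    reproduces the partition at that level.
    """

    horiz: np.ndarray
    vert: np.ndarray
    n_levels: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.vert.shape[0] + 1, self.horiz.shape[1] + 1)


def compute_ucm(ladder: ScaleLadder) -> UCMap:
    """Encode a nested ladder as an ultrametric contour map."""
    lam1 = ladder.n_levels
    lab0 = ladder.levels[0].labels
    h_sal = np.zeros((lab0.shape[0], lab0.shape[1] - 1), dtype=np.int32)
    v_sal = np.zeros((lab0.shape[0] - 1, lab0.shape[1]), dtype=np.int32)
    h_open = lab0[:, :-1] != lab0[:, 1:]
    v_open = lab0[:-1, :] != lab0[1:, :]
    for lam in range(1, lam1 + 1):
        lab = ladder.levels[lam].labels
        h_close = h_open & (lab[:, :-1] == lab[:, 1:])
        v_close = v_open & (lab[:-1, :] == lab[1:, :])
        h_sal[h_close] = lam
        v_sal[v_close] = lam
        h_open &= ~h_close
        v_open &= ~v_close
    # edges never merged below the root would remain open, but the root
    # level closes everything; assert that for safety
    assert not h_open.any() and not v_open.any()
    return UCMap(horiz=h_sal, vert=v_sal, n_levels=lam1)


def threshold_ucm(ucm: UCMap, level: int, img: np.ndarray | None = None) -> Partition:
    """Partition whose boundaries are the edges with saliency > ``level``.

    Inverse of :func:`compute_ucm`: equals the source ladder's partition at
    that level.  ``img`` (optional) supplies intensities for region means;
    without it the means are zero.
    """
    if not (0 <= level <= ucm.n_levels):
        raise ValueError(f"level must lie in [0, {ucm.n_levels}], got {level}")
    h, w = ucm.shape
    flat = np.arange(h * w).reshape(h, w)
    rows, cols, = [], []
    hm = ucm.horiz <= level
    vm = ucm.vert <= level
    rows.append(flat[:, :-1][hm])
    cols.append(flat[:, 1:][hm])
    rows.append(flat[:-1, :][vm])
    cols.append(flat[1:, :][vm])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    adj = sparse.coo_matrix((np.ones(r.size, dtype=np.int8), (r, c)),
                            shape=(h * w, h * w))
    _, comp = connected_components(adj, directed=False)
    base = img if img is not None else np.zeros((h, w))
    return _canonical_partition(comp.reshape(h, w), np.asarray(base, dtype=float))
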