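"""Anatomy packing: tree-constrained CRF labelling of segment pools.

The segment pool is the node set of a :class:`~aphseg.hierarchy.SegmentationTree`.
A labelling assigns each node a label in ``0..K`` (0 = not selected) subject to

* completeness — every pixel is covered by exactly one selected node, and
* non-overlap — no two nodes on the same root-to-leaf path are both selected,

i.e. the selected nodes form an antichain that partitions the image.  The
energy is a sum of unary histogram costs ``U(q, k) = sum_p -log h(I_p; k)``
over the pixels of each selected segment, plus a contrast-sensitive Potts
boundary term ``gamma * exp(-beta * (I_i - I_j)^2)`` over 4-adjacent pixel
couples with different labels.

For K = 2 the constrained minimization is solved *exactly* by a single
min-cut on a "pylon" graph: per tree node two chain vertices (one per
label), the label-1 chains directed root-to-leaf and the label-2 chains
leaf-to-root, joined by an infinite bridge at each leaf, with infinite
reverse edges enforcing monotone (antichain-consistent) cuts and pairwise
terms as inter-chain capacities.  Every valid labelling corresponds to a
finite cut of equal cost and every finite cut decodes to a valid labelling,
so the min cut attains the global minimum.  K > 2 is handled by
alpha-expansion: sweeps of binary keep-vs-alpha moves, each solved by the
same construction, accepted only on strict energy decrease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._graphcut import INF, min_cut
from .hierarchy import SegmentationTree
from .seeding import HistogramModel

__all__ = [
    "EnergyParams",
    "Labeling",
    "ConstraintError",
    "auto_beta",
    "unary_cost",
    "pairwise_cost",
    "total_energy",
    "validate_labeling",
    "leaf_unaries",
    "leaf_pair_weights",
    "solve_binary_pylon",
    "solve_multilabel",
    "labeling_to_pixelmap",
]


class ConstraintError(ValueError):
    """A labelling violates completeness or non-overlap."""


@dataclass(frozen=True)
class EnergyParams:
    """CRF energy weights.

    ``gamma`` scales the boundary (pairwise) term; ``beta`` is the contrast
    sensitivity — ``"auto"`` selects ``1 / (2 * mean((I_i - I_j)^2))`` over
    all 4-adjacent couples, the standard contrast-normalized choice.
    ``n_labels`` is the number K of semantic classes.
    """

    n_labels: int
    gamma: float = 50.0
    beta: float | str = "auto"

    def __post_init__(self) -> None:
        if self.n_labels < 2:
            raise ValueError("n_labels must be >= 2")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if isinstance(self.beta, str) and self.beta != "auto":
            raise ValueError("beta must be a number or 'auto'")
        if not isinstance(self.beta, str) and self.beta < 0:
            raise ValueError("beta must be >= 0")

    def resolve_beta(self, img: np.ndarray) -> float:
        if not isinstance(self.beta, str):
            return float(self.beta)
        return auto_beta(img)


def auto_beta(img: np.ndarray) -> float:
    """Contrast-normalized ``beta = 1 / (2 <(I_i - I_j)^2>)`` over 4-adjacencies."""
    arr = np.asarray(img, dtype=np.float64)
    d2 = np.concatenate([
        ((arr[:, :-1] - arr[:, 1:]) ** 2).ravel(),
        ((arr[:-1, :] - arr[1:, :]) ** 2).ravel(),
    ])
    m = d2.mean() if d2.size else 0.0
    return 0.0 if m == 0.0 else 1.0 / (2.0 * m)


@dataclass
class Labeling:
    """Per-node label vector ``y`` in ``0..K`` (0 = not selected)."""

    y: np.ndarray

    @property
    def selected(self) -> np.ndarray:
        return np.nonzero(self.y > 0)[0]


def validate_labeling(tree: SegmentationTree, y: np.ndarray, n_labels: int) -> None:
    """Raise :class:`ConstraintError` unless exactly one selected ancestor
    covers every leaf (completeness + non-overlap in one condition)."""
    y = np.asarray(y)
    if y.shape != (tree.n_nodes,):
        raise ConstraintError("label vector length does not match the tree")
    if y.min() < 0 or y.max() > n_labels:
        raise ConstraintError(f"labels must lie in 0..{n_labels}")
    for leaf in tree.leaves:
        n_sel = sum(1 for a in tree.ancestors(leaf) if y[a] > 0)
        if n_sel == 0:
            raise ConstraintError(f"leaf {leaf} is uncovered (completeness)")
        if n_sel > 1:
            raise ConstraintError(f"leaf {leaf} has {n_sel} selected ancestors "
                                  "(non-overlap)")


# ---------------------------------------------------------------------------
# energy terms
# ---------------------------------------------------------------------------

def leaf_unaries(tree: SegmentationTree, img: np.ndarray,
                 model: HistogramModel) -> np.ndarray:
    """``(n_leaves, K)`` table of per-leaf unary costs.

    Entry ``[l, k-1]`` is ``sum_{p in leaf l} -log h(bin(I_p); k)``; node
    unaries are sums of these over the node's leaf set.
    """
    if tree.leaf_labels is None:
        raise ValueError("tree carries no pixel-level leaf labels")
    bins = model.bin_of(np.asarray(img).ravel())
    lab = tree.leaf_labels.ravel()
    n_leaves = tree.n_leaves
    out = np.empty((n_leaves, model.n_labels), dtype=np.float64)
    for k in range(model.n_labels):
        cost = -np.log(model.h[k])[bins]
        out[:, k] = np.bincount(lab, weights=cost, minlength=n_leaves)
    return out


def _node_costs(tree: SegmentationTree, leaf_cost: np.ndarray) -> np.ndarray:
    """Aggregate a per-leaf cost vector to every tree node."""
    return np.array([leaf_cost[ls].sum() for ls in tree.leaf_sets])


def unary_cost(tree: SegmentationTree, node: int, label: int, img: np.ndarray,
               model: HistogramModel, mode: str = "per_pixel") -> float:
    """Cost of assigning ``label`` (1..K) to segment ``node``.

    ``mode="per_pixel"`` (default) is the additive product-likelihood
    reading, ``sum_p -log h(bin(I_p); k)``.  ``mode="per_segment"`` scores
    the segment's own histogram against the class model,
    ``-|q| * log(sum_b hhat_q(b) h(b; k))``; it is not additive over the
    tree and is provided for comparison only.  Label 0 costs nothing: the
    segment defers to its descendants.
    """
    if label == 0:
        return 0.0
    if not (1 <= label <= model.n_labels):
        raise ValueError(f"label must lie in 1..{model.n_labels}")
    if mode == "per_pixel":
        table = leaf_unaries(tree, img, model)
        return float(table[tree.leaf_sets[node], label - 1].sum())
    if mode == "per_segment":
        counts = tree.node_histogram(img, node, bins=model.bins, g=model.g)
        hhat = counts / counts.sum()
        return float(-counts.sum() * np.log(float(hhat @ model.h[label - 1])))
    raise ValueError(f"unknown unary mode: {mode!r}")


def pairwise_cost(img: np.ndarray, labelmap: np.ndarray,
                  params: EnergyParams) -> float:
    """Contrast-sensitive Potts boundary cost of a complete pixel label map."""
    arr = np.asarray(img, dtype=np.float64)
    lab = np.asarray(labelmap)
    if lab.min() < 1:
        raise ConstraintError("label map must be complete (labels 1..K)")
    beta = params.resolve_beta(img)
    total = 0.0
    for da, db, la, lb in (
        (arr[:, :-1], arr[:, 1:], lab[:, :-1], lab[:, 1:]),
        (arr[:-1, :], arr[1:, :], lab[:-1, :], lab[1:, :]),
    ):
        m = la != lb
        total += float(np.exp(-beta * (da[m] - db[m]) ** 2).sum())
    return params.gamma * total


def total_energy(tree: SegmentationTree, labeling: Labeling, img: np.ndarray,
                 model: HistogramModel, params: EnergyParams) -> float:
    """Energy ``E = U + V`` of a valid labelling."""
    validate_labeling(tree, labeling.y, params.n_labels)
    u = sum(unary_cost(tree, int(i), int(labeling.y[i]), img, model)
            for i in labeling.selected)
    v = pairwise_cost(img, labeling_to_pixelmap(tree, labeling), params)
    return float(u) + v


def leaf_pair_weights(tree: SegmentationTree, img: np.ndarray,
                      params: EnergyParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate pixel-level boundary costs to adjacent leaf-segment couples.

    Returns ``(a, b, w)`` with ``a < b`` leaf ids and ``w`` the summed
    ``gamma * exp(-beta dI^2)`` over the 4-adjacent pixel couples that span
    the two leaves.  Labels are constant within a leaf, so the pixel Potts
    term aggregates exactly to this leaf-level Potts term.
    """
    lab = tree.leaf_labels
    if lab is None:
        raise ValueError("tree carries no pixel-level leaf labels")
    arr = np.asarray(img, dtype=np.float64)
    beta = params.resolve_beta(img)
    keys, ws = [], []
    for da, db, la, lb in (
        (arr[:, :-1], arr[:, 1:], lab[:, :-1], lab[:, 1:]),
        (arr[:-1, :], arr[1:, :], lab[:-1, :], lab[1:, :]),
    ):
        m = la != lb
        lo = np.minimum(la[m], lb[m]).astype(np.int64)
        hi = np.maximum(la[m], lb[m]).astype(np.int64)
        keys.append(lo * tree.n_leaves + hi)
        ws.append(params.gamma * np.exp(-beta * (da[m] - db[m]) ** 2))
    key = np.concatenate(keys) if keys else np.empty(0, np.int64)
    w = np.concatenate(ws) if ws else np.empty(0)
    uniq, inv = np.unique(key, return_inverse=True)
    wsum = np.bincount(inv, weights=w, minlength=uniq.size)
    return uniq // tree.n_leaves, uniq % tree.n_leaves, wsum


# ---------------------------------------------------------------------------
# binary pylon min-cut
# ---------------------------------------------------------------------------

def _binary_pylon_cut(
    tree: SegmentationTree,
    cost1: np.ndarray,
    cost2: np.ndarray,
    pair_a: np.ndarray,
    pair_b: np.ndarray,
    theta: np.ndarray,
) -> np.ndarray:
    """Solve one binary tree-constrained labelling by min-cut.

    ``cost1``/``cost2`` are per-node costs of selecting the node with side-1
    or side-2; ``theta[e]`` is the 2x2 cost table of leaf couple ``e``
    indexed ``[side_a - 1, side_b - 1]`` and must be submodular in the cut
    variables.  Costs may be arbitrary non-negative values (no additivity
    over the tree is assumed).  Returns the per-leaf side array (values
    1/2, indexed by finest-region id) and the selected-node side vector
    (0 = not selected) decoded from the chain switch positions.
    """
    n = tree.n_nodes
    s, t = 0, 1
    c1 = lambda i: 2 + i
    c2 = lambda i: 2 + n + i
    eu, ev, caps = [], [], []

    def add(u: int, v: int, cap: float) -> None:
        if cap != 0.0:
            eu.append(u)
            ev.append(v)
            caps.append(cap)

    for i in range(n):
        p = int(tree.parent[i])
        if p < 0:
            add(s, c1(i), float(cost1[i]))
            add(c2(i), t, float(cost2[i]))
        else:
            add(c1(p), c1(i), float(cost1[i]))
            add(c1(i), c1(p), INF)
            add(c2(i), c2(p), float(cost2[i]))
            add(c2(p), c2(i), INF)
        # a node may not sit on the selected side of both chains at once;
        # with the monotonicity edges this rules out a label-2 selection
        # above a label-1 switch (and vice versa) on any path
        add(c2(i), c1(i), INF)
        if not tree.children[i]:
            add(c1(i), c2(i), INF)

    leaf_node_of = {}
    for leaf in tree.leaves:
        leaf_node_of[int(tree.leaf_sets[leaf][0])] = leaf

    # pairwise: x_i := [c1_i on sink side] encodes side-1 for leaf i
    for e in range(pair_a.size):
        a = leaf_node_of[int(pair_a[e])]
        b = leaf_node_of[int(pair_b[e])]
        th = theta[e]
        e11, e12, e21, e22 = float(th[0, 0]), float(th[0, 1]), float(th[1, 0]), float(th[1, 1])
        # in x-notation: E(1,1)=e11, E(1,0)=e12, E(0,1)=e21, E(0,0)=e22
        c_ab = e21 + e12 - e22 - e11
        if c_ab < -1e-9 * max(1.0, abs(e11) + abs(e22)):
            raise ValueError("non-submodular pairwise term")
        u_a = e12 - e22
        u_b = e11 - e12
        for node, u in ((a, u_a), (b, u_b)):
            if u >= 0:
                add(s, c1(node), u)
            else:
                add(c1(node), t, -u)
        add(c1(a), c1(b), max(c_ab, 0.0))

    src_side = min_cut(2 + 2 * n, np.array(eu), np.array(ev),
                       np.array(caps), s, t)
    x = ~src_side[2: 2 + n]          # side-1 indicator per node
    z = src_side[2 + n: 2 + 2 * n]   # side-2 indicator per node

    # selected nodes are the chain switch positions
    y_side = np.zeros(n, dtype=np.int64)
    for i in range(n):
        p = int(tree.parent[i])
        if x[i] and (p < 0 or not x[p]):
            y_side[i] = 1
        elif z[i] and (p < 0 or not z[p]):
            y_side[i] = 2

    n_leaf_regions = max(leaf_node_of) + 1
    side = np.zeros(n_leaf_regions, dtype=np.int64)
    for region, leaf in leaf_node_of.items():
        if x[leaf]:
            side[region] = 1
        elif z[leaf]:
            side[region] = 2
        else:
            raise RuntimeError("leaf escaped both chains; cut inconsistent")
    return side, y_side


def solve_binary_pylon(tree: SegmentationTree, img: np.ndarray,
                       model: HistogramModel, params: EnergyParams) -> Labeling:
    """Globally minimize the K = 2 energy subject to the packing constraints."""
    if params.n_labels != 2:
        raise ValueError("solve_binary_pylon requires exactly two labels")
    if tree.n_nodes == 0:
        raise ValueError("empty tree")
    table = leaf_unaries(tree, img, model)
    cost1 = _node_costs(tree, table[:, 0])
    cost2 = _node_costs(tree, table[:, 1])
    a, b, w = leaf_pair_weights(tree, img, params)
    theta = np.zeros((a.size, 2, 2))
    theta[:, 0, 1] = w
    theta[:, 1, 0] = w
    _, y_side = _binary_pylon_cut(tree, cost1, cost2, a, b, theta)
    return Labeling(y=y_side)


# ---------------------------------------------------------------------------
# alpha-expansion for K > 2
# ---------------------------------------------------------------------------

def solve_multilabel(
    tree: SegmentationTree,
    img: np.ndarray,
    model: HistogramModel,
    params: EnergyParams,
    max_sweeps: int = 10,
    pins: np.ndarray | None = None,
    return_trace: bool = False,
):
    """Alpha-expansion over the segment pool.

    Starts from the globally cheapest single label and sweeps
    ``alpha = 1..K``, each move a binary keep-vs-alpha problem solved by the
    pylon min-cut; a move is accepted only if the energy strictly
    decreases, which guarantees termination.  ``pins`` (optional, per finest
    region: 0 = free, k = forced class) realizes hard seeds by adding a
    dominating finite penalty to the other labels of pinned leaves.

    Returns the final :class:`Labeling`, plus the accepted-energy trace when
    ``return_trace`` is set.
    """
    k_labels = params.n_labels
    table = leaf_unaries(tree, img, model)
    a, b, w = leaf_pair_weights(tree, img, params)
    if pins is not None:
        pins = np.asarray(pins)
        big = 2.0 * (np.abs(table).sum() + w.sum()) + 1.0
        for label in range(1, k_labels + 1):
            rows = np.nonzero(pins == label)[0]
            for kk in range(k_labels):
                if kk != label - 1:
                    table[rows, kk] += big

    def energy(leaf_lab: np.ndarray) -> float:
        u = table[np.arange(table.shape[0]), leaf_lab - 1].sum()
        v = w[leaf_lab[a] != leaf_lab[b]].sum() if a.size else 0.0
        return float(u + v)

    cur = np.full(tree.n_leaves, 1 + int(np.argmin(table.sum(axis=0))),
                  dtype=np.int64)
    cur_e = energy(cur)
    trace = [cur_e]

    for _ in range(max_sweeps):
        changed = False
        for alpha in range(1, k_labels + 1):
            keep_leaf = table[np.arange(table.shape[0]), cur - 1]
            cost_keep = _node_costs(tree, keep_leaf)
            cost_alpha = _node_costs(tree, table[:, alpha - 1])
            theta = np.zeros((a.size, 2, 2))
            if a.size:
                theta[:, 0, 0] = w * (cur[a] != cur[b])
                theta[:, 0, 1] = w * (cur[a] != alpha)
                theta[:, 1, 0] = w * (cur[b] != alpha)
            side, _ = _binary_pylon_cut(tree, cost_keep, cost_alpha, a, b, theta)
            new = np.where(side == 2, alpha, cur)
            new_e = energy(new)
            if new_e < cur_e:
                cur, cur_e = new, new_e
                trace.append(cur_e)
                changed = True
        if not changed:
            break

    labeling = _decode_leaf_labels(tree, cur)
    return (labeling, trace) if return_trace else labeling


def _decode_leaf_labels(tree: SegmentationTree, leaf_lab: np.ndarray) -> Labeling:
    """Maximal antichain labelling realizing given per-leaf labels."""
    y = np.zeros(tree.n_nodes, dtype=np.int64)
    stack = [tree.root]
    while stack:
        node = stack.pop()
        labs = leaf_lab[tree.leaf_sets[node]]
        if np.all(labs == labs[0]):
            y[node] = int(labs[0])
        else:
            stack.extend(tree.children[node])
    return Labeling(y=y)


def labeling_to_pixelmap(tree: SegmentationTree, labeling: Labeling) -> np.ndarray:
    """Realize a valid labelling as a per-pixel label image (1..K)."""
    if tree.leaf_labels is None:
        raise ValueError("tree carries no pixel-level leaf labels")
    n_leaf_regions = tree.leaf_labels.max() + 1
    leaf_lab = np.zeros(n_leaf_regions, dtype=np.int64)
    filled = np.zeros(n_leaf_regions, dtype=bool)
    for node in np.nonzero(labeling.y > 0)[0]:
        ls = tree.leaf_sets[int(node)]
        if filled[ls].any():
            raise ConstraintError("overlapping selected segments")
        leaf_lab[ls] = labeling.y[node]
        filled[ls] = True
    if not filled.all():
        raise ConstraintError("labelling does not cover every pixel")
    return leaf_lab[tree.leaf_labels]
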