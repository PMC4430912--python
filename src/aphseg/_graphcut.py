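"""Minimum s-t cut on top of scipy's max-flow.

scipy.sparse.csgraph.maximum_flow operates on integer capacities and
misbehaves silently once any capacity reaches 2**31, so real-valued
capacities are converted by adaptive fixed-point scaling: the scale is
chosen so that the total finite capacity stays below 2**30, which also
bounds the max-flow value.  Structural (infinite) capacities are encoded
as 2**30 — no finite cut ever includes them because a finite cut always
exists in the constructions used here.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

INF = np.inf
_INT_INF = 2**30


def min_cut(n_nodes: int, edges_u: np.ndarray, edges_v: np.ndarray,
            caps: np.ndarray, source: int, sink: int) -> np.ndarray:
    """Return the boolean source-side mask of a minimum s-t cut.

    ``caps`` may contain ``np.inf`` for structural edges.  Parallel edges
    are summed.  Deterministic for a fixed edge list.
    """
    u = np.asarray(edges_u, dtype=np.int64)
    v = np.asarray(edges_v, dtype=np.int64)
    c = np.asarray(caps, dtype=np.float64)
    if np.any(c < 0):
        raise ValueError("capacities must be non-negative")
    finite = np.isfinite(c)
    total = float(c[finite].sum())
    scale = min(2.0**20, (2.0**30 - 1.0) / max(total, 1e-9))
    ic = np.where(finite, np.rint(c * scale), float(_INT_INF)).astype(np.int64)

    keep = ic > 0
    mat = sparse.coo_matrix((ic[keep], (u[keep], v[keep])),
                            shape=(n_nodes, n_nodes)).tocsr()
    res = maximum_flow(mat, source, sink)
    residual = mat - res.flow
    residual.data = (residual.data > 0).astype(np.int8)
    residual.eliminate_zeros()
    reach = breadth_first_order(residual, source, directed=True,
                                return_predecessors=False)
    mask = np.zeros(n_nodes, dtype=bool)
    mask[reach] = True
    if mask[sink]:
        raise RuntimeError("sink reachable after max-flow; inconsistent cut")
    return mask
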