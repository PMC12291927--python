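"""Neighbor joining (Saitou-Nei, Studier-Keppler criterion).

Deterministic given the matrix: ties in the Q criterion resolve to the
smallest (i, j) index pair in the current node ordering.  Negative branch
lengths are kept as computed (a display-time clamp lives in the Newick
writer), so path-length identities on additive matrices hold exactly.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .distance import DistanceMatrix
from .tree import Node, PhyloTree

__all__ = ["nj_tree"]

logger = logging.getLogger(__name__)


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Build the unrooted NJ tree for a valid distance matrix (n >= 3)."""
    n = dist.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    bad = dist.inapplicable_pairs()
    if bad:
        raise ValueError(
            "inapplicable distance for pair(s): "
            + ", ".join(f"{a}--{b}" for a, b in bad)
        )

    d = dist.matrix.astype(float).copy()
    nodes: list[Node] = [Node(name=name) for name in dist.names]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best: tuple[int, int] | None = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                if q < best_q - 1e-15:
                    best_q = q
                    best = (ai, aj)
        assert best is not None
        ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        vj = dij - vi
        if vi < 0 or vj < 0:
            logger.info(
                "negative NJ branch length at join (%s, %s): %.6g / %.6g",
                nodes[i].name or "internal",
                nodes[j].name or "internal",
                vi,
                vj,
            )
        new = Node()
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = vi, vj
        new.children = [child_i, child_j]

        # distances from the new node to every other active node
        new_index = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d[i, k] + d[j, k] - dij)
            d[new_index, k] = d[k, new_index] = duk
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [new_index]

    # resolve the final three nodes around one internal vertex
    x, y, z = active
    lx = 0.5 * (d[x, y] + d[x, z] - d[y, z])
    ly = 0.5 * (d[x, y] + d[y, z] - d[x, z])
    lz = 0.5 * (d[x, z] + d[y, z] - d[x, y])
    center = Node()
    for k, lk in zip((x, y, z), (lx, ly, lz)):
        nodes[k].length = lk
        center.children.append(nodes[k])
    return PhyloTree(center, rooted=False)
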