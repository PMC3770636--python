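"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: minimum steps by
exhaustive enumeration of internal-node state assignments, and Spearman's
rho as a from-scratch Pearson correlation of mid-ranks.
"""

from __future__ import annotations

import math

import numpy as np

from keyrate.matrix import MISSING
from keyrate.tree import PhyloTree


def min_steps_exhaustive(tree: PhyloTree, cells: dict, k: int) -> int:
    """Minimum changes over all assignments of single states to internal nodes.

    Leaves may hold state sets (polymorphism) or MISSING (any state); a
    leaf edge costs nothing iff the parent's assigned state is compatible.
    """
    nodes = tree.preorder()
    internals = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    if not internals:  # single-leaf tree
        return 0
    pos = {id(n): i for i, n in enumerate(internals)}
    n_int = len(internals)
    # grid of all k**n_int assignments, one row per internal node
    grids = np.indices((k,) * n_int).reshape(n_int, -1)
    cost = np.zeros(grids.shape[1], dtype=int)
    for node in internals:
        if node.parent is not None:
            cost += grids[pos[id(node)]] != grids[pos[id(node.parent)]]
    for leaf in leaves:
        cell = cells[leaf.label]
        allowed = (
            np.ones(k, dtype=bool)
            if cell is MISSING
            else np.array([s in cell for s in range(k)])
        )
        cost += ~allowed[grids[pos[id(leaf.parent)]]]
    return int(cost.min())


def midrank(values) -> list[float]:
    """Average ranks for ties, computed directly from sorted positions."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Pearson correlation of mid-ranks, written out longhand."""
    rx, ry = midrank(list(x)), midrank(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)
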