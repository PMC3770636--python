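from __future__ import annotations

import numpy as np
import pytest

from keyrate.matrix import MISSING, CharacterDef, CharacterMatrix
from keyrate.tree import PhyloTree, TreeNode, parse_newick


@pytest.fixture
def balanced_quartet() -> PhyloTree:
    return parse_newick("((A:1,B:1)N1:1,(C:1,D:1)N2:1)R;")


@pytest.fixture
def star_quartet() -> PhyloTree:
    return parse_newick("(A:1,B:1,C:1,D:1);")


def make_matrix(rows: dict[str, list], k_per_char: list[int]) -> CharacterMatrix:
    """Build a matrix from {taxon: [cell, ...]} rows.

    Cells may be an int state, a set of ints, or None for MISSING.
    """
    chars = [
        CharacterDef(
            id=i,
            name=f"c{i}",
            state_labels=tuple(str(s) for s in range(k)),
        )
        for i, k in enumerate(k_per_char)
    ]
    cells = {}
    for taxon, row in rows.items():
        converted = []
        for value in row:
            if value is None:
                converted.append(MISSING)
            elif isinstance(value, (set, frozenset)):
                converted.append(frozenset(value))
            else:
                converted.append(frozenset({value}))
        cells[taxon] = converted
    return CharacterMatrix(list(rows), chars, cells)


def random_tree(
    rng: np.random.Generator,
    n_leaves: int,
    polytomy_prob: float = 0.35,
    label_internals: bool = True,
) -> PhyloTree:
    """Random rooted topology built by repeated merges; polytomies allowed."""
    nodes = [
        TreeNode(f"L{i}", float(rng.uniform(0.1, 2.0))) for i in range(n_leaves)
    ]
    counter = 0
    while len(nodes) > 1:
        m = 2
        while m < len(nodes) and rng.random() < polytomy_prob:
            m += 1
        idx = sorted(rng.choice(len(nodes), size=m, replace=False), reverse=True)
        parent = TreeNode(
            f"N{counter}" if label_internals else None,
            float(rng.uniform(0.1, 2.0)),
        )
        counter += 1
        for i in idx:
            parent.add_child(nodes.pop(i))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    if root.is_leaf:  # n_leaves == 1: hang it under a root
        wrap = TreeNode("N_root")
        root.length = 1.0
        wrap.add_child(root)
        root = wrap
    return PhyloTree(root)


def random_cells(
    rng: np.random.Generator,
    labels: list[str],
    k: int,
    missing_prob: float = 0.15,
    poly_prob: float = 0.15,
) -> dict:
    """Random leaf cells with MISSING and polymorphism mixed in."""
    cells = {}
    for label in labels:
        u = rng.random()
        if u < missing_prob:
            cells[label] = MISSING
        elif u < missing_prob + poly_prob and k >= 2:
            size = int(rng.integers(2, k + 1))
            cells[label] = frozenset(
                int(s) for s in rng.choice(k, size=size, replace=False)
            )
        else:
            cells[label] = frozenset({int(rng.integers(k))})
    return cells
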