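"""Minimum-change (parsimony) step counts and homoplasy statistics.

Characters are unordered (Fitch-type): any state may change into any other
at unit cost. Step counting uses Hartigan's generalization of the Fitch
down-pass, which is exact on trees with polytomies: at each internal node,
count how many child state sets contain each state; if ``K`` is the largest
such count over states and ``c`` the number of children, the node
contributes ``c - K`` changes and passes up the set of states attaining
``K``. Unscored (MISSING) leaves enter as the full wildcard state set and
can never force a change; polymorphic leaves enter as their observed set,
so the count is minimized over their resolutions.

Homoplasy statistics follow the classic indices: with ``s`` the observed
steps, ``m = k_obs - 1`` the minimum conceivable steps and ``g`` the steps
on a completely unresolved bush, the consistency index is ``CI = m/s`` and
the retention index ``RI = (g - s)/(g - m)``. A character is homoplastic
when ``s > m`` (equivalently ``CI < 1``): some state must re-arise or
revert on the tree.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .alignment import Alignment, Partition
from .matrix import MISSING, Cell, CharacterMatrix
from .tree import PhyloTree

__all__ = [
    "StepCount",
    "count_steps",
    "summarize_character",
    "column_steps",
    "class_average_steps",
    "step_table",
]


@dataclass(frozen=True)
class StepCount:
    """Per-character parsimony steps and homoplasy statistics.

    ``ci`` is undefined (None) for invariant characters (s = 0); ``ri`` is
    undefined when g = m, i.e. when the bush score equals the minimum and
    there is no room for retained synapomorphy. Downstream consumers must
    handle the absence rather than coercing to 0 or 1.
    """

    char_id: int
    steps: int
    min_steps: int
    max_steps: int
    k_obs: int
    n_scored: int
    ci: Optional[float]
    ri: Optional[float]
    homoplastic: bool
    unscored: bool = False  # no scored leaf at all


def _leaf_sets(
    tree: PhyloTree,
    cells: Mapping[str, Cell],
    n_states: int,
) -> dict[str, frozenset]:
    full = frozenset(range(n_states))
    out = {}
    for label in tree.leaf_labels:
        if label not in cells:
            raise ValueError(f"leaf {label!r} has no cell in the matrix")
        cell = cells[label]
        out[label] = full if cell is MISSING else frozenset(cell)
    return out


def count_steps(
    tree: PhyloTree,
    cells: Mapping[str, Cell],
    n_states: int,
) -> int:
    """Minimum number of state changes on ``tree`` for one character.

    ``cells`` maps every leaf label to its state set (or MISSING). The
    count is the minimum over all assignments of single states to internal
    nodes and over all resolutions of polymorphic leaves.
    """
    sets = _leaf_sets(tree, cells, n_states)
    steps = 0
    node_set: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            node_set[id(node)] = sets[node.label]
            continue
        counts: Counter = Counter()
        for child in node.children:
            counts.update(node_set[id(child)])
        top = counts.most_common(1)[0][1]
        node_set[id(node)] = frozenset(s for s, c in counts.items() if c == top)
        steps += len(node.children) - top
    return steps


def summarize_character(
    tree: PhyloTree, matrix: CharacterMatrix, char_id: int
) -> StepCount:
    """Steps plus min/max bounds, CI, RI and the homoplasy flag for one character."""
    char = matrix.character(char_id)
    col = matrix.column(char_id)
    leaf_labels = set(tree.leaf_labels)
    scored = {
        t: cell
        for t, cell in col.items()
        if t in leaf_labels and cell is not MISSING
    }
    s = count_steps(tree, {t: col[t] for t in tree.leaf_labels}, char.k)

    observed: set[int] = set()
    for cell in scored.values():
        observed.update(cell)
    k_obs = len(observed)
    n_scored = len(scored)
    m = max(k_obs - 1, 0)
    if n_scored:
        # a polymorphic leaf counts toward a state whenever its set contains it
        contain = Counter()
        for cell in scored.values():
            for state in cell:
                contain[state] += 1
        g = n_scored - max(contain.values())
    else:
        g = 0
    ci = m / s if s > 0 else None
    ri = (g - s) / (g - m) if g > m else None
    return StepCount(
        char_id=char_id,
        steps=s,
        min_steps=m,
        max_steps=g,
        k_obs=k_obs,
        n_scored=n_scored,
        ci=ci,
        ri=ri,
        homoplastic=s > m,
        unscored=n_scored == 0,
    )


def step_table(tree: PhyloTree, matrix: CharacterMatrix) -> list[StepCount]:
    """summarize_character over every character in the matrix."""
    return [summarize_character(tree, matrix, c.id) for c in matrix.characters]


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def column_steps(
    tree: PhyloTree,
    alignment: Alignment,
    partition: Optional[Partition] = None,
) -> pd.DataFrame:
    """Parsimony steps for every alignment column, tagged with its class.

    Columns are unordered 4-state characters; gaps and N are treated as
    MISSING. Columns outside every partition class get class ``None``; a
    column with no scored base is flagged unscored with 0 steps.
    """
    missing_leaves = set(tree.leaf_labels) - set(alignment.taxa)
    if missing_leaves:
        raise ValueError(
            f"tree leaves absent from alignment: {sorted(missing_leaves)}"
        )
    col_class: dict[int, str] = {}
    if partition:
        for name, cols in partition.items():
            for c in cols:
                col_class[c] = name

    rows = []
    seqs = {t: alignment.sequences[t] for t in tree.leaf_labels}
    for j in range(alignment.length):
        cells: dict[str, Cell] = {}
        scored = 0
        for t, s in seqs.items():
            base = s[j]
            if base in _BASE_INDEX:
                cells[t] = frozenset([_BASE_INDEX[base]])
                scored += 1
            else:
                cells[t] = MISSING
        steps = count_steps(tree, cells, 4) if scored else 0
        rows.append(
            {
                "column": j,
                "class": col_class.get(j),
                "steps": steps,
                "scored": scored > 0,
            }
        )
    return pd.DataFrame(rows)


def class_average_steps(
    steps_by_class: Mapping[str, Sequence[float]],
) -> dict[str, float]:
    """Arithmetic mean of steps within each class; empty classes are omitted
    with a warning."""
    out: dict[str, float] = {}
    for name, steps in steps_by_class.items():
        steps = list(steps)
        if not steps:
            warnings.warn(f"class {name!r} has no scored members; omitted")
            continue
        out[name] = sum(steps) / len(steps)
    return out
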