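"""Synthetic trees, characters, matrices and alignments.

The generator emulates the structure of a species-level identification-key
study: an ultrametric tree over a few hundred taxa, a few dozen discrete
characters with 2-6 states whose evolutionary rates span orders of
magnitude, and a nearly complete matrix (a few percent of cells unscored).

Trees come from a pure-birth (Yule) process rescaled to unit height, so a
character's rate reads directly as expected changes per tree height.
Characters evolve under the Mk model (equal exchange rates among k states),
simulated as an explicit Poisson jump process along each branch: the
realized event count is recorded, because the gap between true changes and
the parsimony minimum — hidden, cancelling changes — is exactly what the
homoplasy analysis studies.

All generators are deterministic given their seed. Matched-seed rate
ladders work because per-character rate quantiles and the missing-cell mask
are drawn from dedicated seed-sequence streams, identical across
configurations that differ only in the rate bounds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .matrix import MISSING, Cell, CharacterDef, CharacterMatrix
from .alignment import Alignment, Partition
from .tree import PhyloTree, TreeNode

__all__ = [
    "SimConfig",
    "SimCharacterRecord",
    "simulate_yule_tree",
    "simulate_mk_character",
    "simulate_matrix",
    "simulate_alignment",
]

#: Study-shaped default state-count composition: 19 binary, 17 three-state,
#: 8 four-state and 3 six-state characters (47 total).
DEFAULT_STATE_COUNTS: tuple[int, ...] = (2,) * 19 + (3,) * 17 + (4,) * 8 + (6,) * 3

_SIM_CLASSES = ("color", "morphometric", "sculpture")


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one simulated study.

    Defaults follow the empirical study's shape: ~350 taxa scored for 47
    characters of 2-6 states, matrix > 95% complete (2% of cells unscored),
    and per-character rates log-uniform over two orders of magnitude
    (0.05-5 expected changes per unit tree height).
    """

    seed: int
    n_taxa: int = 350
    birth_rate: float = 1.0
    state_counts: tuple[int, ...] = DEFAULT_STATE_COUNTS
    rate_low: float = 0.05
    rate_high: float = 5.0
    missing_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if not (0 < self.rate_low <= self.rate_high):
            raise ValueError("need 0 < rate_low <= rate_high")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must be in [0, 1)")
        if any(not (2 <= k <= 6) for k in self.state_counts):
            raise ValueError("state counts must lie in [2, 6]")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")

    @property
    def n_chars(self) -> int:
        return len(self.state_counts)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SimConfig":
        """Load from JSON or flat ``key=value`` lines; ``seed`` is mandatory."""
        text = Path(path).read_text()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        if "seed" not in raw:
            raise ValueError(f"{path}: config must set a seed")
        kwargs: dict = {}
        for key in (
            "seed",
            "n_taxa",
            "birth_rate",
            "state_counts",
            "rate_low",
            "rate_high",
            "missing_fraction",
        ):
            if key not in raw:
                continue
            value = raw[key]
            if key in ("seed", "n_taxa"):
                kwargs[key] = int(value)
            elif key == "state_counts":
                if isinstance(value, str):
                    value = [int(v) for v in value.split(",") if v.strip()]
                kwargs[key] = tuple(int(v) for v in value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass(frozen=True)
class SimCharacterRecord:
    """One simulated character with its ground truth.

    ``true_change_count`` is the number of realized jump events on the
    whole tree; parsimony steps never exceed it, but hidden changes can
    cancel, so it may exceed (observed states - 1) or even be positive for
    a character that looks invariant at the leaves.
    """

    character: CharacterDef
    true_rate: float
    true_change_count: int
    leaf_states: dict[str, int]


def simulate_yule_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int = 0
) -> PhyloTree:
    """A pure-birth tree with ``n_taxa`` leaves, rescaled to root height 1.

    Leaves are labelled ``t001 ...`` in preorder. The process starts from
    the root's two daughter lineages; each split picks a uniform extant
    lineage after an exponential wait, and a final exponential wait sets
    the present. Rescaling makes the tree exactly ultrametric with height
    1, so branch lengths are fractions of the total depth (and the choice
    of ``birth_rate`` only shapes relative node depths).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    # active tips with the time their subtending branch began
    tips: list[tuple[TreeNode, float]] = []
    for _ in range(2):
        child = TreeNode()
        root.add_child(child)
        tips.append((child, 0.0))
    t = 0.0
    while len(tips) < n_taxa:
        k = len(tips)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node, start = tips.pop(i)
        node.length = t - start
        for _ in range(2):
            child = TreeNode()
            node.add_child(child)
            tips.append((child, t))
    t += rng.exponential(1.0 / (len(tips) * birth_rate))
    for node, start in tips:
        node.length = t - start

    # rescale and label before validating construction
    scale = 1.0 / t
    order: list[TreeNode] = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(node.children))
    width = max(3, len(str(n_taxa)))
    i = 0
    for node in order:
        if node.length is not None:
            node.length *= scale
        if node.is_leaf:
            i += 1
            node.label = f"t{i:0{width}d}"
    return PhyloTree(root)


def _branch_arrays(tree: PhyloTree) -> tuple[list[TreeNode], np.ndarray]:
    """Preorder nodes (root first) and non-root branch lengths, cached."""
    cached = getattr(tree, "_sim_cache", None)
    if cached is not None:
        return cached
    nodes = tree.preorder()
    lengths = np.array([n.length or 0.0 for n in nodes[1:]], dtype=float)
    tree._sim_cache = (nodes, lengths)  # type: ignore[attr-defined]
    return nodes, lengths


def simulate_mk_character(
    tree: PhyloTree,
    k: int,
    rate: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    character: Optional[CharacterDef] = None,
) -> SimCharacterRecord:
    """Evolve one unordered k-state character along the tree.

    The root state is uniform on the k states; on a branch of length ``t``
    the number of change events is Poisson(rate * t) and each event jumps
    to one of the other k - 1 states uniformly. Every realized event is
    counted, including those later overwritten.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    nodes, lengths = _branch_arrays(tree)
    counts = rng.poisson(rate * lengths) if len(lengths) else np.array([], dtype=int)
    states: dict[int, int] = {id(nodes[0]): int(rng.integers(k))}
    leaf_states: dict[str, int] = {}
    for node, c in zip(nodes[1:], counts):
        s = states[id(node.parent)]
        if c:
            for d in rng.integers(k - 1, size=int(c)):
                s = int(d) if d < s else int(d) + 1
        states[id(node)] = s
        if node.is_leaf:
            leaf_states[node.label] = s
    if nodes[0].is_leaf:  # degenerate single-node tree
        leaf_states[nodes[0].label] = states[id(nodes[0])]
    if character is None:
        character = CharacterDef(
            id=0, name="sim", state_labels=tuple(str(i) for i in range(k))
        )
    return SimCharacterRecord(
        character=character,
        true_rate=rate,
        true_change_count=int(counts.sum()),
        leaf_states=leaf_states,
    )


def simulate_matrix(
    tree: PhyloTree, config: SimConfig
) -> tuple[CharacterMatrix, list[SimCharacterRecord]]:
    """Simulate a full character matrix under ``config``.

    Per-character rates are log-uniform on [rate_low, rate_high]; MISSING
    cells are placed Bernoulli(missing_fraction) per cell; class tags are
    assigned round-robin over color/morphometric/sculpture. The rate
    quantiles, the missing mask and each character's jump process draw
    from separate child streams of the config seed, so runs that differ
    only in the rate bounds share everything else.
    """
    n_chars = config.n_chars
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_chars + 2)
    rate_rng = np.random.default_rng(children[0])
    missing_rng = np.random.default_rng(children[1])

    u = rate_rng.uniform(size=n_chars)
    log_lo, log_hi = math.log(config.rate_low), math.log(config.rate_high)
    rates = np.exp(log_lo + u * (log_hi - log_lo))

    records: list[SimCharacterRecord] = []
    chars: list[CharacterDef] = []
    for i, k in enumerate(config.state_counts):
        char = CharacterDef(
            id=i,
            name=f"char{i + 1:02d}",
            state_labels=tuple(str(j) for j in range(k)),
            class_tag=_SIM_CLASSES[i % len(_SIM_CLASSES)],
        )
        chars.append(char)
        rec = simulate_mk_character(
            tree,
            k,
            float(rates[i]),
            rng=np.random.default_rng(children[i + 2]),
            character=char,
        )
        records.append(rec)

    taxa = tree.leaf_labels
    missing_mask = missing_rng.uniform(size=(len(taxa), n_chars)) < config.missing_fraction
    cells: dict[str, list[Cell]] = {}
    for ti, taxon in enumerate(taxa):
        row: list[Cell] = []
        for ci, rec in enumerate(records):
            if missing_mask[ti, ci]:
                row.append(MISSING)
            else:
                row.append(frozenset([rec.leaf_states[taxon]]))
        cells[taxon] = row
    return CharacterMatrix(taxa, chars, cells), records


_BASES = "ACGT"


def simulate_alignment(
    tree: PhyloTree,
    n_sites_per_class: dict[str, int],
    class_rates: dict[str, float],
    seed: int = 0,
) -> tuple[Alignment, Partition]:
    """Simulate DNA columns as 4-state Mk (Jukes-Cantor-like) characters.

    Sites are grouped into contiguous named classes, each with its own
    substitution rate; the returned partition maps class names to 0-based
    column indices, ready to write as a RAxML-style partition file.
    """
    unknown = set(n_sites_per_class) - set(class_rates)
    if unknown:
        raise ValueError(f"classes without a rate: {sorted(unknown)}")
    if any(r < 0 for r in class_rates.values()):
        raise ValueError("class rates must be >= 0")
    ss = np.random.SeedSequence(seed)
    taxa = tree.leaf_labels
    columns: dict[str, list[str]] = {t: [] for t in taxa}
    partition: Partition = {}
    col = 0
    total_sites = sum(n_sites_per_class.values())
    streams = iter(ss.spawn(total_sites))
    for name, n_sites in n_sites_per_class.items():
        rate = class_rates[name]
        cols = []
        for _ in range(n_sites):
            rec = simulate_mk_character(
                tree, 4, rate, rng=np.random.default_rng(next(streams))
            )
            for t in taxa:
                columns[t].append(_BASES[rec.leaf_states[t]])
            cols.append(col)
            col += 1
        partition[name] = cols
    alignment = Alignment({t: "".join(columns[t]) for t in taxa})
    return alignment, partition
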