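"""Character ranking and interactive elimination for identification keys.

An interactive key proceeds by selecting observed character states; taxa
whose cell for that character neither contains the selected state nor is
MISSING are eliminated. A "Best"-style ranking orders characters by how
evenly their states partition the remaining taxa, because an even split
maximizes the expected number of eliminations per selection.

The score implemented here is the expected retained fraction: with ``N``
active taxa, ``n_s`` of them compatible with state ``s`` (polymorphic taxa
count for each of their states), ``u`` unscored, and selection probability
``p_s = n_s / sum_t n_t``,

    b = sum_s p_s * (n_s + u) / N .

Lower is better; ``b = 1`` exactly when no selection can eliminate anything.
With complete binary data this reduces to the Simpson concentration of the
state frequencies, so it is a pure evenness measure. The exact score used
by commercial key software is unpublished; any monotone evenness measure
yields the same ranking behavior in practice, and this one is
parameter-free and reproducible.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .matrix import MISSING, CharacterMatrix

__all__ = [
    "RankEntry",
    "KeySession",
    "KeyPathResult",
    "KeyDepthSummary",
    "best_score",
    "rank_best",
    "select_state",
    "greedy_key_path",
    "mean_key_depth",
]


@dataclass(frozen=True)
class RankEntry:
    """One character's position in a Best-style ranking.

    ``best_score`` is the expected retained fraction in (0, 1]; rank 1 is
    the most useful character. ``usable`` is False when fewer than two
    states are observed among the active taxa (such a character can never
    eliminate anything and is appended after the usable ones).
    """

    char_id: int
    best_score: float
    rank: int
    usable: bool


@dataclass(frozen=True)
class KeySession:
    """Immutable state of one interactive identification session."""

    matrix: CharacterMatrix
    active: tuple[str, ...]
    history: tuple[tuple[int, int], ...] = ()  # (char_id, state) selections

    @classmethod
    def start(cls, matrix: CharacterMatrix) -> "KeySession":
        return cls(matrix=matrix, active=tuple(matrix.taxa))


def _score(
    matrix: CharacterMatrix, char_id: int, active: Sequence[str]
) -> tuple[float, bool]:
    char = matrix.character(char_id)
    n = [0] * char.k
    u = 0
    for taxon in active:
        cell = matrix.cell(taxon, char_id)
        if cell is MISSING:
            u += 1
        else:
            for s in cell:
                n[s] += 1
    total = sum(n)
    N = len(active)
    observed = sum(1 for x in n if x > 0)
    if total == 0:
        return 1.0, False
    b = sum((x / total) * (x + u) / N for x in n if x > 0)
    return b, observed >= 2


def best_score(
    matrix: CharacterMatrix, char_id: int, active_taxa: Optional[Sequence[str]] = None
) -> float:
    """Expected fraction of active taxa retained after one state selection.

    ``active_taxa`` defaults to all taxa. Returns 1.0 when the character
    cannot eliminate any active taxon.
    """
    active = list(active_taxa) if active_taxa is not None else list(matrix.taxa)
    if not active:
        raise ValueError("active taxon set is empty")
    b, _ = _score(matrix, char_id, active)
    return b


def rank_best(
    matrix: CharacterMatrix, active_taxa: Optional[Sequence[str]] = None
) -> list[RankEntry]:
    """Rank all characters, most useful (lowest score) first.

    Ties break by ascending character id; unusable characters (fewer than
    two observed states among active taxa) are appended after the usable
    ones, also score- then id-ordered, and flagged.
    """
    active = list(active_taxa) if active_taxa is not None else list(matrix.taxa)
    if not active:
        raise ValueError("active taxon set is empty")
    scored = []
    for char in matrix.characters:
        b, usable = _score(matrix, char.id, active)
        scored.append((not usable, b, char.id, usable))
    scored.sort()
    return [
        RankEntry(char_id=cid, best_score=b, rank=i + 1, usable=usable)
        for i, (_, b, cid, usable) in enumerate(scored)
    ]


def select_state(session: KeySession, char_id: int, state: int) -> KeySession:
    """Apply one state selection, eliminating incompatible taxa.

    A taxon survives iff its cell contains the state or is MISSING. A
    selection that would empty the active set raises without mutating the
    session.
    """
    char = session.matrix.character(char_id)
    if not (0 <= state < char.k):
        raise ValueError(
            f"state {state} out of range for character {char.name!r} (k={char.k})"
        )
    kept = tuple(
        t
        for t in session.active
        if (cell := session.matrix.cell(t, char_id)) is MISSING or state in cell
    )
    if not kept:
        raise ValueError(
            f"no matching taxa for state {state} of character {char.name!r}"
        )
    return replace(
        session, active=kept, history=session.history + ((char_id, state),)
    )


@dataclass(frozen=True)
class KeyPathResult:
    """Outcome of driving the key toward one target taxon."""

    target: str
    path: tuple[tuple[int, int], ...]
    final_active: tuple[str, ...]

    @property
    def unique(self) -> bool:
        return len(self.final_active) == 1

    @property
    def depth(self) -> int:
        return len(self.path)


def greedy_key_path(matrix: CharacterMatrix, target_taxon: str) -> KeyPathResult:
    """Identify ``target_taxon`` by always following the Best suggestion.

    At each step the best-ranked unused character scored in the target is
    selected with the target's own state (for polymorphic cells, the
    contained state held by fewest active taxa, ties by state index). Stops
    when the active set is the target alone or no usable scored character
    remains; a non-unique endpoint is reported, not raised.
    """
    if target_taxon not in matrix.taxa:
        raise KeyError(f"unknown taxon {target_taxon!r}")
    session = KeySession.start(matrix)
    used: set[int] = set()
    while len(session.active) > 1:
        ranking = rank_best(matrix, session.active)
        choice = next(
            (
                e
                for e in ranking
                if e.usable
                and e.char_id not in used
                and matrix.cell(target_taxon, e.char_id) is not MISSING
            ),
            None,
        )
        if choice is None:
            break
        used.add(choice.char_id)
        cell = matrix.cell(target_taxon, choice.char_id)
        if len(cell) == 1:
            state = next(iter(cell))
        else:
            # rarest compatible state eliminates the most taxa
            counts = {}
            for s in sorted(cell):
                counts[s] = sum(
                    1
                    for t in session.active
                    if (c := matrix.cell(t, choice.char_id)) is not MISSING
                    and s in c
                )
            state = min(sorted(cell), key=lambda s: (counts[s], s))
        session = select_state(session, choice.char_id, state)
    return KeyPathResult(
        target=target_taxon,
        path=session.history,
        final_active=session.active,
    )


@dataclass(frozen=True)
class KeyDepthSummary:
    """Aggregate key-path statistics over a sample of target taxa."""

    n: int
    mean_depth: float
    median_depth: float
    max_depth: int
    fraction_unique: float


def mean_key_depth(
    matrix: CharacterMatrix,
    taxa: Optional[Sequence[str]] = None,
    n_sample: Optional[int] = None,
    seed: int = 0,
) -> KeyDepthSummary:
    """Greedy key-path depth statistics over a (sub)sample of taxa.

    Either pass explicit ``taxa`` or an ``n_sample`` drawn without
    replacement using ``seed``; by default all taxa are used. Sampling is
    over the sorted taxon list so the result is invariant to matrix row
    order.
    """
    if taxa is None:
        pool = sorted(matrix.taxa)
        if n_sample is not None and n_sample < len(pool):
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(pool), size=n_sample, replace=False)
            taxa = [pool[i] for i in sorted(idx)]
        else:
            taxa = pool
    if not taxa:
        raise ValueError("no taxa to sample")
    results = [greedy_key_path(matrix, t) for t in taxa]
    depths = [r.depth for r in results]
    return KeyDepthSummary(
        n=len(results),
        mean_depth=sum(depths) / len(depths),
        median_depth=float(statistics.median(depths)),
        max_depth=max(depths),
        fraction_unique=sum(r.unique for r in results) / len(results),
    )
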