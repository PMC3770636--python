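"""Aligned DNA with RAxML-style partition assignments.

An :class:`Alignment` is a dict of equal-length sequences over the alphabet
``{A, C, G, T, -, N}``; a partition maps a class name (e.g. ``mt3`` for COI
third codon positions) to the 0-based column indices belonging to it.
Partition files follow the RAxML convention: 1-based inclusive ranges with
an optional ``\\3`` stride for codon positions, e.g. ``DNA, mt3 = 3-1536\\3``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from Bio import SeqIO

__all__ = [
    "Alignment",
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "read_partition",
    "write_partition",
    "read_alignment",
]

DNA_ALPHABET = set("ACGTN-")


class AlignmentError(ValueError):
    """Raised for length mismatches, bad symbols, or overlapping partitions."""


@dataclass
class Alignment:
    """Equal-length sequences keyed by taxon label."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise AlignmentError(
                f"sequences differ in length: {sorted(lengths)}"
            )
        for taxon, seq in self.sequences.items():
            bad = set(seq.upper()) - DNA_ALPHABET
            if bad:
                raise AlignmentError(
                    f"sequence {taxon!r} contains symbols outside "
                    f"ACGTN-: {sorted(bad)}"
                )
        # normalize to upper case once
        self.sequences = {t: s.upper() for t, s in self.sequences.items()}

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    def column(self, j: int) -> dict[str, str]:
        return {t: s[j] for t, s in self.sequences.items()}


Partition = dict[str, list[int]]  # class name -> sorted 0-based column indices


def read_fasta(path: Union[str, Path]) -> Alignment:
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise AlignmentError(f"{path}: no sequences")
    return Alignment(records)


def write_fasta(alignment: Alignment, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for taxon, seq in alignment.sequences.items():
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


_PART_LINE = re.compile(
    r"^\s*\w+\s*,\s*(?P<name>[\w.+-]+)\s*=\s*(?P<ranges>.+?)\s*$"
)


def read_partition(path: Union[str, Path], n_columns: int) -> Partition:
    """Parse RAxML-style partition lines into 0-based column classes.

    Ranges are 1-based inclusive; ``start-end\\3`` takes every third column
    starting at ``start``. A column may belong to at most one class.
    """
    partition: Partition = {}
    claimed: dict[int, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _PART_LINE.match(line)
        if m is None:
            raise AlignmentError(f"cannot parse partition line {raw!r}")
        name = m.group("name")
        if name in partition:
            raise AlignmentError(f"duplicate partition class {name!r}")
        cols: list[int] = []
        for rng in m.group("ranges").split(","):
            rng = rng.strip()
            rm = re.fullmatch(
                r"(?P<start>\d+)(?:-(?P<end>\d+))?(?:\\(?P<stride>\d+))?", rng
            )
            if rm is None:
                raise AlignmentError(
                    f"cannot parse range {rng!r} in partition {name!r}"
                )
            start = int(rm.group("start"))
            end = int(rm.group("end") or start)
            stride = int(rm.group("stride") or 1)
            if start < 1 or end > n_columns or start > end:
                raise AlignmentError(
                    f"range {rng!r} in partition {name!r} outside "
                    f"1..{n_columns}"
                )
            cols.extend(range(start - 1, end, stride))
        for c in cols:
            if c in claimed:
                raise AlignmentError(
                    f"column {c + 1} claimed by both {claimed[c]!r} and {name!r}"
                )
            claimed[c] = name
        partition[name] = sorted(cols)
    return partition


def write_partition(partition: Partition, path: Union[str, Path]) -> None:
    """Write a partition as RAxML-style lines (contiguous runs, 1-based)."""
    lines = []
    for name, cols in partition.items():
        runs: list[str] = []
        cols = sorted(cols)
        i = 0
        while i < len(cols):
            j = i
            while j + 1 < len(cols) and cols[j + 1] == cols[j] + 1:
                j += 1
            if i == j:
                runs.append(f"{cols[i] + 1}")
            else:
                runs.append(f"{cols[i] + 1}-{cols[j] + 1}")
            i = j + 1
        lines.append(f"DNA, {name} = {', '.join(runs)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_alignment(
    fasta_path: Union[str, Path], partition_path: Union[str, Path]
) -> tuple[Alignment, Partition]:
    """Read a FASTA alignment together with its partition file."""
    alignment = read_fasta(fasta_path)
    partition = read_partition(partition_path, alignment.length)
    return alignment, partition
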