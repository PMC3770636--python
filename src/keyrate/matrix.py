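"""Discrete taxon-by-character matrices.

A matrix cell is either a non-empty set of state indices (a singleton for an
ordinary observation, larger for a polymorphic taxon) or ``MISSING``
(``None``). The two are kept distinct at the I/O layer because downstream
consumers disagree about their meaning: parsimony treats an unscored leaf as
the full wildcard state set, whereas an interactive key retains an unscored
taxon on every selection.

Supported dialects: CSV/TSV with taxa as rows (``a/b`` polymorphism, ``?``
missing) and a minimal NEXUS CHARACTERS/DATA block (SYMBOLS, ``?``, ``{ab}``).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "MISSING",
    "Cell",
    "CharacterDef",
    "CharacterMatrix",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
]

#: Sentinel for an unscored cell. Kept as ``None`` so that ``cell is MISSING``
#: and truthiness tests both behave.
MISSING = None

Cell = Optional[frozenset]  # frozenset[int] or MISSING

CHARACTER_CLASSES = ("color", "morphometric", "sculpture", "molecular")


class MatrixParseError(ValueError):
    """Raised for malformed matrix files or invariant violations."""


@dataclass(frozen=True)
class CharacterDef:
    """Definition of one discrete character.

    ``state_labels`` is the ordered list of state names; a cell's integer
    state indices index into it. ``class_tag`` groups characters for
    per-class summaries (color / morphometric / sculpture / molecular).
    """

    id: int
    name: str
    state_labels: tuple[str, ...]
    class_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if len(set(self.state_labels)) != len(self.state_labels):
            raise ValueError(
                f"character {self.name!r}: duplicate state labels {self.state_labels}"
            )
        if self.class_tag is not None and self.class_tag not in CHARACTER_CLASSES:
            raise ValueError(
                f"character {self.name!r}: unknown class {self.class_tag!r}"
            )

    @property
    def k(self) -> int:
        return len(self.state_labels)


class CharacterMatrix:
    """A rectangular taxon x character matrix of state-set cells."""

    def __init__(
        self,
        taxa: Sequence[str],
        characters: Sequence[CharacterDef],
        cells: dict[str, list[Cell]],
    ) -> None:
        if len(set(taxa)) != len(taxa):
            dups = sorted({t for t in taxa if list(taxa).count(t) > 1})
            raise MatrixParseError(f"duplicate taxa: {dups}")
        self.taxa = list(taxa)
        self.characters = list(characters)
        self._cells = cells
        self._validate()

    def _validate(self) -> None:
        n_chars = len(self.characters)
        for taxon in self.taxa:
            if taxon not in self._cells:
                raise MatrixParseError(f"taxon {taxon!r} has no row")
            row = self._cells[taxon]
            if len(row) != n_chars:
                raise MatrixParseError(
                    f"ragged row for taxon {taxon!r}: "
                    f"{len(row)} cells, expected {n_chars}"
                )
            for char, cell in zip(self.characters, row):
                if cell is MISSING:
                    continue
                if not cell:
                    raise MatrixParseError(
                        f"empty state set for taxon {taxon!r}, "
                        f"character {char.name!r}"
                    )
                bad = [s for s in cell if not (0 <= s < char.k)]
                if bad:
                    raise MatrixParseError(
                        f"state index {bad[0]} out of range for taxon "
                        f"{taxon!r}, character {char.name!r} (k={char.k})"
                    )

    # -- access -------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def cell(self, taxon: str, char_id: int) -> Cell:
        return self._cells[taxon][char_id]

    def row(self, taxon: str) -> list[Cell]:
        return list(self._cells[taxon])

    def column(self, char_id: int) -> dict[str, Cell]:
        """All cells for one character, keyed by taxon."""
        return {t: self._cells[t][char_id] for t in self.taxa}

    def character(self, char_id: int) -> CharacterDef:
        for c in self.characters:
            if c.id == char_id:
                return c
        raise KeyError(f"no character with id {char_id}")

    @property
    def completeness(self) -> float:
        """Fraction of cells that are scored (non-MISSING)."""
        total = self.n_taxa * self.n_characters
        if total == 0:
            return 1.0
        scored = sum(
            1
            for t in self.taxa
            for cell in self._cells[t]
            if cell is not MISSING
        )
        return scored / total

    def row_signature(self, taxon: str) -> tuple:
        return tuple(self._cells[taxon])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.characters == other.characters
            and all(self._cells[t] == other._cells[t] for t in self.taxa)
        )


# ---------------------------------------------------------------------------
# CSV / TSV dialect
# ---------------------------------------------------------------------------


def _parse_cell(
    token: str, char: CharacterDef, taxon: str
) -> Cell:
    token = token.strip()
    if token in ("?", ""):
        return MISSING
    labels = token.split("/")
    indices = set()
    label_to_idx = {lab: i for i, lab in enumerate(char.state_labels)}
    for lab in labels:
        lab = lab.strip()
        if lab not in label_to_idx:
            raise MatrixParseError(
                f"unknown state label {lab!r} for taxon {taxon!r}, "
                f"character {char.name!r} (states: {list(char.state_labels)})"
            )
        indices.add(label_to_idx[lab])
    return frozenset(indices)


def _format_cell(cell: Cell, char: CharacterDef) -> str:
    if cell is MISSING:
        return "?"
    return "/".join(char.state_labels[i] for i in sorted(cell))


def _infer_characters(
    header: list[str], rows: list[tuple[str, list[str]]]
) -> list[CharacterDef]:
    """Build CharacterDefs from observed tokens when none were supplied.

    State labels are the distinct observed labels, ordered numerically when
    all are integers and lexicographically otherwise.
    """
    chars = []
    for j, name in enumerate(header):
        observed: set[str] = set()
        for _, tokens in rows:
            token = tokens[j].strip()
            if token in ("?", ""):
                continue
            observed.update(lab.strip() for lab in token.split("/"))
        if all(re.fullmatch(r"-?\d+", lab) for lab in observed):
            labels = tuple(sorted(observed, key=int))
        else:
            labels = tuple(sorted(observed))
        chars.append(CharacterDef(id=j, name=name, state_labels=labels))
    return chars


def read_matrix(
    path: Union[str, Path],
    characters: Optional[Sequence[CharacterDef]] = None,
    dialect: Optional[str] = None,
) -> CharacterMatrix:
    """Read a character matrix from CSV/TSV or a simple NEXUS file.

    ``dialect`` is one of ``csv``, ``tsv``, ``nexus``; when omitted it is
    inferred from the file extension (.nex/.nexus -> nexus, .tsv -> tsv,
    otherwise csv). When ``characters`` is omitted for CSV/TSV input, state
    labels are inferred from the observed tokens.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {".nex": "nexus", ".nexus": "nexus", ".tsv": "tsv"}.get(
            suffix, "csv"
        )
    if dialect == "nexus":
        return _read_nexus(path, characters)
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    delim = "\t" if dialect == "tsv" else ","

    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        all_rows = [r for r in reader if r and any(c.strip() for c in r)]
    if not all_rows:
        raise MatrixParseError(f"{path}: no taxa")
    header = [h.strip() for h in all_rows[0][1:]]
    body: list[tuple[str, list[str]]] = []
    for r in all_rows[1:]:
        taxon = r[0].strip()
        body.append((taxon, [c for c in r[1:]]))
    if not body:
        raise MatrixParseError(f"{path}: no taxa")

    n_chars = len(header)
    for taxon, tokens in body:
        if len(tokens) != n_chars:
            raise MatrixParseError(
                f"{path}: ragged row for taxon {taxon!r}: "
                f"{len(tokens)} cells, expected {n_chars}"
            )
    if characters is None:
        chars = _infer_characters(header, body)
    else:
        chars = list(characters)
        if len(chars) != n_chars:
            raise MatrixParseError(
                f"{path}: {n_chars} columns but {len(chars)} character "
                "definitions supplied"
            )
    cells = {
        taxon: [_parse_cell(tok, char, taxon) for tok, char in zip(tokens, chars)]
        for taxon, tokens in body
    }
    return CharacterMatrix([t for t, _ in body], chars, cells)


def write_matrix(
    matrix: CharacterMatrix, path: Union[str, Path], dialect: str = "csv"
) -> None:
    """Write a matrix in the CSV/TSV or simple NEXUS dialect (round-trip safe)."""
    path = Path(path)
    if dialect == "nexus":
        _write_nexus(matrix, path)
        return
    delim = {"csv": ",", "tsv": "\t"}[dialect]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["taxon"] + [c.name for c in matrix.characters])
        for taxon in matrix.taxa:
            writer.writerow(
                [taxon]
                + [
                    _format_cell(cell, char)
                    for cell, char in zip(matrix.row(taxon), matrix.characters)
                ]
            )


# ---------------------------------------------------------------------------
# Minimal NEXUS CHARACTERS dialect
# ---------------------------------------------------------------------------
#
# Handled: BEGIN CHARACTERS (or DATA); DIMENSIONS NTAX/NCHAR; FORMAT with
# SYMBOLS="..." MISSING=? GAP=-; a non-interleaved MATRIX with {ab} or (ab)
# polymorphism. State symbols are single characters shared across columns,
# as NEXUS defines them; per-character state labels become the symbols
# observed in that column unless CharacterDefs are supplied.


def _read_nexus(
    path: Path, characters: Optional[Sequence[CharacterDef]]
) -> CharacterMatrix:
    text = path.read_text()
    text = re.sub(r"\[[^\]]*\]", "", text)  # strip NEXUS comments
    m = re.search(
        r"begin\s+(?:characters|data)\s*;(.*?)end\s*;",
        text,
        re.IGNORECASE | re.DOTALL,
    )
    if m is None:
        raise MatrixParseError(f"{path}: no CHARACTERS or DATA block")
    block = m.group(1)

    symbols = "0123456789"
    missing_sym, gap_sym = "?", "-"
    fmt = re.search(r"format\s+([^;]*);", block, re.IGNORECASE | re.DOTALL)
    if fmt:
        fm = re.search(r'symbols\s*=\s*"([^"]*)"', fmt.group(1), re.IGNORECASE)
        if fm:
            symbols = fm.group(1).replace(" ", "")
        mm = re.search(r"missing\s*=\s*(\S)", fmt.group(1), re.IGNORECASE)
        if mm:
            missing_sym = mm.group(1)
        gm = re.search(r"gap\s*=\s*(\S)", fmt.group(1), re.IGNORECASE)
        if gm:
            gap_sym = gm.group(1)

    mat = re.search(r"matrix(.*?);", block, re.IGNORECASE | re.DOTALL)
    if mat is None:
        raise MatrixParseError(f"{path}: no MATRIX statement")
    rows: list[tuple[str, list[str]]] = []
    for line in mat.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        tm = re.match(r"(?:'([^']+)'|(\S+))\s+(.*)", line)
        if tm is None:
            raise MatrixParseError(f"{path}: cannot parse matrix row {line!r}")
        taxon = tm.group(1) or tm.group(2)
        seq = tm.group(3).replace(" ", "")
        tokens: list[str] = []
        i = 0
        while i < len(seq):
            ch = seq[i]
            if ch in "{(":
                close = "}" if ch == "{" else ")"
                j = seq.index(close, i)
                tokens.append(seq[i + 1 : j])
                i = j + 1
            else:
                tokens.append(ch)
                i += 1
        rows.append((taxon, tokens))
    if not rows:
        raise MatrixParseError(f"{path}: no taxa")

    n_chars = len(rows[0][1])
    for taxon, tokens in rows:
        if len(tokens) != n_chars:
            raise MatrixParseError(
                f"{path}: ragged row for taxon {taxon!r}: "
                f"{len(tokens)} cells, expected {n_chars}"
            )

    if characters is None:
        chars = []
        for j in range(n_chars):
            observed: set[str] = set()
            for _, tokens in rows:
                for sym in tokens[j]:
                    if sym not in (missing_sym, gap_sym):
                        observed.add(sym)
            order = {s: i for i, s in enumerate(symbols)}
            labels = tuple(sorted(observed, key=lambda s: (order.get(s, len(order)), s)))
            chars.append(CharacterDef(id=j, name=f"char{j + 1}", state_labels=labels))
    else:
        chars = list(characters)
        if len(chars) != n_chars:
            raise MatrixParseError(
                f"{path}: {n_chars} columns but {len(chars)} character "
                "definitions supplied"
            )

    cells: dict[str, list[Cell]] = {}
    for taxon, tokens in rows:
        row: list[Cell] = []
        for tok, char in zip(tokens, chars):
            if all(sym in (missing_sym, gap_sym) for sym in tok):
                row.append(MISSING)
                continue
            label_to_idx = {lab: i for i, lab in enumerate(char.state_labels)}
            idxs = set()
            for sym in tok:
                if sym in (missing_sym, gap_sym):
                    continue
                if sym not in label_to_idx:
                    raise MatrixParseError(
                        f"{path}: unknown state symbol {sym!r} for taxon "
                        f"{taxon!r}, character {char.name!r}"
                    )
                idxs.add(label_to_idx[sym])
            row.append(frozenset(idxs))
        cells[taxon] = row
    return CharacterMatrix([t for t, _ in rows], chars, cells)


def _write_nexus(matrix: CharacterMatrix, path: Path) -> None:
    # single-character symbols are required by the format; refuse otherwise
    all_labels = {lab for c in matrix.characters for lab in c.state_labels}
    if any(len(lab) != 1 for lab in all_labels):
        raise ValueError("NEXUS output requires single-character state labels")
    symbols = "".join(sorted(all_labels))
    lines = [
        "#NEXUS",
        "BEGIN CHARACTERS;",
        f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f'  FORMAT SYMBOLS="{symbols}" MISSING=?;',
        "  MATRIX",
    ]
    width = max(len(t) for t in matrix.taxa) + 2
    for taxon in matrix.taxa:
        toks = []
        for cell, char in zip(matrix.row(taxon), matrix.characters):
            if cell is MISSING:
                toks.append("?")
            elif len(cell) == 1:
                toks.append(char.state_labels[next(iter(cell))])
            else:
                toks.append("{" + "".join(char.state_labels[i] for i in sorted(cell)) + "}")
        name = f"'{taxon}'" if any(c.isspace() for c in taxon) else taxon
        lines.append(f"  {name:<{width}}{''.join(toks)}")
    lines += ["  ;", "END;", ""]
    Path(path).write_text("\n".join(lines))
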