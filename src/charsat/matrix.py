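"""Discrete morphological character matrices.

A character matrix holds taxa in rows and discrete characters (states coded
as small non-negative integers) in columns.  A cell is either a state set —
a singleton for a fixed score, larger for a polymorphism — or one of two
sentinel tokens: ``MISSING`` ("?") and ``INAPPLICABLE`` ("-", the NEXUS gap).
Both sentinels are excluded from all computations; the distinction is kept
in the data model and on round-trip only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import dendropy

__all__ = [
    "MISSING",
    "INAPPLICABLE",
    "Cell",
    "CharacterMatrix",
    "PARTITION_VOCABULARY",
    "MatrixParseError",
    "MatrixValidationError",
    "read_nexus_matrix",
    "write_nexus_matrix",
]

#: Anatomical partition labels accepted by default.
PARTITION_VOCABULARY = frozenset(
    {"skull", "postcranium", "snout", "temporal", "dentition"}
)


class _Token:
    __slots__ = ("_name",)

    def __init__(self, name: str):
        self._name = name

    def __repr__(self) -> str:
        return self._name


MISSING = _Token("MISSING")
INAPPLICABLE = _Token("INAPPLICABLE")

Cell = Union[frozenset, _Token]


class MatrixParseError(ValueError):
    """Raised when a NEXUS character block cannot be parsed."""


class MatrixValidationError(ValueError):
    """Raised when matrix content violates an invariant."""


@dataclass
class CharacterMatrix:
    """Taxa x characters matrix of discrete states.

    Parameters
    ----------
    taxa : ordered taxon names, unique.
    cells : one row per taxon; each row a list of `Cell`.
    ordered : per-character flag; ordered characters use min state-set
        distance rescaled by the observed state range, unordered use
        set-intersection match/mismatch.
    partitions : per-character set of anatomical partition labels.
    """

    taxa: list
    cells: list
    ordered: list = field(default=None)
    partitions: list = field(default=None)

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixValidationError(f"duplicate taxon names: {dupes}")
        if len(self.cells) != len(self.taxa):
            raise MatrixValidationError("one cell row required per taxon")
        widths = {len(row) for row in self.cells}
        if len(widths) > 1:
            raise MatrixValidationError(f"ragged rows: lengths {sorted(widths)}")
        if self.ordered is None:
            self.ordered = [False] * self.n_chars
        if self.partitions is None:
            self.partitions = [set() for _ in range(self.n_chars)]
        if len(self.ordered) != self.n_chars or len(self.partitions) != self.n_chars:
            raise MatrixValidationError("per-character metadata length mismatch")

    # -- dimensions ----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def row(self, taxon: str) -> list:
        return self.cells[self.taxa.index(taxon)]

    # -- per-character summaries --------------------------------------
    def observed_states(self, j: int) -> frozenset:
        states = set()
        for row in self.cells:
            cell = row[j]
            if isinstance(cell, frozenset):
                states |= cell
        return frozenset(states)

    def n_observed_states(self, j: int) -> int:
        return len(self.observed_states(j))

    def state_range(self, j: int) -> int:
        states = self.observed_states(j)
        if not states:
            return 0
        return max(states) - min(states)

    # -- subsetting ----------------------------------------------------
    def char_indices_for_partition(self, label: str) -> list:
        return [j for j in range(self.n_chars) if label in self.partitions[j]]

    def subset_chars(self, indices: Sequence[int]) -> "CharacterMatrix":
        indices = list(indices)
        return CharacterMatrix(
            taxa=list(self.taxa),
            cells=[[row[j] for j in indices] for row in self.cells],
            ordered=[self.ordered[j] for j in indices],
            partitions=[set(self.partitions[j]) for j in indices],
        )

    def subset_taxa(self, names: Iterable[str]) -> "CharacterMatrix":
        names = list(names)
        missing = [n for n in names if n not in self.taxa]
        if missing:
            raise MatrixValidationError(f"taxa not in matrix: {missing}")
        idx = [self.taxa.index(n) for n in names]
        return CharacterMatrix(
            taxa=names,
            cells=[[c for c in self.cells[i]] for i in idx],
            ordered=list(self.ordered),
            partitions=[set(p) for p in self.partitions],
        )

    def missing_mask(self):
        """Boolean (n_taxa, n_chars) array: True where the cell is scored."""
        import numpy as np

        out = np.zeros((self.n_taxa, self.n_chars), dtype=bool)
        for i, row in enumerate(self.cells):
            for j, cell in enumerate(row):
                out[i, j] = isinstance(cell, frozenset)
        return out

    def set_partitions_from_table(self, assignments, vocabulary=PARTITION_VOCABULARY):
        """Apply `{char_index: iterable of labels}` partition assignments."""
        for j, labels in assignments.items():
            labels = set(labels)
            bad = labels - set(vocabulary)
            if bad:
                raise MatrixValidationError(
                    f"partition labels {sorted(bad)} outside vocabulary"
                )
            if not 0 <= j < self.n_chars:
                raise MatrixValidationError(f"character index {j} out of range")
            self.partitions[j] = labels

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        if self.taxa != other.taxa or self.ordered != other.ordered:
            return False
        for ra, rb in zip(self.cells, other.cells):
            for a, b in zip(ra, rb):
                if isinstance(a, frozenset) != isinstance(b, frozenset):
                    return False
                if isinstance(a, frozenset) and a != b:
                    return False
                if isinstance(a, _Token) and a is not b:
                    return False
        return True


# ---------------------------------------------------------------------------
# NEXUS I/O (dendropy-backed reader, deterministic writer)
# ---------------------------------------------------------------------------

def _cell_from_state(state) -> Cell:
    if state.symbol == "?":
        return MISSING
    if state.symbol == "-":
        return INAPPLICABLE
    members = state.fundamental_states or (state,)
    vals = frozenset(int(ms.symbol) for ms in members if ms.symbol not in ("-",))
    if not vals:
        return INAPPLICABLE
    return vals


def read_nexus_matrix(path) -> CharacterMatrix:
    """Read a NEXUS CHARACTERS/DATA block of digit-coded standard characters.

    "?" parses to ``MISSING``, the gap "-" to ``INAPPLICABLE``, and
    polymorphisms "{01}"/"(01)" to multi-member state sets.
    """
    try:
        dm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises several error classes
        raise MatrixParseError(f"cannot parse NEXUS matrix {path}: {exc}") from exc
    taxa = [t.label for t in dm.taxon_namespace]
    if len(set(taxa)) != len(taxa):
        raise MatrixValidationError(f"duplicate taxon names in {path}")
    cells = []
    for t in dm.taxon_namespace:
        seq = dm[t]
        cells.append([_cell_from_state(s) for s in seq])
    return CharacterMatrix(taxa=taxa, cells=cells)


def _cell_symbol(cell: Cell) -> str:
    if cell is MISSING:
        return "?"
    if cell is INAPPLICABLE:
        return "-"
    vals = sorted(cell)
    if len(vals) == 1:
        return str(vals[0])
    return "{" + "".join(str(v) for v in vals) + "}"


def write_nexus_matrix(matrix: CharacterMatrix, path) -> None:
    """Write a matrix as a NEXUS DATA block; output is byte-stable."""
    buf = io.StringIO()
    buf.write("#NEXUS\n")
    buf.write("BEGIN DATA;\n")
    buf.write(f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};\n")
    buf.write('FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=? GAP=-;\n')
    buf.write("MATRIX\n")
    width = max((len(t) for t in matrix.taxa), default=0) + 2
    for t, row in zip(matrix.taxa, matrix.cells):
        name = t.replace(" ", "_")
        buf.write(name.ljust(width))
        buf.write("".join(_cell_symbol(c) for c in row))
        buf.write("\n")
    buf.write(";\nEND;\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
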