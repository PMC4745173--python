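"""Unit-vector indicator encodings of nucleotide sequences.

A sequence over {A, C, G, T} is turned into a sparse binary matrix by
mapping each letter to one of the canonical unit vectors e1..e4 of R^4
under an *assignment code* (a letter ordering such as ``"ACGT"``, meaning
A -> e1, C -> e2, G -> e3, T -> e4).  Column j of the resulting 4 x N
matrix Y is the unit vector of residue j.

The 24 possible assignment codes partition into exactly three equivalence
classes that produce identical wavelet spectral slopes.  Each class is
characterised by how it pairs the letters:

=====  ============  =========================
class  letter pairs  nucleotide characteristic
=====  ============  =========================
1      AC | GT       amino / keto
2      AG | CT       purine / pyrimidine
3      AT | CG       weak / strong H-bonds
=====  ============  =========================

Stacking one single-code encoding from each class yields a 12-row matrix,
zero-padded to 16 rows so the row dimension is a power of two; the slope
computed from this stacked encoding is invariant to the choice of
representatives (the "translation-invariant" encoding).

Cumulative matrices Y* (running sums along each row of Y) are the actual
input to the wavelet transform: they convert the spike-train indicator
rows into monotone counting paths whose regularity the spectral slope
measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

LETTERS = "ACGT"

#: One representative assignment per equivalence class, in class order.
DEFAULT_REPRESENTATIVES: tuple[str, str, str] = ("ACGT", "AGCT", "ATCG")

_CLASS_OF_PARTITION = {
    frozenset({frozenset("AC"), frozenset("GT")}): 1,
    frozenset({frozenset("AG"), frozenset("CT")}): 2,
    frozenset({frozenset("AT"), frozenset("CG")}): 3,
}


class InvalidAssignmentError(ValueError):
    """A letter order that is not a permutation of ACGT."""


class InvalidRepresentativesError(ValueError):
    """A representative triple that does not cover all three classes."""


class EncodingError(ValueError):
    """A residue that cannot be mapped to a unit vector (strict mode)."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A labelled DNA string, uppercased on construction."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


def as_sequence(seq: "NucleotideSequence | str", id: str = "seq") -> NucleotideSequence:
    """Coerce a plain string into a :class:`NucleotideSequence`."""
    if isinstance(seq, NucleotideSequence):
        return seq
    return NucleotideSequence(id, seq)


def classify_assignment(order: str) -> int:
    """Equivalence class (1, 2 or 3) of an assignment code.

    Two codes share a class iff one arises from the other by swapping the
    letters within its two pairs and/or swapping the pairs themselves.
    """
    order = order.upper()
    if sorted(order) != sorted(LETTERS):
        raise InvalidAssignmentError(f"not a permutation of ACGT: {order!r}")
    partition = frozenset({frozenset(order[:2]), frozenset(order[2:])})
    return _CLASS_OF_PARTITION[partition]


@lru_cache(maxsize=64)
def _row_lookup(order: str) -> np.ndarray:
    # byte value -> row index under `order`, -1 for anything unmappable
    table = np.full(256, -1, dtype=np.int8)
    for row, letter in enumerate(order):
        table[ord(letter)] = row
        table[ord(letter.lower())] = row
    table.setflags(write=False)
    return table


def sequence_rows(residues: str, order: str = LETTERS) -> np.ndarray:
    """Row index (0..3) of every residue under ``order``; -1 if unmappable."""
    raw = np.frombuffer(residues.encode("ascii", errors="replace"), dtype=np.uint8)
    return _row_lookup(order)[raw]


def invalid_mask(residues: str) -> np.ndarray:
    """Boolean mask of positions holding letters outside {A, C, G, T}."""
    return sequence_rows(residues) < 0


def encode_single(
    seq: NucleotideSequence | str, order: str = "ACGT", strict: bool = False
) -> np.ndarray:
    """4 x N indicator matrix of ``seq`` under the assignment ``order``.

    Unmappable residues (N, IUPAC ambiguity codes, ...) produce an all-zero
    column unless ``strict``, in which case :class:`EncodingError` is raised
    naming the 1-based offending position.  Downstream slope computations
    turn windows containing such columns into missing slopes.
    """
    s = as_sequence(seq)
    classify_assignment(order)  # validates the permutation
    rows = sequence_rows(s.residues, order)
    if strict and (rows < 0).any():
        pos = int(np.argmax(rows < 0))
        raise EncodingError(
            f"unmappable residue {s.residues[pos]!r} at position {pos + 1} "
            f"of sequence {s.id!r}"
        )
    Y = np.zeros((4, rows.size))
    valid = np.nonzero(rows >= 0)[0]
    Y[rows[valid], valid] = 1.0
    return Y


def encode_invariant(
    seq: NucleotideSequence | str,
    representatives: tuple[str, str, str] = DEFAULT_REPRESENTATIVES,
    strict: bool = False,
) -> np.ndarray:
    """16 x N translation-invariant indicator matrix.

    Rows 1-4, 5-8 and 9-12 (1-based) hold the single-code encodings under
    one representative from each equivalence class; rows 13-16 are zero
    padding so the row count is a power of two.  The padding is fixed at
    zero: with the Haar basis it never leaks into the detail rows used by
    the slope.
    """
    if len(representatives) != 3:
        raise InvalidRepresentativesError(
            f"need exactly 3 representatives, got {len(representatives)}"
        )
    classes = [classify_assignment(rep) for rep in representatives]
    if sorted(classes) != [1, 2, 3]:
        raise InvalidRepresentativesError(
            f"representatives {representatives!r} cover classes {classes}, "
            "expected one from each of classes 1, 2, 3"
        )
    s = as_sequence(seq)
    blocks = [encode_single(s, rep, strict=strict) for rep in representatives]
    blocks.append(np.zeros((4, len(s))))
    return np.vstack(blocks)


def cumulate(Y: np.ndarray) -> np.ndarray:
    """Cumulative matrix Y*: running sums along each row of Y.

    Entry (i, j) counts occurrences of the letter coded by row i among the
    first j residues; each row is nondecreasing.
    """
    return np.cumsum(np.asarray(Y), axis=1)
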