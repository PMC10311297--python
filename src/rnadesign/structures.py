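"""Sequence and secondary-structure data model.

An RNA secondary structure is a set of nested (pseudoknot-free) base pairs
over positions 1..n, written in dot-bracket notation: ``(`` and ``)`` mark
the two sides of a pair, ``.`` marks an unpaired position.  This module
provides parsing/validation, the pair/unpaired index sets, the per-position
structure distance, and the sequence-structure compatibility check used to
keep a design inside the ensemble of its target.

Indexing convention: the public ``pair_set`` / ``unpaired_set`` attributes
and all error messages are 1-based, matching how structures are written in
the literature.  The ``partner`` array is a 0-based internal helper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

#: The four RNA nucleotides, in canonical order.
BASES = ("A", "C", "G", "U")

#: The six admissible pair types: Watson-Crick plus the G-U wobble pair.
PAIR_TYPES = (("C", "G"), ("G", "C"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G"))

ALLOWED_PAIRS = frozenset(PAIR_TYPES)


class StructureParseError(ValueError):
    """Raised when a dot-bracket string is malformed."""


class RnaSequence(str):
    """A validated RNA sequence over the alphabet {A, C, G, U}.

    Subclasses :class:`str`, so instances can be used anywhere a plain
    string is expected.  Lowercase input is upper-cased; any other
    character is rejected.
    """

    def __new__(cls, bases: str) -> "RnaSequence":
        s = str(bases).upper()
        if not s:
            raise ValueError("empty RNA sequence")
        for idx, c in enumerate(s):
            if c not in "ACGU":
                raise ValueError(f"invalid base {c!r} at position {idx + 1}")
        return super().__new__(cls, s)

    @property
    def n(self) -> int:
        return len(self)


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure.

    Parameters
    ----------
    dotbracket:
        The structure in dot-bracket notation, characters ``( ) .`` only.

    Attributes
    ----------
    pair_set:
        Frozen set of 1-based pairs ``(i, j)`` with ``i < j``.
    unpaired_set:
        Frozen set of 1-based unpaired positions.
    partner:
        0-based int array; ``partner[i]`` is the 0-based partner of ``i``,
        or ``-1`` if position ``i`` is unpaired.
    """

    dotbracket: str
    pair_set: frozenset = field(init=False, repr=False)
    unpaired_set: frozenset = field(init=False, repr=False)

    def __post_init__(self) -> None:
        db = self.dotbracket
        if not db:
            raise StructureParseError("empty structure string")
        stack: list[int] = []
        partner = np.full(len(db), -1, dtype=np.int64)
        pairs = []
        for idx, c in enumerate(db):
            if c == "(":
                stack.append(idx)
            elif c == ")":
                if not stack:
                    raise StructureParseError(
                        f"unmatched ')' at position {idx + 1}"
                    )
                i = stack.pop()
                partner[i] = idx
                partner[idx] = i
                pairs.append((i + 1, idx + 1))
            elif c != ".":
                raise StructureParseError(
                    f"illegal character {c!r} at position {idx + 1}"
                )
        if stack:
            raise StructureParseError(
                f"unmatched '(' at position {stack[0] + 1}"
            )
        partner.setflags(write=False)
        object.__setattr__(self, "pair_set", frozenset(pairs))
        object.__setattr__(
            self,
            "unpaired_set",
            frozenset(i + 1 for i in range(len(db)) if partner[i] < 0),
        )
        object.__setattr__(self, "_partner", partner)

    @property
    def n(self) -> int:
        return len(self.dotbracket)

    @property
    def partner(self) -> np.ndarray:
        return self._partner  # type: ignore[attr-defined]

    @classmethod
    def from_pairs(cls, n: int, pairs: Iterable[tuple[int, int]]) -> "SecondaryStructure":
        """Build a structure from 1-based pairs; validates nesting via reparse."""
        chars = ["."] * n
        for i, j in pairs:
            if not (1 <= i < j <= n):
                raise ValueError(f"pair ({i}, {j}) out of range for n={n}")
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return cls("".join(chars))

    def __str__(self) -> str:
        return self.dotbracket


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    Raises :class:`StructureParseError` naming the 1-based offending
    position for unbalanced brackets or illegal characters.
    """
    return SecondaryStructure(text)


def structure_distance(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """Per-position distance between two equal-length structures.

    ``d(a, b) = n - 2 * |shared pairs| - |shared unpaired positions|``,
    i.e. the number of positions whose pairing status (partner index, or
    unpaired) differs between the two structures.  Symmetric, zero iff the
    structures are identical, and at most ``n``.
    """
    if a.n != b.n:
        raise ValueError(f"length mismatch: {a.n} != {b.n}")
    shared_pairs = len(a.pair_set & b.pair_set)
    shared_unpaired = len(a.unpaired_set & b.unpaired_set)
    return a.n - 2 * shared_pairs - shared_unpaired


def is_compatible(x: RnaSequence | str, y: SecondaryStructure) -> bool:
    """True iff every pair of ``y`` is an admissible pair type in ``x``.

    The admissible types are the Watson-Crick pairs CG/GC/AU/UA plus the
    GU/UG wobble pair.  Raises on length mismatch.
    """
    if len(x) != y.n:
        raise ValueError(f"length mismatch: sequence {len(x)} vs structure {y.n}")
    for i, j in y.pair_set:
        if (x[i - 1], x[j - 1]) not in ALLOWED_PAIRS:
            return False
    return True
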