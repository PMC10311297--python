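"""Seeded generation of valid pseudoknot-free target structures.

The generator builds targets recursively from the same vocabulary real
secondary structures are made of — helices, hairpin loops, internal
loops/bulges, and multiloop branches — with controllable length, helix
lengths, and loop sizes, and always produces a structure of exactly the
requested length.  It emulates the *shape* statistics of design targets
(nested helices at realistic lengths), not the base-composition or motif
statistics of any natural RNA family.

Also packaged here: the 20-nt two-hairpin worked example (with its
companion targeted initialization sequence) and the small hand-built
oracle fixtures used throughout the tests, so the whole suite runs
without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PuzzleSet
from .structures import SecondaryStructure, parse_dotbracket

__all__ = [
    "StructureGenSpec",
    "random_structure",
    "worked_examples",
    "WORKED_EXAMPLE_STRUCTURE",
    "WORKED_EXAMPLE_SEQUENCE",
    "TIE_SEQUENCE",
]

#: 20-nt two-hairpin target used as the running example.
WORKED_EXAMPLE_STRUCTURE = "(((...)))..(((...)))"

#: One of the 64 equiprobable targeted initializations of the target above.
WORKED_EXAMPLE_SEQUENCE = "CGGAAACCGAAGCGAAACGC"

#: A sequence with two tied minimum-energy structures under the toy model
#: (either CG hairpin, but not both); exercises the MFE-vs-uMFE distinction.
TIE_SEQUENCE = "CAAAGAAAC"


@dataclass(frozen=True)
class StructureGenSpec:
    """Controls for the random-structure generator.

    ``helix_len_range`` bounds the stacked pairs per helix,
    ``loop_len_range`` the unpaired runs (hairpin loops and loop sides);
    hairpin loops never go below 3 unpaired bases so thermodynamic
    engines accept every fixture.  ``branching_prob`` is the chance an
    open region splits into two helix units (multiloop-style branching).
    """

    n: int
    helix_len_range: tuple[int, int] = (2, 8)
    loop_len_range: tuple[int, int] = (3, 8)
    branching_prob: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        hmin, hmax = self.helix_len_range
        lmin, lmax = self.loop_len_range
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (1 <= hmin <= hmax):
            raise ValueError("invalid helix_len_range")
        if not (3 <= lmin <= lmax):
            raise ValueError("loop_len_range minimum must be >= 3 (hairpin minimum)")
        if not (0.0 <= self.branching_prob <= 1.0):
            raise ValueError("branching_prob must be in [0, 1]")

    @property
    def min_unit(self) -> int:
        """Smallest length a helix-enclosed unit can occupy."""
        return 2 * self.helix_len_range[0] + 3


def random_structure(
    spec: StructureGenSpec, rng: np.random.Generator | None = None
) -> SecondaryStructure:
    """Draw one valid pseudoknot-free structure of length exactly ``spec.n``.

    Regions too short to host a helix become unpaired runs; otherwise a
    helix is always placed, so fully-forced specs (e.g. helix range (3, 3),
    loop range (3, 3), n = 9) yield their unique shape deterministically.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    hmin, hmax = spec.helix_len_range
    lmin, lmax = spec.loop_len_range
    need = spec.min_unit

    def open_region(m: int) -> str:
        # exterior or multiloop interior: gaps and helix units
        if m < need:
            return "." * m
        if m >= 2 * need + 1 and rng.random() < spec.branching_prob:
            g = int(rng.integers(1, min(lmax, m - 2 * need) + 1))
            a = int(rng.integers(need, m - g - need + 1))
            return helix_unit(a) + "." * g + open_region(m - g - a)
        gl = int(rng.integers(0, min(lmax, m - need) + 1))
        gr = int(rng.integers(0, min(lmax, m - need - gl) + 1))
        return "." * gl + helix_unit(m - gl - gr) + "." * gr

    def helix_unit(m: int) -> str:
        # a helix enclosing an interior; m >= need
        h = int(rng.integers(hmin, min(hmax, (m - 3) // 2) + 1))
        return "(" * h + interior(m - 2 * h) + ")" * h

    def interior(m: int) -> str:
        # the loop closed by a helix; m >= 3
        if m < need:
            return "." * m
        can_hairpin = lmin <= m <= lmax
        can_multi = m >= 2 * need + 1
        can_internal = m - need >= 1
        r = rng.random()
        if can_hairpin and (r < 0.25 or not (can_multi or can_internal)):
            return "." * m  # hairpin loop
        if can_multi and r < 0.45:
            return open_region(m)  # multiloop
        if not can_internal:
            # no room for a loop gap and a further helix: close as a loop
            return "." * m
        # internal loop / bulge: at least one unpaired side breaks stacking
        total_gap = int(rng.integers(1, min(2 * lmax, m - need) + 1))
        gl = int(rng.integers(0, total_gap + 1))
        gr = total_gap - gl
        return "." * gl + helix_unit(m - total_gap) + "." * gr

    return parse_dotbracket(open_region(spec.n))


def worked_examples() -> PuzzleSet:
    """The packaged example targets: worked example plus oracle fixtures."""
    entries = {
        "two_hairpins_20": WORKED_EXAMPLE_STRUCTURE,
        "open_chain_5": ".....",
        "hairpin_9": "(((...)))",
        "single_pair_5": "(...)",
        "tie_probe_9": "(...)....."[:9],
    }
    return PuzzleSet(
        {name: parse_dotbracket(db) for name, db in entries.items()}
    )
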