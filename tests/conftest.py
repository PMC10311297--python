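"""Shared fixtures and independent brute-force oracles.

The oracles here recompute ensemble quantities from the exhaustively
enumerated ensemble (plain sums over structures) so the dynamic programs
and objective formulas are checked against an independent path.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from rnadesign.folding import TOY_MODEL, enumerate_ensemble
from rnadesign.structures import BASES, SecondaryStructure


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), n))


def ensemble_oracle(x: str, model=TOY_MODEL):
    """Q, bpp matrix, unpaired probs, MFE set, and (structure, prob) list,
    all computed by direct summation over the enumerated ensemble."""
    ens = enumerate_ensemble(x, model)
    n = len(x)
    weights = np.array([math.exp(-e / model.RT) for _, e in ens])
    Q = weights.sum()
    probs = weights / Q
    bpp = np.zeros((n, n))
    q = np.zeros(n)
    for (y, _), p in zip(ens, probs):
        for i, j in y.pair_set:
            bpp[i - 1, j - 1] += p
        for j in y.unpaired_set:
            q[j - 1] += p
    bpp = bpp + bpp.T
    emin = min(e for _, e in ens)
    mfe_set = {y.dotbracket for y, e in ens if abs(e - emin) <= 1e-9}
    return Q, bpp, q, mfe_set, [(y, p) for (y, _), p in zip(ens, probs)]


def pairing_profile(y: SecondaryStructure) -> tuple:
    """Partner index per position (None if unpaired): the per-index view
    of a structure used as the independent distance oracle."""
    return tuple(int(p) if p >= 0 else None for p in y.partner)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
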