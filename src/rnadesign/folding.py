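"""Folding oracle: toy nearest-pair energy model with exhaustive and DP engines.

The search engine only needs a small contract from an energy model: the
partition function and base-pair probabilities of a sequence, the
equilibrium probability of a given structure, the set of minimum free
energy (MFE) structures, and the MFE/uMFE criterion check.  This module
provides that contract twice over for a deliberately simple, self-contained
energy model:

* exhaustive enumeration of the ensemble (feasible up to ~16 nt), and
* O(n^3) dynamic programs (inside-outside for the partition function and
  pair probabilities; min-plus with co-optimal counting for the MFE set),

so every ensemble quantity has an in-repo brute-force oracle.  The toy
model assigns a fixed energy per pair type (CG/GC strongest, then AU/UA,
then the GU/UG wobble), a bonus per stacked pair, and a minimum hairpin
size, which is enough to make GC helices dominate ensembles the way they
do under nearest-neighbor models.  A thermodynamic engine (ViennaRNA) can
be swapped in through the same interface, see :mod:`rnadesign.vienna`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Protocol

import numpy as np

from .structures import ALLOWED_PAIRS, RnaSequence, SecondaryStructure

__all__ = [
    "EnergyModel",
    "TOY_MODEL",
    "EnsembleSummary",
    "CriterionResult",
    "FoldAnalysis",
    "FoldingBackend",
    "ToyBackend",
    "get_backend",
    "energy_of_structure",
    "enumerate_structures",
    "enumerate_ensemble",
    "partition_function",
    "prob_of_structure",
    "mfe_structures",
    "mfe_value",
    "check_criterion",
    "positional_entropy",
    "IncompatibleStructureError",
]

#: Structures longer than this are refused by exhaustive enumeration.
ENUMERATION_CAP = 16

#: Tolerance for energy ties (toy energies are small exact sums).
ENERGY_TOL = 1e-9


class IncompatibleStructureError(ValueError):
    """A structure lies outside the ensemble of the sequence."""


@dataclass(frozen=True)
class EnergyModel:
    """Toy nearest-pair energy model (arbitrary units, RT-scaled).

    Parameters
    ----------
    pair_energy:
        Energy of each admissible pair type.  Defaults: CG/GC -3.0,
        AU/UA -2.0, GU/UG -1.0.
    stack_bonus:
        Energy added for each pair (i, j) whose inner neighbor
        (i+1, j-1) is also paired.  Default -1.0.
    min_hairpin:
        Minimum number of unpaired-capable positions enclosed by a pair;
        pair (i, j) requires j - i - 1 >= min_hairpin.  Default 3.
    RT:
        Boltzmann scale; weights are exp(-E / RT).  Default 1.0.
    """

    pair_energy: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("C", "G"): -3.0,
            ("G", "C"): -3.0,
            ("A", "U"): -2.0,
            ("U", "A"): -2.0,
            ("G", "U"): -1.0,
            ("U", "G"): -1.0,
        }
    )
    stack_bonus: float = -1.0
    min_hairpin: int = 3
    RT: float = 1.0

    def __post_init__(self) -> None:
        if self.RT <= 0:
            raise ValueError("RT must be positive")
        if self.min_hairpin < 0:
            raise ValueError("min_hairpin must be non-negative")
        missing = ALLOWED_PAIRS - set(self.pair_energy)
        if missing:
            raise ValueError(f"pair_energy missing types: {sorted(missing)}")
        for k, v in self.pair_energy.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite energy for pair {k}")

    def pairable(self, x: str, i: int, j: int) -> bool:
        """Whether 0-based positions i < j may pair in sequence ``x``."""
        return (
            j - i - 1 >= self.min_hairpin
            and (x[i], x[j]) in self.pair_energy
        )


TOY_MODEL = EnergyModel()


@dataclass
class EnsembleSummary:
    """Ensemble-level quantities of one sequence.

    Attributes
    ----------
    log_Q:
        Natural log of the partition function (kept in log space so long
        sequences do not overflow).
    bpp:
        Symmetric (n, n) matrix of base-pair probabilities ``p_ij``.
    """

    log_Q: float
    bpp: np.ndarray
    _unpaired: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.bpp.shape[0]

    @property
    def Q(self) -> float:
        """Partition function; may overflow to ``inf`` for long sequences."""
        try:
            return math.exp(self.log_Q)
        except OverflowError:
            return math.inf

    @property
    def unpaired_prob(self) -> np.ndarray:
        """Vector ``q_j = 1 - sum_i p_ij`` of unpaired probabilities."""
        if self._unpaired is None:
            q = 1.0 - self.bpp.sum(axis=0)
            self._unpaired = np.clip(q, 0.0, 1.0)
        return self._unpaired


@dataclass(frozen=True)
class CriterionResult:
    satisfies_mfe: bool
    satisfies_umfe: bool


@dataclass
class FoldAnalysis:
    """One full evaluation of a sequence against a target structure."""

    summary: EnsembleSummary
    target_prob: float


def energy_of_structure(
    x: str, y: SecondaryStructure, model: EnergyModel = TOY_MODEL
) -> float:
    """Toy free energy of ``y`` for ``x``: pair terms plus stacking bonuses.

    Raises :class:`IncompatibleStructureError` if any pair of ``y`` is not
    an admissible pair type in ``x`` or violates the hairpin minimum
    (i.e. ``y`` is outside the ensemble Y(x)).
    """
    if len(x) != y.n:
        raise ValueError(f"length mismatch: {len(x)} vs {y.n}")
    partner = y.partner
    e = 0.0
    for i, j in y.pair_set:
        i0, j0 = i - 1, j - 1
        if not model.pairable(x, i0, j0):
            raise IncompatibleStructureError(
                f"pair ({i}, {j}) = {x[i0]}-{x[j0]} not admissible"
            )
        e += model.pair_energy[(x[i0], x[j0])]
        if j0 - 1 > i0 + 1 and partner[i0 + 1] == j0 - 1:
            e += model.stack_bonus
    return e


# ---------------------------------------------------------------------------
# Exhaustive enumeration (the oracle path)
# ---------------------------------------------------------------------------

def enumerate_structures(
    x: str, model: EnergyModel = TOY_MODEL, cap: int = ENUMERATION_CAP
) -> list[SecondaryStructure]:
    """All pseudoknot-free structures ``x`` can form, including the empty one.

    Recursive enumeration over regions; refuses sequences longer than
    ``cap`` (use the dynamic programs instead).
    """
    n = len(x)
    if n > cap:
        raise ValueError(
            f"n={n} exceeds enumeration cap {cap}; use partition_function /"
            " mfe_structures (dynamic programming) instead"
        )

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        # all pair-sets for region [i, j] inclusive, 0-based
        if i > j:
            return ((),)
        out = []
        # position i unpaired
        out.extend(rec(i + 1, j))
        # position i paired with k
        for k in range(i + model.min_hairpin + 1, j + 1):
            if model.pairable(x, i, k):
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        out.append(((i, k),) + inner + outer)
        return tuple(out)

    structures = []
    for pairs in rec(0, n - 1):
        structures.append(
            SecondaryStructure.from_pairs(n, [(i + 1, j + 1) for i, j in pairs])
        )
    rec.cache_clear()
    return structures


def enumerate_ensemble(
    x: str, model: EnergyModel = TOY_MODEL, cap: int = ENUMERATION_CAP
) -> list[tuple[SecondaryStructure, float]]:
    """Every structure of the ensemble with its toy energy (brute force)."""
    return [
        (y, energy_of_structure(x, y, model))
        for y in enumerate_structures(x, model, cap)
    ]


# ---------------------------------------------------------------------------
# Dynamic programs
# ---------------------------------------------------------------------------

def _pair_weight_matrix(x: str, model: EnergyModel, kappa: float) -> np.ndarray:
    """Scaled Boltzmann weight of each admissible pair; 0 where disallowed."""
    n = len(x)
    W = np.zeros((n, n))
    inv_k2 = 1.0 / (kappa * kappa)
    for i in range(n):
        for j in range(i + model.min_hairpin + 1, n):
            e = model.pair_energy.get((x[i], x[j]))
            if e is not None:
                W[i, j] = math.exp(-e / model.RT) * inv_k2
    return W


def partition_function(
    x: str, model: EnergyModel = TOY_MODEL
) -> EnsembleSummary:
    """Partition function and base-pair probabilities by inside-outside DP.

    O(n^3) McCaskill-style recursions over two inside matrices (general
    region, and region closed by a pair, which carries the conditional
    stacking bonus) and their outside counterparts.  To keep intermediate
    values in floating-point range the per-nucleotide contributions are
    rescaled by ``exp(-G_mfe / (n RT))`` so the MFE structure has scaled
    weight 1; the reported ``log_Q`` undoes the scaling.
    """
    n = len(x)
    RnaSequence(x)  # validate alphabet
    gmfe = _mfe_tables(x, model)[0][0, n - 1] if n > 1 else 0.0
    kappa = math.exp(max(0.0, -gmfe / (model.RT * n)))
    su = 1.0 / kappa  # scaled weight of one unpaired position
    stw = math.exp(-model.stack_bonus / model.RT)
    W = _pair_weight_matrix(x, model, kappa)

    Q = np.zeros((n, n))
    Qb = np.zeros((n, n))
    # A[h, k] = Q over region [h, k-1]; A[k, k] = 1 (empty region)
    A = np.eye(n + 1)[:n, :]
    mh = model.min_hairpin
    for j in range(n):
        for i in range(j - mh - 1, -1, -1):
            if W[i, j] > 0.0:
                qint = Q[i + 1, j - 1] if j - 1 >= i + 1 else 1.0
                qbint = Qb[i + 1, j - 1] if j - 1 >= i + 1 else 0.0
                Qb[i, j] = W[i, j] * (qint + (stw - 1.0) * qbint)
        m = A[: j + 1, : j + 1] @ Qb[: j + 1, j]
        prev = np.ones(j + 1)
        if j > 0:
            prev[:j] = Q[:j, j - 1]
        Q[: j + 1, j] = su * prev + m
        if j + 1 < n:
            A[: j + 1, j + 1] = Q[: j + 1, j]

    log_Q = math.log(Q[0, n - 1]) + n * math.log(kappa)

    # Outside pass: OQ[i, j] is the outside value of the general-region item,
    # Ob[i, j] of the paired-region item; p_ij = Qb * Ob / Q_total.
    OQ = np.zeros((n, n))
    Ob = np.zeros((n, n))
    OQ[0, n - 1] = 1.0
    for span in range(n - 1, -1, -1):
        for i in range(0, n - span):
            j = i + span
            if (i, j) != (0, n - 1):
                acc = 0.0
                if j + 1 < n:
                    acc += su * OQ[i, j + 1]
                    acc += OQ[i, j + 1 :] @ Qb[j + 1, j + 1 :]
                if i - 1 >= 0 and j + 1 < n and W[i - 1, j + 1] > 0.0:
                    acc += Ob[i - 1, j + 1] * W[i - 1, j + 1]
                OQ[i, j] = acc
            if Qb[i, j] > 0.0:
                acc = OQ[: i + 1, j] @ A[: i + 1, i]
                if i - 1 >= 0 and j + 1 < n and W[i - 1, j + 1] > 0.0:
                    acc += Ob[i - 1, j + 1] * W[i - 1, j + 1] * (stw - 1.0)
                Ob[i, j] = acc

    bpp = Qb * Ob / Q[0, n - 1]
    bpp = bpp + bpp.T
    np.clip(bpp, 0.0, 1.0, out=bpp)
    return EnsembleSummary(log_Q=log_Q, bpp=bpp)


def prob_of_structure(
    x: str,
    y: SecondaryStructure,
    model: EnergyModel = TOY_MODEL,
    summary: EnsembleSummary | None = None,
) -> float:
    """Equilibrium probability ``p(y | x) = exp(-E(x, y) / RT) / Q(x)``.

    Raises :class:`IncompatibleStructureError` when ``y`` is outside the
    ensemble of ``x``.  A precomputed ``summary`` avoids refolding.
    """
    e = energy_of_structure(x, y, model)
    if summary is None:
        summary = partition_function(x, model)
    return math.exp(-e / model.RT - summary.log_Q)


def _mfe_tables(x: str, model: EnergyModel):
    """Min-plus DP tables: (E, Eb, Enb) with paired / not-paired split.

    ``E[i, j]`` is the minimum energy over region [i, j]; ``Eb`` restricts
    to (i, j) paired (carrying the conditional stack bonus with its inner
    neighbor); ``Enb`` to (i, j) not paired together.
    """
    n = len(x)
    INF = math.inf
    E = np.zeros((n, n))
    Eb = np.full((n, n), INF)
    Enb = np.zeros((n, n))
    mh = model.min_hairpin
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            if model.pairable(x, i, j):
                e0 = model.pair_energy[(x[i], x[j])]
                if j - 1 >= i + 1:
                    inner = min(
                        model.stack_bonus + Eb[i + 1, j - 1], Enb[i + 1, j - 1]
                    )
                else:
                    inner = 0.0
                Eb[i, j] = e0 + inner
            # (i, j) not paired together: j unpaired, or j paired with k > i
            best = E[i, j - 1]
            ks = np.arange(i + 1, j + 1)
            vals = E[i, ks - 1] + Eb[ks, j]
            if vals.size:
                best = min(best, vals.min())
            Enb[i, j] = best
            E[i, j] = min(Eb[i, j], best)
    return E, Eb, Enb


def mfe_value(x: str, model: EnergyModel = TOY_MODEL) -> float:
    """Minimum free energy over the ensemble (0 for the empty structure)."""
    n = len(x)
    if n < 2:
        return 0.0
    E, _, _ = _mfe_tables(x, model)
    return float(E[0, n - 1])


def _count_cooptimal(x: str, model: EnergyModel, tables=None) -> float:
    """Number of structures attaining the minimum energy (float; may be inf)."""
    n = len(x)
    if n < 2:
        return 1.0
    E, Eb, Enb = tables if tables is not None else _mfe_tables(x, model)
    C = np.ones((n, n))
    Cb = np.zeros((n, n))
    Cnb = np.ones((n, n))
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            if math.isfinite(Eb[i, j]):
                if j - 1 >= i + 1:
                    c = 0.0
                    st = model.stack_bonus + Eb[i + 1, j - 1]
                    target = Eb[i, j] - model.pair_energy[(x[i], x[j])]
                    if abs(st - target) <= ENERGY_TOL:
                        c += Cb[i + 1, j - 1]
                    if abs(Enb[i + 1, j - 1] - target) <= ENERGY_TOL:
                        c += Cnb[i + 1, j - 1]
                    Cb[i, j] = c
                else:
                    Cb[i, j] = 1.0
            # not-paired-together count
            c = 0.0
            if abs((E[i, j - 1] if j - 1 >= i else 0.0) - Enb[i, j]) <= ENERGY_TOL:
                c += C[i, j - 1] if j - 1 >= i else 1.0
            for k in range(i + 1, j + 1):
                if not math.isfinite(Eb[k, j]):
                    continue
                left = E[i, k - 1] if k - 1 >= i else 0.0
                if abs(left + Eb[k, j] - Enb[i, j]) <= ENERGY_TOL:
                    cl = C[i, k - 1] if k - 1 >= i else 1.0
                    c += cl * Cb[k, j]
            Cnb[i, j] = c
            tot = 0.0
            if abs(Eb[i, j] - E[i, j]) <= ENERGY_TOL:
                tot += Cb[i, j]
            if abs(Enb[i, j] - E[i, j]) <= ENERGY_TOL:
                tot += Cnb[i, j]
            C[i, j] = tot
    return float(C[0, n - 1])


def mfe_structures(
    x: str, model: EnergyModel = TOY_MODEL
) -> set[SecondaryStructure]:
    """The full argmin set: every structure attaining the minimum energy.

    Zero-slack traceback over the min-plus tables; ties are enumerated
    exhaustively, so the result matches brute-force enumeration.
    """
    n = len(x)
    if n < 2:
        return {SecondaryStructure("." * n)}
    E, Eb, Enb = _mfe_tables(x, model)

    @lru_cache(maxsize=None)
    def tb(i: int, j: int, which: str) -> tuple[tuple[tuple[int, int], ...], ...]:
        if i > j:
            return ((),)
        if which == "b":  # (i, j) paired
            e0 = model.pair_energy[(x[i], x[j])]
            if j - 1 < i + 1:
                return (((i, j),),)
            out = []
            target = Eb[i, j] - e0
            if abs(model.stack_bonus + Eb[i + 1, j - 1] - target) <= ENERGY_TOL:
                out.extend(((i, j),) + s for s in tb(i + 1, j - 1, "b"))
            if abs(Enb[i + 1, j - 1] - target) <= ENERGY_TOL:
                out.extend(((i, j),) + s for s in tb(i + 1, j - 1, "nb"))
            return tuple(out)
        if which == "nb":  # (i, j) not paired together
            out = []
            base = E[i, j - 1] if j - 1 >= i else 0.0
            if abs(base - Enb[i, j]) <= ENERGY_TOL:
                out.extend(tb(i, j - 1, "any"))
            for k in range(i + 1, j + 1):
                if not math.isfinite(Eb[k, j]):
                    continue
                left = E[i, k - 1] if k - 1 >= i else 0.0
                if abs(left + Eb[k, j] - Enb[i, j]) <= ENERGY_TOL:
                    for l in tb(i, k - 1, "any"):
                        for r in tb(k, j, "b"):
                            out.append(l + r)
            return tuple(out)
        # any
        out = []
        if math.isfinite(Eb[i, j]) and abs(Eb[i, j] - E[i, j]) <= ENERGY_TOL:
            out.extend(tb(i, j, "b"))
        if abs(Enb[i, j] - E[i, j]) <= ENERGY_TOL:
            out.extend(tb(i, j, "nb"))
        return tuple(out)

    result = {
        SecondaryStructure.from_pairs(n, [(a + 1, b + 1) for a, b in pairs])
        for pairs in tb(0, n - 1, "any")
    }
    tb.cache_clear()
    return result


def check_criterion(
    x: str, y_star: SecondaryStructure, model: EnergyModel = TOY_MODEL
) -> CriterionResult:
    """MFE / uMFE check via zero-slack co-optimal counting.

    ``satisfies_mfe`` iff the target attains the minimum energy;
    ``satisfies_umfe`` additionally requires the minimum to be unique, as
    determined by counting all co-optimal structures (the DP analogue of
    enumerating the zero-slack suboptimal set).
    """
    if len(x) != y_star.n:
        raise ValueError(f"length mismatch: {len(x)} vs {y_star.n}")
    try:
        e = energy_of_structure(x, y_star, model)
    except IncompatibleStructureError:
        return CriterionResult(False, False)
    n = len(x)
    tables = _mfe_tables(x, model) if n > 1 else None
    gmfe = float(tables[0][0, n - 1]) if n > 1 else 0.0
    if e > gmfe + ENERGY_TOL:
        return CriterionResult(False, False)
    count = _count_cooptimal(x, model, tables)
    return CriterionResult(True, count <= 1.0 + ENERGY_TOL)


def positional_entropy(summary: EnsembleSummary) -> np.ndarray:
    """Shannon entropy of each position's pairing distribution.

    ``S_i = -sum_j p_ij ln p_ij - q_i ln q_i`` with ``0 ln 0 := 0``.  Low
    values mean the position's fate is well determined in the ensemble.
    The commonly reported scalar metric is the mean over positions.
    """
    p = summary.bpp
    q = summary.unpaired_prob
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0.0, p * np.log(p), 0.0)
        qlogq = np.where(q > 0.0, q * np.log(q), 0.0)
    return -plogp.sum(axis=1) - qlogq


# ---------------------------------------------------------------------------
# Backend contract
# ---------------------------------------------------------------------------

class FoldingBackend(Protocol):
    """What the search engine requires from an energy model."""

    name: str

    def fold_summary(self, x: str) -> EnsembleSummary: ...

    def structure_prob(self, x: str, y: SecondaryStructure) -> float: ...

    def analyze(self, x: str, y_star: SecondaryStructure) -> FoldAnalysis: ...

    def mfe_structures(self, x: str) -> set[str]: ...

    def criterion(self, x: str, y_star: SecondaryStructure) -> CriterionResult: ...


class ToyBackend:
    """The built-in toy model behind the :class:`FoldingBackend` contract."""

    name = "toy"

    def __init__(self, model: EnergyModel = TOY_MODEL):
        self.model = model

    def fold_summary(self, x: str) -> EnsembleSummary:
        return partition_function(x, self.model)

    def structure_prob(self, x: str, y: SecondaryStructure) -> float:
        return prob_of_structure(x, y, self.model)

    def analyze(self, x: str, y_star: SecondaryStructure) -> FoldAnalysis:
        summary = partition_function(x, self.model)
        try:
            prob = prob_of_structure(x, y_star, self.model, summary=summary)
        except IncompatibleStructureError:
            prob = 0.0  # target lies outside the ensemble of x
        return FoldAnalysis(summary=summary, target_prob=prob)

    def mfe_structures(self, x: str) -> set[str]:
        return {s.dotbracket for s in mfe_structures(x, self.model)}

    def criterion(self, x: str, y_star: SecondaryStructure) -> CriterionResult:
        return check_criterion(x, y_star, self.model)


def get_backend(name: str, model: EnergyModel | None = None, **options) -> FoldingBackend:
    """Construct a folding backend by name ("toy" or "vienna")."""
    if name == "toy":
        return ToyBackend(model or TOY_MODEL)
    if name == "vienna":
        from .vienna import ViennaBackend  # deferred: engine is optional

        return ViennaBackend(**options)
    raise ValueError(f"unknown folding backend {name!r}")
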