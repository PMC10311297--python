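"""Structure-aware multifrontier search for RNA inverse folding.

The engine minimizes an ensemble objective (target-probability deficit or
normalized ensemble defect) over sequences compatible with a target
structure, and harvests every intermediate sequence that happens to
satisfy the MFE or uMFE criterion as a byproduct.  One design run:

1. *Targeted initialization*: unpaired target positions start as A, each
   target pair draws GC or CG at random, repeated until k distinct
   sequences exist.  Complementary all-GC helices strongly favor the
   target while leaving loops inert.
2. Iterate, keeping a frontier (priority queue) of the k lowest-objective
   distinct sequences seen in the whole history:
   a. draw one frontier sequence with probability proportional to
      exp((1 - f) / T) (Boltzmann over objective values),
   b. draw a position with probability proportional to exp(eps_i / T'),
      where eps_i is the positional ensemble defect (T' = 2T by default),
   c. apply a *structured mutation*: jointly resample the local
      structural unit containing the position (stack, mismatch, or both),
      excluding the current joint assignment,
   d. evaluate the new sequence, update the frontier, and record it in
      the MFE/uMFE byproduct sets if it passes the criterion check.
3. Stop when the best objective drops below a threshold, when no
   improvement is seen for a patience window, or after M iterations.

Each stage can be ablated independently (switches in
:class:`DesignConfig`) to fall back to random initialization, uniform
sampling, single-position mutation, a single-incumbent search (k = 1), or
final-sequence-only criterion checking.
"""

from __future__ import annotations

import enum
import itertools
import logging
import warnings
from bisect import insort
from dataclasses import dataclass, field

import numpy as np

from .folding import CriterionResult, FoldingBackend
from .objectives import objective_from_analysis, positional_defect
from .structures import BASES, PAIR_TYPES, RnaSequence, SecondaryStructure

_logger = logging.getLogger(__name__)

__all__ = [
    "DesignConfig",
    "Candidate",
    "Frontier",
    "DesignResult",
    "MutationScenario",
    "targeted_init",
    "sample_candidate",
    "sample_position",
    "classify_site",
    "scenario_unit",
    "enumerate_proposals",
    "structured_mutation",
    "design",
]


@dataclass
class DesignConfig:
    """All knobs of one design run.

    Defaults: frontier size ``k = 10``, sampling temperature ``T = 1.0``
    (position temperature ``T' = 2T``), at most ``M = 5000`` iterations,
    convergence when the best objective drops below 0.01 or fails to
    improve for 2000 consecutive iterations.
    """

    objective: str = "probability"
    k: int = 10
    T: float = 1.0
    t_prime: float | None = None  # defaults to 2 * T
    max_iters: int = 5000
    converge_eps: float = 0.01
    patience: int = 2000
    seed: int = 0
    use_targeted_init: bool = True
    use_boltzmann_sampling: bool = True
    use_structured_mutation: bool = True
    multifrontier: bool = True
    collect_byproducts: bool = True
    record_evaluations: bool = False
    log_every: int = 0  # 0 disables per-iteration logging

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if not (0 <= self.converge_eps < 1):
            raise ValueError("converge_eps must be in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    @property
    def effective_k(self) -> int:
        return self.k if self.multifrontier else 1

    @property
    def effective_t_prime(self) -> float:
        return 2.0 * self.T if self.t_prime is None else self.t_prime


@dataclass
class Candidate:
    """A sequence with its cached objective and positional defects."""

    sequence: RnaSequence
    objective: float
    iteration_found: int
    defects: np.ndarray = field(repr=False)
    criterion: CriterionResult | None = field(default=None, repr=False)
    order: int = 0  # insertion tie-break


class Frontier:
    """The k lowest-objective distinct sequences seen so far.

    Ordered ascending by (objective, insertion order); a new sequence
    enters only if it is absent and either the frontier is not full or it
    strictly beats the current worst entry (which is evicted).  Earlier
    entries win objective ties.
    """

    def __init__(self, k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self._entries: list[tuple[float, int, Candidate]] = []
        self._sequences: set[str] = set()

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def entries(self) -> list[Candidate]:
        return [c for _, _, c in self._entries]

    @property
    def best(self) -> Candidate:
        return self._entries[0][2]

    def add(self, cand: Candidate) -> bool:
        """Insert if admissible; returns whether the frontier changed."""
        if cand.sequence in self._sequences:
            return False
        if len(self._entries) >= self.k:
            worst_obj = self._entries[-1][0]
            if cand.objective >= worst_obj:
                return False
            _, _, worst = self._entries.pop()
            self._sequences.discard(worst.sequence)
        insort(self._entries, (cand.objective, cand.order, cand))
        self._sequences.add(cand.sequence)
        return True


@dataclass
class DesignResult:
    """Output of one design run.

    ``x_mfe`` / ``x_umfe`` are the byproduct solution lists (unique, in
    discovery order; every uMFE solution is also an MFE solution);
    ``x_best`` is the final frontier; ``trace[t]`` is the best objective
    after iteration t (entry 0 is the post-initialization value).
    """

    x_mfe: list[RnaSequence]
    x_umfe: list[RnaSequence]
    x_best: list[Candidate]
    trace: list[float]
    iterations_run: int
    stop_reason: str  # "converged" | "patience" | "max_iters"
    evaluations: list[tuple[RnaSequence, float]] = field(default_factory=list)
    byproduct_objectives: dict[str, float] = field(default_factory=dict)

    @property
    def best(self) -> Candidate:
        return self.x_best[0]


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def targeted_init(
    y_star: SecondaryStructure,
    k: int,
    rng: np.random.Generator,
    targeted: bool = True,
) -> list[RnaSequence]:
    """Draw ``k`` distinct initial sequences for the target structure.

    Targeted scheme: A at every unpaired position; an independent uniform
    choice between (G, C) and (C, G) at every pair.  With ``targeted``
    False (ablation), unpaired positions draw uniformly from the four
    bases and pairs from the six admissible pair types.

    If the structure admits fewer than ``k`` distinct targeted sequences
    (fewer than log2(k) pairs), the maximal distinct set is returned with
    a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs = sorted(y_star.pair_set)
    n = y_star.n
    if targeted:
        limit = 2 ** len(pairs) if len(pairs) < 63 else k
        if limit < k:
            warnings.warn(
                f"structure admits only {limit} distinct targeted initializations"
                f" (< k = {k})",
                stacklevel=2,
            )
            k = limit
    out: list[RnaSequence] = []
    seen: set[str] = set()
    # bounded retry loop; distinct draws exist by the cap above
    while len(out) < k:
        chars = ["A"] * n
        if not targeted:
            for pos in y_star.unpaired_set:
                chars[pos - 1] = BASES[rng.integers(4)]
        for i, j in pairs:
            if targeted:
                a, b = ("G", "C") if rng.integers(2) == 0 else ("C", "G")
            else:
                a, b = PAIR_TYPES[rng.integers(6)]
            chars[i - 1] = a
            chars[j - 1] = b
        s = "".join(chars)
        if s not in seen:
            seen.add(s)
            out.append(RnaSequence(s))
    return out


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _boltzmann_draw(
    weights_exponent: np.ndarray, rng: np.random.Generator
) -> int:
    # subtract max for numerical stability; normalization cancels the shift
    w = np.exp(weights_exponent - weights_exponent.max())
    return int(rng.choice(len(w), p=w / w.sum()))


def sample_candidate(
    frontier: Frontier,
    T: float,
    rng: np.random.Generator,
    boltzmann: bool = True,
) -> Candidate:
    """Draw a frontier entry with probability proportional to exp((1 - f) / T).

    Low-objective entries are favored; as T -> 0 the draw concentrates on
    the best entry, as T -> inf it becomes uniform.  With ``boltzmann``
    False (ablation) the draw is uniform.
    """
    if len(frontier) == 0:
        raise ValueError("frontier is empty")
    if T <= 0:
        raise ValueError("T must be positive")
    entries = frontier.entries
    if not boltzmann:
        return entries[int(rng.integers(len(entries)))]
    exponents = np.array([(1.0 - c.objective) / T for c in entries])
    return entries[_boltzmann_draw(exponents, rng)]


def sample_position(
    defects: np.ndarray,
    t_prime: float,
    rng: np.random.Generator,
    boltzmann: bool = True,
) -> int:
    """Draw a 0-based position with probability proportional to exp(eps_i / T').

    Positions that are incorrectly structured in the ensemble (high
    positional defect) are favored.  Uniform when ablated.
    """
    if t_prime <= 0:
        raise ValueError("t_prime must be positive")
    n = len(defects)
    if not boltzmann:
        return int(rng.integers(n))
    return _boltzmann_draw(np.asarray(defects, dtype=float) / t_prime, rng)


# ---------------------------------------------------------------------------
# Structured mutation
# ---------------------------------------------------------------------------

class MutationScenario(enum.Enum):
    """Local structural unit jointly resampled around a sampled position.

    The first six are the structured scenarios (joint space sizes in
    parentheses, after excluding the current assignment): STACK (35),
    PAIRED_DOUBLE_MISMATCH (95), STACK_PLUS_DOUBLE_MISMATCH (575),
    MISMATCH_5PRIME (23), MISMATCH_3PRIME (23),
    UNPAIRED_DOUBLE_MISMATCH (95).  PAIR is the fallback for paired
    positions whose inner context fits no scenario (5 alternatives);
    TRIVIAL resamples a single unpaired position (3 alternatives).
    """

    STACK = "stack"
    PAIRED_DOUBLE_MISMATCH = "paired_double_mismatch"
    STACK_PLUS_DOUBLE_MISMATCH = "stack_plus_double_mismatch"
    MISMATCH_5PRIME = "mismatch_5prime"
    MISMATCH_3PRIME = "mismatch_3prime"
    UNPAIRED_DOUBLE_MISMATCH = "unpaired_double_mismatch"
    PAIR = "pair"
    TRIVIAL = "trivial"


def classify_site(y_star: SecondaryStructure, i: int) -> MutationScenario:
    """Deterministically classify 0-based position ``i`` of the target.

    Paired positions are tested against the largest defined local unit
    first: stack plus double mismatches, then stack, then the
    loop-closing pair with its two interior mismatches; a paired position
    whose inner context matches none of these (e.g. a multiloop branch
    point) falls back to PAIR.  Unpaired positions trigger a scenario
    only when they sit just inside a pair (positions i+1 or j-1 of a pair
    (i, j)); all other unpaired positions are TRIVIAL.
    """
    n = y_star.n
    if not 0 <= i < n:
        raise IndexError(f"position {i} out of range for n={n}")
    partner = y_star.partner
    j = partner[i]
    if j >= 0:
        a, b = (i, j) if i < j else (j, i)
        inner_paired = (
            b - 1 > a + 1 and partner[a + 1] == b - 1
        )
        if inner_paired:
            if (
                b - 2 > a + 2
                and partner[a + 2] < 0
                and partner[b - 2] < 0
            ):
                return MutationScenario.STACK_PLUS_DOUBLE_MISMATCH
            return MutationScenario.STACK
        if (
            b - 1 > a + 1
            and partner[a + 1] < 0
            and partner[b - 1] < 0
        ):
            return MutationScenario.PAIRED_DOUBLE_MISMATCH
        return MutationScenario.PAIR
    # unpaired position: look for an enclosing pair with i just inside it
    if i - 1 >= 0 and partner[i - 1] > i:  # i is a+1 of pair (a, b)
        a, b = i - 1, partner[i - 1]
        if partner[b - 1] < 0 and b - 1 != i:
            return MutationScenario.UNPAIRED_DOUBLE_MISMATCH
        if partner[b - 1] >= 0:
            return MutationScenario.MISMATCH_5PRIME
        return MutationScenario.TRIVIAL
    if i + 1 < n and 0 <= partner[i + 1] < i:  # i is b-1 of pair (a, b)
        a, b = partner[i + 1], i + 1
        if partner[a + 1] < 0 and a + 1 != i:
            return MutationScenario.UNPAIRED_DOUBLE_MISMATCH
        if partner[a + 1] >= 0:
            return MutationScenario.MISMATCH_3PRIME
        return MutationScenario.TRIVIAL
    return MutationScenario.TRIVIAL


def scenario_unit(
    y_star: SecondaryStructure, i: int
) -> tuple[MutationScenario, list[tuple[int, int]], list[int]]:
    """The mutation unit at position ``i``: (scenario, pair slots, free slots).

    Pair slots are 0-based (a, b) pairs jointly assigned one of the six
    pair types; free slots are 0-based unpaired positions assigned one of
    the four bases.  All indices refer to the target structure.
    """
    scenario = classify_site(y_star, i)
    partner = y_star.partner
    j = partner[i]
    if scenario in (
        MutationScenario.STACK,
        MutationScenario.PAIRED_DOUBLE_MISMATCH,
        MutationScenario.STACK_PLUS_DOUBLE_MISMATCH,
        MutationScenario.PAIR,
    ):
        a, b = (i, j) if i < j else (j, i)
        if scenario is MutationScenario.STACK:
            return scenario, [(a, b), (a + 1, b - 1)], []
        if scenario is MutationScenario.PAIRED_DOUBLE_MISMATCH:
            return scenario, [(a, b)], [a + 1, b - 1]
        if scenario is MutationScenario.STACK_PLUS_DOUBLE_MISMATCH:
            return scenario, [(a, b), (a + 1, b - 1)], [a + 2, b - 2]
        return scenario, [(a, b)], []
    if scenario is MutationScenario.MISMATCH_5PRIME:
        a, b = i - 1, partner[i - 1]
        return scenario, [(a, b)], [i]
    if scenario is MutationScenario.MISMATCH_3PRIME:
        a, b = partner[i + 1], i + 1
        return scenario, [(a, b)], [i]
    if scenario is MutationScenario.UNPAIRED_DOUBLE_MISMATCH:
        if i - 1 >= 0 and y_star.partner[i - 1] > i:
            a, b = i - 1, partner[i - 1]
        else:
            a, b = partner[i + 1], i + 1
        return scenario, [(a, b)], [a + 1, b - 1]
    return MutationScenario.TRIVIAL, [], [i]


def _assignments(n_pairs: int, n_free: int):
    """All joint assignments: tuples of pair types then free bases."""
    return itertools.product(
        *([PAIR_TYPES] * n_pairs + [BASES] * n_free)
    )


def enumerate_proposals(
    x: str, y_star: SecondaryStructure, i: int
) -> list[RnaSequence]:
    """All sequences reachable by one structured mutation at position ``i``.

    The joint assignment over the unit differs from the current one (a
    single slot may keep its value as long as the whole unit changes);
    every proposal remains compatible with the target.
    """
    scenario, pair_slots, free_slots = scenario_unit(y_star, i)
    current = tuple(
        [(x[a], x[b]) for a, b in pair_slots] + [x[p] for p in free_slots]
    )
    out = []
    for assign in _assignments(len(pair_slots), len(free_slots)):
        if assign == current:
            continue
        chars = list(x)
        for (a, b), (ca, cb) in zip(pair_slots, assign):
            chars[a] = ca
            chars[b] = cb
        for p, c in zip(free_slots, assign[len(pair_slots) :]):
            chars[p] = c
        out.append(RnaSequence("".join(chars)))
    return out


def structured_mutation(
    x: str,
    y_star: SecondaryStructure,
    i: int,
    rng: np.random.Generator,
    structured: bool = True,
) -> RnaSequence:
    """One mutation at 0-based position ``i``, uniform over the proposal space.

    With ``structured`` False (ablation), falls back to the traditional
    minimal move: resample the single base (unpaired position, 3
    alternatives) or the single pair type (paired position, 5
    alternatives).
    """
    if structured:
        scenario, pair_slots, free_slots = scenario_unit(y_star, i)
    else:
        j = y_star.partner[i]
        if j >= 0:
            a, b = (i, j) if i < j else (j, i)
            pair_slots, free_slots = [(a, b)], []
        else:
            pair_slots, free_slots = [], [i]
    current = tuple(
        [(x[a], x[b]) for a, b in pair_slots] + [x[p] for p in free_slots]
    )
    size = 6 ** len(pair_slots) * 4 ** len(free_slots)
    # uniform over the space minus the current assignment, via rejection
    while True:
        assign = tuple(
            [PAIR_TYPES[rng.integers(6)] for _ in pair_slots]
            + [BASES[rng.integers(4)] for _ in free_slots]
        )
        if assign != current or size == 1:
            break
    chars = list(x)
    for (a, b), (ca, cb) in zip(pair_slots, assign):
        chars[a] = ca
        chars[b] = cb
    for p, c in zip(free_slots, assign[len(pair_slots) :]):
        chars[p] = c
    return RnaSequence("".join(chars))


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

def _evaluate(
    x: RnaSequence,
    y_star: SecondaryStructure,
    backend: FoldingBackend,
    kind: str,
    iteration: int,
    order: int,
    cache: dict,
    check: bool,
) -> Candidate:
    cached = cache.get(x)
    if cached is not None:
        obj, eps, crit = cached
    else:
        analysis = backend.analyze(x, y_star)
        obj = objective_from_analysis(analysis, y_star, kind)
        eps = positional_defect(analysis.summary, y_star)
        crit = None
    if check and crit is None:
        crit = backend.criterion(x, y_star)
    cache[x] = (obj, eps, crit)
    return Candidate(
        sequence=x,
        objective=obj,
        iteration_found=iteration,
        defects=eps,
        criterion=crit,
        order=order,
    )


def design(
    y_star: SecondaryStructure,
    config: DesignConfig,
    backend: FoldingBackend,
) -> DesignResult:
    """Run one multifrontier design for the target structure.

    Fully deterministic given (target, config, backend): a single RNG
    stream seeded from ``config.seed`` drives initialization, both
    sampling stages, and mutation in a fixed call order.  Repeated
    sequences are looked up in an evaluation cache rather than refolded;
    this changes nothing about the trajectory, only its cost.
    """
    rng = np.random.default_rng(config.seed)
    k = config.effective_k
    kind = config.objective
    frontier = Frontier(k)
    x_mfe: list[RnaSequence] = []
    x_umfe: list[RnaSequence] = []
    mfe_seen: set[str] = set()
    cache: dict = {}
    evaluations: list[tuple[RnaSequence, float]] = []
    byproduct_objectives: dict[str, float] = {}
    order = itertools.count()

    def record(cand: Candidate) -> None:
        if config.record_evaluations:
            evaluations.append((cand.sequence, cand.objective))
        if cand.criterion is not None and cand.criterion.satisfies_mfe:
            if cand.sequence not in mfe_seen:
                mfe_seen.add(cand.sequence)
                x_mfe.append(cand.sequence)
                byproduct_objectives[cand.sequence] = cand.objective
                if cand.criterion.satisfies_umfe:
                    x_umfe.append(cand.sequence)

    inits = targeted_init(y_star, k, rng, targeted=config.use_targeted_init)
    for x0 in inits:
        cand = _evaluate(
            x0, y_star, backend, kind, 0, next(order), cache,
            check=config.collect_byproducts,
        )
        frontier.add(cand)
        record(cand)

    trace = [frontier.best.objective]
    best_obj = trace[0]
    since_improvement = 0
    iterations = 0
    stop_reason = "max_iters"

    if best_obj < config.converge_eps:
        stop_reason = "converged"
    else:
        for t in range(1, config.max_iters + 1):
            parent = sample_candidate(
                frontier, config.T, rng, boltzmann=config.use_boltzmann_sampling
            )
            pos = sample_position(
                parent.defects,
                config.effective_t_prime,
                rng,
                boltzmann=config.use_boltzmann_sampling,
            )
            x_new = structured_mutation(
                parent.sequence, y_star, pos, rng,
                structured=config.use_structured_mutation,
            )
            cand = _evaluate(
                x_new, y_star, backend, kind, t, next(order), cache,
                check=config.collect_byproducts,
            )
            frontier.add(cand)
            record(cand)
            iterations = t
            current_best = frontier.best.objective
            trace.append(current_best)
            if current_best < best_obj:
                best_obj = current_best
                since_improvement = 0
            else:
                since_improvement += 1
            if config.log_every and t % config.log_every == 0:
                _logger.info(
                    "iter=%d best=%.6g frontier=%d mfe=%d umfe=%d",
                    t, current_best, len(frontier), len(x_mfe), len(x_umfe),
                )
            if current_best < config.converge_eps:
                stop_reason = "converged"
                break
            if since_improvement >= config.patience:
                stop_reason = "patience"
                break

    if not config.collect_byproducts:
        # ablation: only the final best sequence is criterion-checked
        best = frontier.best
        crit = backend.criterion(best.sequence, y_star)
        best.criterion = crit
        if crit.satisfies_mfe:
            x_mfe.append(best.sequence)
            byproduct_objectives[best.sequence] = best.objective
            if crit.satisfies_umfe:
                x_umfe.append(best.sequence)

    return DesignResult(
        x_mfe=x_mfe,
        x_umfe=x_umfe,
        x_best=frontier.entries,
        trace=trace,
        iterations_run=iterations,
        stop_reason=stop_reason,
        evaluations=evaluations,
        byproduct_objectives=byproduct_objectives,
    )
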