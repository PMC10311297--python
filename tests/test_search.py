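"""Multifrontier search: initialization, sampling, mutation, engine."""

import math

import numpy as np
import pytest

from rnadesign.fixtures import (
    StructureGenSpec,
    WORKED_EXAMPLE_SEQUENCE,
    WORKED_EXAMPLE_STRUCTURE,
    random_structure,
)
from rnadesign.folding import CriterionResult, EnsembleSummary, ToyBackend
from rnadesign.search import (
    Candidate,
    DesignConfig,
    Frontier,
    MutationScenario,
    classify_site,
    design,
    enumerate_proposals,
    sample_candidate,
    sample_position,
    scenario_unit,
    structured_mutation,
    targeted_init,
)
from rnadesign.structures import is_compatible, parse_dotbracket


def make_candidate(seq, obj, order=0):
    return Candidate(
        sequence=seq, objective=obj, iteration_found=0,
        defects=np.zeros(len(seq)), order=order,
    )


class TestTargetedInit:
    def test_worked_example_pattern(self, rng):
        y = parse_dotbracket(WORKED_EXAMPLE_STRUCTURE)
        for x in targeted_init(y, 10, rng):
            assert all(x[p - 1] == "A" for p in y.unpaired_set)
            for i, j in y.pair_set:
                assert {x[i - 1], x[j - 1]} == {"C", "G"}
            assert is_compatible(x, y)

    def test_printed_sequence_is_reachable(self, rng):
        y = parse_dotbracket(WORKED_EXAMPLE_STRUCTURE)
        drawn = {targeted_init(y, 1, rng)[0] for _ in range(2000)}
        assert WORKED_EXAMPLE_SEQUENCE in drawn
        assert len(drawn) == 64  # all 2^6 pair assignments appear

    def test_no_pairs_single_sequence(self, rng):
        y = parse_dotbracket(".....")
        with pytest.warns(UserWarning, match="distinct"):
            out = targeted_init(y, 3, rng)
        assert out == ["AAAAA"]

    def test_k_distinct(self, rng):
        y = parse_dotbracket(WORKED_EXAMPLE_STRUCTURE)
        out = targeted_init(y, 10, rng)
        assert len(set(out)) == 10

    def test_random_init_stays_compatible(self, rng):
        y = parse_dotbracket(WORKED_EXAMPLE_STRUCTURE)
        for x in targeted_init(y, 10, rng, targeted=False):
            assert is_compatible(x, y)


class TestSampling:
    def test_single_entry_certain(self, rng):
        f = Frontier(3)
        f.add(make_candidate("AAAA", 0.5))
        assert sample_candidate(f, 1.0, rng).sequence == "AAAA"

    def test_boltzmann_ratio_two_entries(self, rng):
        f = Frontier(2)
        f.add(make_candidate("AAAA", 0.0, order=0))
        f.add(make_candidate("CCCC", 1.0, order=1))
        draws = sum(
            sample_candidate(f, 1.0, rng).sequence == "AAAA" for _ in range(10_000)
        )
        assert draws / 10_000 == pytest.approx(math.e / (math.e + 1), abs=0.015)

    def test_dirac_limit(self, rng):
        f = Frontier(2)
        f.add(make_candidate("AAAA", 0.2, order=0))
        f.add(make_candidate("CCCC", 0.9, order=1))
        assert all(
            sample_candidate(f, 1e-6, rng).sequence == "AAAA" for _ in range(1000)
        )

    def test_uniform_when_ablated(self, rng):
        f = Frontier(2)
        f.add(make_candidate("AAAA", 0.0, order=0))
        f.add(make_candidate("CCCC", 1.0, order=1))
        draws = sum(
            sample_candidate(f, 1.0, rng, boltzmann=False).sequence == "AAAA"
            for _ in range(10_000)
        )
        assert draws / 10_000 == pytest.approx(0.5, abs=0.015)

    def test_position_weighting(self, rng):
        eps = np.array([1.0, 0.0, 0.0, 0.0])
        hits = sum(sample_position(eps, 2.0, rng) == 0 for _ in range(10_000))
        expected = math.exp(0.5) / (math.exp(0.5) + 3)
        assert hits / 10_000 == pytest.approx(expected, abs=0.015)

    def test_single_position(self, rng):
        assert sample_position(np.array([0.3]), 2.0, rng) == 0


class TestClassification:
    @pytest.mark.parametrize(
        "db, pos, expected",
        [
            # pos is 0-based
            ("((...))", 0, MutationScenario.STACK_PLUS_DOUBLE_MISMATCH),
            ("((...))", 6, MutationScenario.STACK_PLUS_DOUBLE_MISMATCH),
            ("(((...)))", 0, MutationScenario.STACK),
            ("(((...)))", 1, MutationScenario.STACK_PLUS_DOUBLE_MISMATCH),
            ("(((...)))", 2, MutationScenario.PAIRED_DOUBLE_MISMATCH),
            ("(...)", 0, MutationScenario.PAIRED_DOUBLE_MISMATCH),
            ("(...)", 1, MutationScenario.UNPAIRED_DOUBLE_MISMATCH),
            ("(...)", 3, MutationScenario.UNPAIRED_DOUBLE_MISMATCH),
            ("(...)", 2, MutationScenario.TRIVIAL),
            ("........", 3, MutationScenario.TRIVIAL),
            ("(.(...))", 1, MutationScenario.MISMATCH_5PRIME),
            ("((...).)", 6, MutationScenario.MISMATCH_3PRIME),
            # multiloop branch point: paired, irregular inner context
            ("((...)(...))", 0, MutationScenario.PAIR),
        ],
    )
    def test_scenarios(self, db, pos, expected):
        assert classify_site(parse_dotbracket(db), pos) is expected

    def test_deterministic_total_function(self, rng):
        for _ in range(20):
            y = random_structure(StructureGenSpec(n=40), rng)
            for i in range(40):
                s1 = classify_site(y, i)
                assert s1 is classify_site(y, i)
                assert isinstance(s1, MutationScenario)


class TestProposalSpaces:
    @pytest.mark.parametrize(
        "db, x, pos, expected_size",
        [
            ("(((...)))", "GGGAAACCC", 0, 35),            # stack
            ("(...)", "GAAAC", 0, 95),                    # pair + double mismatch
            ("((...))", "GGAAACC", 0, 575),               # stack + double mismatch
            ("(.(...))", "GAGAAACC", 1, 23),              # 5' single mismatch
            ("((...).)", "GGAAACAC", 6, 23),              # 3' single mismatch
            ("(...)", "GAAAC", 1, 95),                    # unpaired double mismatch
            ("((...)(...))", "GGAAACGAAACC", 0, 5),       # pair fallback
            ("........", "AAAAAAAA", 3, 3),               # trivial
        ],
    )
    def test_exhaustive_cardinalities(self, db, x, pos, expected_size):
        y = parse_dotbracket(db)
        proposals = enumerate_proposals(x, y, pos)
        assert len(proposals) == expected_size
        assert len(set(proposals)) == expected_size  # no duplicates
        assert x not in proposals
        for p in proposals:
            assert is_compatible(p, y)

    def test_mutation_closure_property(self, rng):
        # structured mutations never break target compatibility and never
        # return the unchanged sequence
        for _ in range(100):
            y = random_structure(StructureGenSpec(n=30), rng)
            x = targeted_init(y, 1, rng)[0]
            for _ in range(100):
                i = int(rng.integers(30))
                x2 = structured_mutation(x, y, i, rng)
                assert x2 != x
                assert is_compatible(x2, y)
                x = x2

    def test_mutation_changes_only_the_unit(self, rng):
        y = parse_dotbracket("((...))")
        x = "GGAAACC"
        _, pair_slots, free_slots = scenario_unit(y, 0)
        unit = {p for ab in pair_slots for p in ab} | set(free_slots)
        for _ in range(50):
            x2 = structured_mutation(x, y, 0, rng)
            diff = {i for i in range(7) if x2[i] != x[i]}
            assert diff and diff <= unit

    def test_traditional_mutation_when_ablated(self, rng):
        y = parse_dotbracket("((...))")
        x = "GGAAACC"
        for _ in range(50):
            x2 = structured_mutation(x, y, 0, rng, structured=False)
            # only the sampled pair may change
            assert all(x2[i] == x[i] for i in (1, 2, 3, 4, 5))
            assert (x2[0], x2[6]) != (x[0], x[6])


class TestFrontier:
    def test_insert_into_empty(self):
        f = Frontier(2)
        assert f.add(make_candidate("AAAA", 0.4))
        assert [c.sequence for c in f.entries] == ["AAAA"]

    def test_duplicate_rejected(self):
        f = Frontier(2)
        f.add(make_candidate("AAAA", 0.4, order=0))
        assert not f.add(make_candidate("AAAA", 0.1, order=1))
        assert len(f) == 1

    def test_eviction_semantics(self):
        f = Frontier(2)
        f.add(make_candidate("AAAA", 0.1, order=0))
        f.add(make_candidate("CCCC", 0.5, order=1))
        assert f.add(make_candidate("GGGG", 0.3, order=2))
        assert [c.objective for c in f.entries] == [0.1, 0.3]

    def test_tie_earlier_wins(self):
        f = Frontier(1)
        f.add(make_candidate("AAAA", 0.3, order=0))
        assert not f.add(make_candidate("CCCC", 0.3, order=1))
        assert f.best.sequence == "AAAA"


class _ScriptedBackend:
    """Minimal contract double: objective favors A-content; the criterion
    marks all-A sequences; used to exercise the engine without folding."""

    name = "scripted"

    def _summary(self, x):
        n = len(x)
        bpp = np.zeros((n, n))
        return EnsembleSummary(log_Q=0.0, bpp=bpp)

    def fold_summary(self, x):
        return self._summary(x)

    def structure_prob(self, x, y):
        return x.count("A") / len(x)

    def analyze(self, x, y):
        from rnadesign.folding import FoldAnalysis

        return FoldAnalysis(self._summary(x), self.structure_prob(x, y))

    def mfe_structures(self, x):
        return {"." * len(x)}

    def criterion(self, x, y):
        allA = set(x) == {"A"}
        return CriterionResult(allA, allA)


class TestEngine:
    def test_open_chain_converges_immediately(self):
        y = parse_dotbracket(".....")
        res = design(y, DesignConfig(seed=0), ToyBackend())
        assert res.stop_reason == "converged"
        assert res.iterations_run == 0
        assert res.x_umfe == ["AAAAA"]
        assert res.best.objective == pytest.approx(0.0)

    def test_determinism_bit_for_bit(self):
        y = parse_dotbracket(WORKED_EXAMPLE_STRUCTURE)
        cfg = DesignConfig(seed=7, max_iters=60)
        r1 = design(y, cfg, ToyBackend())
        r2 = design(y, cfg, ToyBackend())
        assert [c.sequence for c in r1.x_best] == [c.sequence for c in r2.x_best]
        assert r1.trace == r2.trace
        assert r1.x_mfe == r2.x_mfe and r1.x_umfe == r2.x_umfe
        assert r1.stop_reason == r2.stop_reason

    def test_trace_monotone_and_byproducts_sound(self):
        y = parse_dotbracket(WORKED_EXAMPLE_STRUCTURE)
        be = ToyBackend()
        res = design(y, DesignConfig(seed=3, max_iters=120), be)
        assert all(a >= b for a, b in zip(res.trace, res.trace[1:]))
        assert set(res.x_umfe) <= set(res.x_mfe)
        for x in res.x_mfe:
            assert be.criterion(x, y).satisfies_mfe
        for x in res.x_umfe:
            assert be.criterion(x, y).satisfies_umfe

    def test_frontier_is_k_best_of_history(self):
        y = parse_dotbracket(WORKED_EXAMPLE_STRUCTURE)
        cfg = DesignConfig(seed=11, max_iters=80, record_evaluations=True, k=5)
        res = design(y, cfg, ToyBackend())
        best_by_seq = {}
        for seq, obj in res.evaluations:
            best_by_seq.setdefault(seq, obj)
        expected = sorted(best_by_seq.values())[: len(res.x_best)]
        got = [c.objective for c in res.x_best]
        assert got == pytest.approx(expected)

    def test_multifrontier_off_equals_k1(self):
        y = parse_dotbracket(WORKED_EXAMPLE_STRUCTURE)
        r1 = design(y, DesignConfig(seed=5, max_iters=50, multifrontier=False), ToyBackend())
        r2 = design(y, DesignConfig(seed=5, max_iters=50, k=1), ToyBackend())
        assert r1.trace == r2.trace
        assert [c.sequence for c in r1.x_best] == [c.sequence for c in r2.x_best]

    def test_patience_stop(self):
        y = parse_dotbracket("(((...)))")
        cfg = DesignConfig(seed=1, max_iters=5000, patience=20, converge_eps=0.0)
        res = design(y, cfg, ToyBackend())
        assert res.stop_reason in ("patience", "max_iters")
        if res.stop_reason == "patience":
            assert res.iterations_run < 5000

    def test_runs_against_contract_double(self):
        y = parse_dotbracket("(((...)))")
        res = design(y, DesignConfig(seed=0, max_iters=30), _ScriptedBackend())
        assert res.iterations_run <= 30
        assert all(0 <= v <= 1 for v in res.trace)

    def test_byproducts_off_checks_only_final_best(self):
        y = parse_dotbracket(".....")
        res = design(
            y, DesignConfig(seed=0, collect_byproducts=False), ToyBackend()
        )
        assert len(res.x_mfe) <= 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DesignConfig(k=0)
        with pytest.raises(ValueError):
            DesignConfig(T=0.0)
        with pytest.raises(ValueError):
            DesignConfig(converge_eps=1.0)
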