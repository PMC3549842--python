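"""Search engine: moves, tabu, memory, elite set, and full runs."""

import random

import numpy as np
import pytest

from fccfold import (
    FCC,
    Conformation,
    EliteSet,
    LocalMinimaMemory,
    LocalSearch,
    SearchParams,
    enumerate_saws,
    fitness,
    get_packed,
    hp_energy,
    noniso_encode,
    random_saw,
    run,
    validate,
)
from fccfold.codec import steps_to_codes


def make_engine(sequence, coords=None, seed=0, **kw):
    engine = LocalSearch(sequence, SearchParams(seed=seed, **kw))
    if coords is not None:
        engine._set_conformation(coords)
    return engine


class TestInitialization:
    def test_single_monomer_sits_at_the_origin(self):
        engine = make_engine("H")
        assert engine.coords == [(0, 0, 0)]

    def test_same_seed_reproduces_the_walk(self):
        a = make_engine("HPHPHP" * 5, seed=11)
        b = make_engine("HPHPHP" * 5, seed=11)
        assert a.coords == b.coords

    def test_random_walks_are_always_valid(self):
        for seed in range(40):
            rng = random.Random(seed)
            coords = random_saw(50, rng, FCC)
            c = Conformation("P" * 50, tuple(coords))
            assert validate(c, FCC).ok

    def test_bad_sequence_is_rejected(self):
        with pytest.raises(ValueError):
            LocalSearch("HPX", SearchParams())
        with pytest.raises(ValueError):
            LocalSearch("", SearchParams())

    def test_bad_params_are_rejected(self):
        with pytest.raises(ValueError):
            SearchParams(memory_rate=1.5).validate()
        with pytest.raises(ValueError):
            SearchParams(max_stable=0).validate()


class TestTypeSchedule:
    def test_default_nine_h_then_one_p(self):
        engine = make_engine("HPHP")
        assert [engine.select_monomer_type(i) for i in range(1, 11)] == ["H"] * 9 + ["P"]
        assert engine.select_monomer_type(20) == "P"

    def test_strict_alternation_with_unit_period(self):
        engine = make_engine("HPHP", type_period=(1, 1))
        assert [engine.select_monomer_type(i) for i in range(1, 5)] == ["H", "P", "H", "P"]


class TestMoveGeneration:
    def test_interior_monomer_targets_are_common_free_neighbors(self):
        engine = make_engine("HHH", coords=((0, 0, 0), (1, 1, 0), (2, 0, 0)))
        targets = engine._candidate_targets(1)
        assert set(targets) == {(1, -1, 0), (1, 0, 1), (1, 0, -1)}

    def test_all_tabu_monomers_yield_no_moves(self):
        engine = make_engine("HHHH", seed=3)
        for i in range(4):
            engine.tabu[i] = 10**9
        assert engine.generate_moves("H") == []

    def test_h_moves_come_sorted_by_delta(self):
        engine = make_engine("HHHHHHHH", seed=5)
        moves = engine.generate_moves("H")
        deltas = [m.delta for m in moves]
        assert deltas == sorted(deltas)

    def test_applying_any_generated_move_preserves_validity(self):
        checked = 0
        for seed in range(30):
            engine = make_engine("HPHHPHPHHPHH", seed=seed)
            for mtype in ("H", "P"):
                for move in engine.generate_moves(mtype):
                    coords = list(engine.coords)
                    coords[move.monomer] = move.target
                    c = Conformation(engine.sequence, tuple(coords))
                    assert validate(c, FCC).ok
                    checked += 1
        assert checked > 100

    def test_end_moves_can_be_disabled(self):
        engine = make_engine("HHH", coords=((0, 0, 0), (1, 1, 0), (2, 0, 0)),
                             move_ends=False)
        assert engine._candidate_targets(0) == []
        assert engine._candidate_targets(2) == []

    def test_generated_deltas_match_module_delta_fitness(self):
        from fccfold import delta_fitness

        engine = make_engine("HHPHHPHH", seed=9)
        c = engine.conformation()
        for move in engine.generate_moves("H"):
            assert move.delta == delta_fitness(c, move.monomer, move.target)


class TestEliteSet:
    def test_top_is_minimal_fitness_with_recency_tiebreak(self):
        elite = EliteSet()
        elite.push(10, 1, ((0, 0, 0),))
        elite.push(5, 2, ((1, 1, 0),))
        elite.push(5, 7, ((0, 1, 1),))
        fit, negit, _, coords = elite.top()
        assert fit == 5 and -negit == 7 and coords == ((0, 1, 1),)

    def test_top_always_minimal_against_full_sort(self):
        rng = random.Random(0)
        elite = EliteSet()
        pushed = []
        for k in range(200):
            f, it = rng.randrange(50), k
            elite.push(f, it, ((f, it, 0),))
            pushed.append((f, -it))
        assert elite.top()[:2] == min(pushed)

    def test_capacity_evicts_the_worst(self):
        elite = EliteSet(capacity=3)
        for f in (4, 2, 9, 1):
            elite.push(f, f, ((f, 0, 0),))
        assert len(elite) == 3
        assert [e[0] for e in elite.entries] == [1, 2, 4]


class TestLocalMinimaMemory:
    def test_rate_one_stores_every_offer(self):
        memory = LocalMinimaMemory(rate=1.0)
        rng = random.Random(0)
        for k in range(50):
            memory.offer([k % 12, 0, 1], rng)
        assert len(memory) == 50 == memory.encountered

    def test_rate_zero_stores_nothing(self):
        memory = LocalMinimaMemory(rate=0.0)
        rng = random.Random(0)
        for _ in range(50):
            memory.offer([0, 1, 2], rng)
        assert len(memory) == 0
        assert memory.encountered == 50

    def test_length_mismatch_is_rejected(self):
        memory = LocalMinimaMemory()
        memory.add([0, 1, 2])
        with pytest.raises(ValueError):
            memory.matches([0, 1], 1)


class TestSelectMove:
    def test_memory_matched_best_is_skipped_for_runner_up(self):
        engine = make_engine("HHHHHH", seed=2, proximity=0)
        moves = engine.generate_moves("H")
        assert len(moves) >= 2
        best_enc = engine._candidate_encoding(moves[0])
        engine.memory.add(best_enc)
        selected = engine.select_move(moves)
        assert selected is not None
        assert engine.discards >= 1
        assert engine._candidate_encoding(selected).tolist() != best_enc.tolist()

    def test_unmatched_best_is_taken(self):
        engine = make_engine("HHHHHH", seed=2)
        moves = engine.generate_moves("H")
        assert engine.select_move(moves) == moves[0]

    def test_exhausted_list_signals_stagnation(self):
        engine = make_engine("HHHHHH", seed=2, proximity=0)
        moves = engine.generate_moves("H")
        for m in moves:
            engine.memory.add(engine._candidate_encoding(m))
        assert engine.select_move(moves) is None
        assert engine.non_improving == engine.params.max_stable + 1

    def test_elite_set_receives_only_unmatched_runner_ups(self):
        engine = make_engine("HHHHHH", seed=4, proximity=0)
        moves = engine.generate_moves("H")
        engine.select_move(moves)
        for fit, _negit, _cnt, coords in engine.elite.entries:
            enc = np.asarray(noniso_encode(steps_to_codes(coords, FCC), FCC), dtype=np.uint8)
            assert not engine.memory.matches(enc, engine.params.proximity)
            assert fit == fitness(Conformation(engine.sequence, coords))


class TestSelectFromEliteSet:
    def test_single_unmatched_element_is_returned_and_released(self):
        engine = make_engine("HHHH", seed=1)
        coords = tuple(engine.coords)
        engine.elite.push(fitness(engine.conformation()), 1, coords)
        selected = engine.select_from_elite_set()
        assert selected is not None and selected[0] == coords
        assert len(engine.elite) == 0

    def test_matched_top_is_popped_then_second_returned(self):
        engine = make_engine("HHHHHH", seed=1, proximity=0)
        rng = random.Random(5)
        walk_a = tuple(random_saw(6, rng, FCC))
        walk_b = tuple(random_saw(6, rng, FCC))
        engine.elite.push(0, 10, walk_a)   # top (better fitness)
        engine.elite.push(1, 11, walk_b)
        enc_a = noniso_encode(steps_to_codes(walk_a, FCC), FCC)
        engine.memory.add(enc_a)
        selected = engine.select_from_elite_set()
        assert selected is not None and selected[0] == walk_b

    def test_empty_set_signals_failure(self):
        engine = make_engine("HHHH", seed=1)
        assert engine.select_from_elite_set() is None


class TestRun:
    def test_all_polar_sequence_finishes_with_zero_energy(self):
        result = run("P" * 12, SearchParams(max_iterations=200, seed=0))
        assert result.best_energy == 0
        assert result.best_fitness == 0
        assert result.iterations == 200

    def test_fixed_seed_gives_identical_traces(self):
        params = dict(max_iterations=400, seed=123)
        a = run("HPHHPPHHPH", SearchParams(**params))
        b = run("HPHHPPHHPH", SearchParams(**params))
        assert a.trace == b.trace
        assert a.best_conformation.coords == b.best_conformation.coords

    def test_best_energy_is_reached_by_the_returned_conformation(self):
        result = run("HHPHHPHH", SearchParams(max_iterations=2000, seed=7))
        assert validate(result.best_conformation, FCC).ok
        assert hp_energy(result.best_conformation) == result.best_energy

    def test_small_instance_reaches_enumeration_optimum(self):
        sequence = "HHPHHPH"  # n=7
        walks = list(enumerate_saws(7, FCC, reduce_symmetry=True))
        optimum = min(
            hp_energy(Conformation(sequence, w)) for w in walks
        )
        result = run(sequence, SearchParams(max_iterations=30_000, seed=3))
        assert result.best_energy == optimum

    def test_observer_sees_every_iteration(self):
        seen = []
        run("HPHPHPHP", SearchParams(max_iterations=50, seed=0),
            observer=lambda e: seen.append(e.iteration))
        assert seen == list(range(1, 51))

    def test_retreat_lands_on_the_selected_elite_conformation(self):
        failures = []

        def check(engine):
            if "retreat" in engine.last_events:
                if tuple(engine.coords) != engine.last_retreat_target:
                    failures.append(engine.iteration)

        result = run(
            "HHHHPPHHHHPPHHHH",
            SearchParams(max_iterations=3000, seed=2, max_stable=30),
            observer=check,
        )
        assert result.retreats > 0
        assert failures == []

    def test_run_invariants_on_a_short_search(self):
        """Validity, monotone best energy, and tabu compliance each step."""
        shadow_tabu = {}
        best_seen = [0]

        def check(engine):
            coords = engine.coords
            assert len(set(coords)) == engine.n
            for k in range(engine.n - 1):
                p, q = coords[k], coords[k + 1]
                assert FCC.contains_step((q[0] - p[0], q[1] - p[1], q[2] - p[2]))
            assert engine.best_energy <= best_seen[0]
            best_seen[0] = engine.best_energy
            if "move" in engine.last_events:
                i = engine.last_move.monomer
                assert engine.iteration >= shadow_tabu.get(i, 0), "tabu violated"
            if "retreat" in engine.last_events or "restart" in engine.last_events:
                shadow_tabu.clear()
            elif "move" in engine.last_events:
                shadow_tabu[engine.last_move.monomer] = (
                    engine.iteration + engine.tenure
                )

        run("HPHHPHPHHPHHPHHHPHPH", SearchParams(max_iterations=4000, seed=9),
            observer=check)

    def test_incremental_fitness_and_energy_track_full_recompute(self):
        def check(engine):
            if engine.iteration % 500 == 0:
                c = engine.conformation()
                assert engine.fitness == fitness(c)
                assert engine.energy == hp_energy(c)

        run("HHPHHPPHHPHH", SearchParams(max_iterations=2000, seed=4),
            observer=check)
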