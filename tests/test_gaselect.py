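"""GA wrapper selection: cost function, operators, search behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpdus import gaselect
from cpdus.gaselect import (
    GAConfig,
    SubsetEvaluator,
    calibrate_lambdas,
    cost,
    crossover,
    exhaustive_search,
    mutate,
    repeat_runs,
    run_ga,
    tournament_select,
)
from cpdus.synthetic_flora import planted_table


class _StubEvaluator:
    """Duck-typed evaluator with a fixed error rate, for arithmetic tests."""

    def __init__(self, d, E=0.1):
        self.d = d
        self.E = E

    def evaluate(self, bits):
        return gaselect.EvalRecord(E=self.E, N=int(np.sum(bits)))


class TestCost:
    @pytest.mark.parametrize(
        "E,N,l1,l2,expected",
        [(0.05, 22, 1.0, 0.0, 0.05), (0.0, 10, 1.0, 0.01, 0.10), (0.2, 5, 0.5, 0.02, 0.20)],
    )
    def test_arithmetic(self, E, N, l1, l2, expected):
        assert cost(E, N, l1, l2) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cost(-0.1, 5, 1.0, 0.01)
        with pytest.raises(ValueError):
            cost(0.1, 0, 1.0, 0.01)


class TestCalibrate:
    def test_ratio_arithmetic(self):
        l1, l2 = calibrate_lambdas(_StubEvaluator(40, E=0.10), n_probe=20, seed=0)
        assert l1 == 1.0
        # mean N of ~Binomial(40, 1/2) probes is ~20, so lambda2 ~ 0.005
        assert l2 == pytest.approx(0.005, rel=0.15)

    def test_zero_error_floors_lambda2(self):
        with pytest.warns(UserWarning):
            _, l2 = calibrate_lambdas(_StubEvaluator(10, E=0.0), n_probe=10, seed=0)
        assert l2 == pytest.approx(1e-4)

    def test_seeded_determinism(self):
        a = calibrate_lambdas(_StubEvaluator(12, E=0.2), n_probe=15, seed=3)
        b = calibrate_lambdas(_StubEvaluator(12, E=0.2), n_probe=15, seed=3)
        assert a == b


class TestTournament:
    def test_full_tournament_always_returns_global_best(self):
        rng = np.random.default_rng(0)
        costs = np.array([3.0, 1.0, 2.0, 5.0])
        for _ in range(20):
            assert tournament_select(costs, size=4, rng=rng) == 1

    def test_size_one_is_uniform(self):
        rng = np.random.default_rng(1)
        costs = np.array([1.0, 2.0, 3.0, 4.0])
        picks = [tournament_select(costs, 1, rng) for _ in range(4000)]
        freqs = np.bincount(picks, minlength=4) / 4000
        assert np.allclose(freqs, 0.25, atol=0.03)

    def test_win_probability_matches_combinatorial_oracle(self):
        """Best of 5 with tournament size 3 wins iff drawn, i.e. with
        probability 1 - C(4,3)/C(5,3) = 0.6."""
        rng = np.random.default_rng(2)
        costs = np.array([5.0, 4.0, 1.0, 3.0, 2.0])
        wins = sum(tournament_select(costs, 3, rng) == 2 for _ in range(10_000))
        assert wins / 10_000 == pytest.approx(0.6, abs=0.02)

    def test_oversized_tournament_rejected(self):
        with pytest.raises(ValueError):
            tournament_select(np.array([1.0, 2.0]), 3, np.random.default_rng(0))


class TestCrossover:
    def test_zero_rate_copies_parents(self):
        rng = np.random.default_rng(0)
        a = np.array([1, 0, 1, 1, 0], dtype=bool)
        b = np.array([0, 1, 0, 0, 1], dtype=bool)
        c1, c2 = crossover(a, b, rate=0.0, rng=rng)
        assert (c1 == a).all() and (c2 == b).all()

    def test_ones_zeros_conserve_bit_count(self):
        rng = np.random.default_rng(1)
        d = 12
        for _ in range(50):
            c1, c2 = crossover(np.ones(d, bool), np.zeros(d, bool), rate=1.0, rng=rng)
            assert c1.sum() + c2.sum() == d

    def test_bit_frequency_matches_cut_enumeration_oracle(self):
        """With parents (all-ones, all-zeros), child1 carries a 1 at position
        j iff the uniform cut in 1..d-1 lands beyond j."""
        rng = np.random.default_rng(2)
        d, n = 8, 20_000
        counts = np.zeros(d)
        for _ in range(n):
            c1, _ = crossover(np.ones(d, bool), np.zeros(d, bool), rate=1.0, rng=rng)
            counts += c1
        expected = (d - 1 - np.arange(d)) / (d - 1)
        assert np.allclose(counts / n, expected, atol=0.02)


class TestMutate:
    def test_zero_rate_is_identity(self):
        bits = np.array([1, 0, 1], dtype=bool)
        assert (mutate(bits, 0.0, np.random.default_rng(0)) == bits).all()

    def test_rate_one_complements(self):
        bits = np.array([1, 0, 1, 0], dtype=bool)
        assert (mutate(bits, 1.0, np.random.default_rng(0)) == ~bits).all()

    def test_flip_fraction_matches_binomial_oracle(self):
        rng = np.random.default_rng(3)
        bits = np.zeros(100_000, dtype=bool)
        flipped = mutate(bits, 0.02, rng).sum()
        assert flipped / 100_000 == pytest.approx(0.02, abs=0.002)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 30), st.floats(0, 1), st.integers(0, 10_000))
    def test_children_never_empty(self, d, rate, seed):
        rng = np.random.default_rng(seed)
        bits = rng.random(d) < 0.2
        assert mutate(bits, rate, rng).any()
        c1, c2 = crossover(bits, ~bits, rate, rng)
        assert c1.any() and c2.any()


@pytest.fixture(scope="module")
def planted_eval():
    table, informative = planted_table(150, 5, 2, 4, seed=1)
    return SubsetEvaluator(table, cv=3, n_estimators=30, seed=0), informative


class TestEvaluateSubset:
    def test_informative_subset_has_low_error(self, planted_eval):
        ev, informative = planted_eval
        bits = np.array([c in informative for c in ev.columns])
        assert ev.evaluate(bits).E < 0.15

    def test_noise_subset_scores_at_chance(self, planted_eval):
        ev, informative = planted_eval
        bits = np.array([c not in informative for c in ev.columns])
        assert ev.evaluate(bits).E == pytest.approx(1 - 1 / 5, abs=0.12)

    def test_memoisation_returns_identical_record(self, planted_eval):
        ev, _ = planted_eval
        bits = np.array([True] * ev.d)
        before = ev.n_evaluations
        r1 = ev.evaluate(bits)
        r2 = ev.evaluate(bits)
        assert r1 is r2
        assert ev.n_evaluations <= before + 1

    def test_empty_chromosome_rejected(self, planted_eval):
        ev, _ = planted_eval
        with pytest.raises(ValueError):
            ev.evaluate(np.zeros(ev.d, dtype=bool))


class TestRunGA:
    def test_defaults_follow_standard_configuration(self):
        cfg = GAConfig()
        assert (cfg.pop_size, cfg.generations, cfg.tournament_size) == (50, 20, 3)

    def test_matches_exhaustive_search_on_small_problem(self, planted_eval):
        ev, _ = planted_eval
        res = run_ga(ev, GAConfig(pop_size=30, generations=10, seed=0))
        _, best_cost = exhaustive_search(ev, *res.lambdas)
        assert res.cost == pytest.approx(best_cost, abs=1e-12)

    def test_trace_is_monotone_for_every_seed(self, planted_eval):
        ev, _ = planted_eval
        for seed in range(3):
            res = run_ga(ev, GAConfig(pop_size=20, generations=8, seed=seed))
            assert res.trace.is_monotone()

    def test_cost_decomposition_exact(self, planted_eval):
        ev, _ = planted_eval
        res = run_ga(ev, GAConfig(pop_size=15, generations=5, seed=4))
        l1, l2 = res.lambdas
        assert res.cost == pytest.approx(l1 * res.error + l2 * res.N, abs=1e-12)
        rec = ev.evaluate(res.bits)
        assert rec.E == res.error and rec.N == res.N


class TestRepeatRuns:
    def test_five_runs_one_core_flag(self, planted_eval):
        ev, _ = planted_eval
        results, summary = repeat_runs(ev, GAConfig(pop_size=15, generations=5, seed=0), n_runs=5)
        assert len(results) == 5
        assert len(summary) == 5
        assert summary["core"].sum() == 1

    def test_core_flag_prefers_accuracy_then_brevity(self, planted_eval):
        ev, _ = planted_eval
        _, summary = repeat_runs(ev, GAConfig(pop_size=15, generations=5, seed=2), n_runs=3)
        core = summary[summary["core"]].iloc[0]
        assert core["accuracy"] == summary["accuracy"].max()
        ties = summary[summary["accuracy"] == core["accuracy"]]
        assert core["length"] == ties["length"].min()

    def test_core_accuracy_reproducible_from_scratch(self, planted_eval):
        ev, _ = planted_eval
        results, summary = repeat_runs(ev, GAConfig(pop_size=15, generations=5, seed=1), n_runs=2)
        core = results[int(summary[summary["core"]]["run"].iloc[0]) - 1]
        table, _ = planted_table(150, 5, 2, 4, seed=1)
        fresh = SubsetEvaluator(table, cv=3, n_estimators=30, seed=0)
        rec = fresh.evaluate(core.bits)
        assert rec.E == pytest.approx(core.error, abs=1e-12)
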