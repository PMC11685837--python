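"""Epistatic landscapes, greedy accumulation, the exact oracle, and
experiment planning."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from grape.greedy import (
    AccumulationPath,
    brute_force_best,
    combine_cluster_winners,
    greedy_accumulate,
    greedy_benchmark,
    plan_experiment,
    simulate_landscape,
)


def additive(effects: dict, noise=0.0, seed=0):
    from grape.greedy import EpistaticLandscape

    return EpistaticLandscape(
        mutations=tuple(effects), additive=dict(effects), epistasis={},
        noise_sd=noise, seed=seed,
    )


class TestLandscape:
    def test_empty_set_is_zero_without_noise(self):
        land = simulate_landscape(5, seed=1)
        assert land.measure(set()) == 0.0

    def test_additive_when_no_epistasis(self):
        land = simulate_landscape(6, epistasis_fraction=0.0, seed=2)
        for m, n in combinations(land.mutations, 2):
            assert land.measure({m, n}) == pytest.approx(
                land.additive[m] + land.additive[n])

    def test_full_set_equals_direct_summation(self):
        land = simulate_landscape(6, (1.0, 2.0), epistasis_fraction=0.3,
                                  epistasis_sd=1.0, noise_sd=0.0, seed=42)
        direct = sum(land.additive.values()) + sum(land.epistasis.values())
        assert land.true_value(set(land.mutations)) == pytest.approx(direct)

    def test_reproducible_for_seed(self):
        a = simulate_landscape(7, epistasis_fraction=0.5, epistasis_sd=2.0, seed=9)
        b = simulate_landscape(7, epistasis_fraction=0.5, epistasis_sd=2.0, seed=9)
        assert a.additive == b.additive and a.epistasis == b.epistasis

    def test_noise_is_per_measurement(self):
        land = simulate_landscape(3, noise_sd=1.0, seed=4)
        values = {land.measure({"M1"}) for _ in range(5)}
        assert len(values) > 1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_landscape(0)
        with pytest.raises(ValueError):
            simulate_landscape(3, epistasis_fraction=1.5)
        with pytest.raises(ValueError):
            simulate_landscape(3, noise_sd=-1.0)

    def test_unknown_mutation_rejected(self):
        land = simulate_landscape(3, seed=0)
        with pytest.raises(KeyError):
            land.true_value({"nope"})


class TestGreedyAccumulate:
    def test_additive_forced_path(self):
        land = additive({"up2": 2.0, "up1": 1.0, "down": -1.0})
        path = greedy_accumulate(list(land.mutations), land.measure,
                                 min_improvement=0.5)
        assert path.accepted == ["up2", "up1"]
        assert path.final_delta_tm == pytest.approx(3.0)
        assert path.stop_reason == "no_improvement"

    def test_all_negative_empty_path(self):
        land = additive({"a": -1.0, "b": -2.0})
        path = greedy_accumulate(list(land.mutations), land.measure)
        assert path.accepted == []
        assert path.stop_reason == "no_improvement"

    def test_accepted_trace_strictly_increasing_by_tolerance(self):
        land = simulate_landscape(8, (2.0, 2.0), epistasis_fraction=0.3,
                                  epistasis_sd=1.5, seed=13)
        path = greedy_accumulate(list(land.mutations), land.measure,
                                 min_improvement=1.5)
        trace = [0.0] + path.delta_tm_trace
        assert all(b - a >= 1.5 for a, b in zip(trace, trace[1:]))

    def test_evaluation_budget_bound(self):
        for seed in range(10):
            land = simulate_landscape(7, epistasis_fraction=0.4,
                                      epistasis_sd=2.0, seed=seed)
            path = greedy_accumulate(list(land.mutations), land.measure)
            k = len(land.mutations)
            assert path.evaluations_used <= k * (k + 1) // 2

    def test_budget_stops_search(self):
        land = additive({f"m{i}": 2.0 for i in range(6)})
        path = greedy_accumulate(list(land.mutations), land.measure, budget=4)
        assert path.evaluations_used == 4
        assert path.stop_reason == "budget"

    def test_evaluator_error_preserves_partial_path(self):
        calls = {"n": 0}

        def flaky(subset):
            calls["n"] += 1
            if calls["n"] > 4:
                raise RuntimeError("instrument failure")
            return float(len(subset))

        with pytest.raises(RuntimeError) as excinfo:
            greedy_accumulate(["a", "b", "c"], flaky, min_improvement=0.5)
        partial = excinfo.value.partial_path
        assert partial.evaluations_used == 4
        assert partial.stop_reason == "evaluator_error"

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            greedy_accumulate([], lambda s: 0.0)

    def test_additive_recovers_positive_set(self):
        """On additive noise-free landscapes greedy takes exactly the
        mutations whose effect clears the tolerance-compatible optimum."""
        for seed in range(20):
            land = simulate_landscape(9, (1.0, 2.0), epistasis_fraction=0.0,
                                      seed=seed)
            path = greedy_accumulate(list(land.mutations), land.measure,
                                     min_improvement=1e-9)
            positive = {m for m, a in land.additive.items() if a > 0}
            assert path.final_set == positive
            best_set, best_value = brute_force_best(land)
            assert best_set == positive
            assert path.final_delta_tm == pytest.approx(best_value)


class TestBruteForce:
    def test_additive_examples(self):
        land = additive({"up2": 2.0, "up1": 1.0, "down": -1.0})
        best_set, value = brute_force_best(land)
        assert best_set == {"up2", "up1"} and value == pytest.approx(3.0)
        all_neg = additive({"a": -1.0, "b": -0.5})
        assert brute_force_best(all_neg) == (frozenset(), 0.0)

    def test_oracle_dominates_greedy(self):
        for seed in range(10):
            land = simulate_landscape(10, epistasis_fraction=0.4,
                                      epistasis_sd=2.0, seed=100 + seed)
            path = greedy_accumulate(list(land.mutations), land.measure,
                                     min_improvement=1e-9)
            _, best_value = brute_force_best(land)
            assert land.true_value(path.final_set) <= best_value + 1e-9

    def test_size_limit(self):
        land = simulate_landscape(5, seed=0)
        with pytest.raises(ValueError):
            brute_force_best(land, max_n=4)


class TestPlanExperiment:
    members = {0: ["A1V", "S2T"], 1: ["D3G"]}

    def test_first_round_is_all_singles(self):
        proposal = plan_experiment(self.members, None)
        assert proposal[0]["next_round"] == ["A1V", "S2T"]
        assert proposal[1]["next_round"] == ["D3G"]
        assert not proposal[0]["converged"]

    def test_second_round_extends_best_single(self):
        results = pd.DataFrame({
            "variant": ["A1V", "S2T", "D3G"],
            "delta_tm": [3.0, 1.8, 0.4],
        })
        proposal = plan_experiment(self.members, results)
        assert proposal[0]["current_best"] == "A1V"
        assert proposal[0]["next_round"] == ["A1V+S2T"]
        # D3G failed the 1.5 °C bar: cluster 1 is converged at wild type
        assert proposal[1]["converged"]

    def test_converged_when_no_extension_qualifies(self):
        results = pd.DataFrame({
            "variant": ["A1V", "S2T", "A1V+S2T"],
            "delta_tm": [3.0, 1.8, 3.9],
        })
        proposal = plan_experiment(self.members, results)
        assert proposal[0]["converged"]
        assert proposal[0]["current_best"] == "A1V"

    def test_cross_cluster_subset_ignored_with_warning(self):
        results = pd.DataFrame({
            "variant": ["A1V+D3G"], "delta_tm": [5.0],
        })
        proposal = plan_experiment(self.members, results)
        assert any("spans clusters" in w for w in proposal["warnings"])
        assert proposal[0]["next_round"] == ["A1V", "S2T"]


class TestGreedyBenchmark:
    def test_additive_always_reaches_optimum(self):
        table = greedy_benchmark(repetitions=20, n=6, epistasis_fraction=0.0,
                                 noise_sd=0.0, min_improvement=1e-9, seed=3)
        assert table["reached_optimum"].all()
        # regret is a difference of two float sums taken in different orders
        assert (table["regret"].abs() < 1e-9).all()

    def test_evaluations_within_bound(self):
        table = greedy_benchmark(repetitions=30, n=8, epistasis_fraction=0.4,
                                 epistasis_sd=1.5, seed=5)
        assert (table["evaluations"] <= 8 * 9 // 2).all()

    def test_regret_nonnegative(self):
        table = greedy_benchmark(repetitions=30, n=7, epistasis_fraction=0.5,
                                 epistasis_sd=2.0, noise_sd=0.5, seed=6)
        assert (table["regret"] >= -1e-9).all()

    def test_frozen_regression_value(self):
        """Regression pin for the canonical benchmark settings, value
        computed once with the exhaustive oracle."""
        table = greedy_benchmark(repetitions=200, n=8, epistasis_fraction=0.3,
                                 epistasis_sd=1.0, noise_sd=0.0, seed=7)
        assert table["regret"].mean() == pytest.approx(1.7035230264701813,
                                                       rel=1e-9)


class TestCombineClusterWinners:
    def path(self, accepted, value):
        return AccumulationPath(accepted=list(accepted),
                                delta_tm_trace=[value] if accepted else [],
                                stop_reason="no_improvement")

    def test_first_proposal_is_union(self):
        land = additive({"A1V": 2.0, "S2T": 2.0, "D3G": 2.0})
        paths = {0: self.path(["A1V", "S2T"], 4.0), 1: self.path(["D3G"], 2.0)}
        final = combine_cluster_winners(paths, land.measure)
        assert final.evaluations[0][0] == {"A1V", "S2T", "D3G"}
        assert final.final_set == {"A1V", "S2T", "D3G"}
        assert final.final_delta_tm == pytest.approx(6.0)

    def test_position_conflict_rejected(self):
        paths = {0: self.path(["A123G"], 2.0), 1: self.path(["A123S"], 2.0)}
        with pytest.raises(ValueError, match="conflict"):
            combine_cluster_winners(paths, lambda s: 0.0)

    def test_single_cluster_identity(self):
        paths = {0: self.path(["A1V", "S2T"], 4.0)}
        final = combine_cluster_winners(paths, lambda s: 0.0)
        assert final.final_set == {"A1V", "S2T"}
        assert final.final_delta_tm == pytest.approx(4.0)
        assert final.evaluations_used == 0

    def test_falls_back_when_union_epistatically_bad(self):
        # strong negative coupling makes the union worse than cluster 0 alone
        from grape.greedy import EpistaticLandscape

        land = EpistaticLandscape(
            mutations=("A1V", "S2T", "D3G"),
            additive={"A1V": 3.0, "S2T": 2.0, "D3G": 2.0},
            epistasis={frozenset({"A1V", "D3G"}): -8.0},
        )
        paths = {0: self.path(["A1V", "S2T"], 5.0), 1: self.path(["D3G"], 2.0)}
        final = combine_cluster_winners(paths, land.measure)
        assert final.final_set == {"A1V", "S2T"}
        assert final.final_delta_tm == pytest.approx(5.0)
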