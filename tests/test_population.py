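"""Life-cycle steps: selection resampling, Poisson mutation, segmental LGT."""

import numpy as np
import pytest

from lgtratchet import (ExtinctionError, FitnessModel, ParameterError,
                        SimulationParams, advance_generation, init_population,
                        lgt_step, llc_size, mutation_step, segment_loci,
                        selection_step, simulate)

from conftest import make_state


class TestInitPopulation:
    @pytest.mark.parametrize("N,g", [(3, 4), (1, 1), (5000, 100)])
    def test_starts_mutation_free(self, N, g):
        state = init_population(SimulationParams(N=N, g=g, mu=0.0))
        assert state.counts.shape == (N, g)
        assert not state.counts.any()
        assert state.generation == 0
        assert llc_size(state) == N


class TestSelectionStep:
    def test_degenerate_weights_clone_single_parent(self, rng):
        state = make_state([[1, 2], [3, 4], [5, 6]])
        child = selection_step(state, np.array([1.0, 0.0, 0.0]), rng)
        assert np.all(child.counts == [1, 2])
        assert child.generation == state.generation + 1

    def test_parent_matrix_left_unmodified(self, rng):
        state = make_state([[1, 2], [3, 4]])
        before = state.counts.copy()
        selection_step(state, np.array([1.0, 1.0]), rng)
        assert np.array_equal(state.counts, before)

    def test_all_zero_fitness_raises_extinction(self, rng):
        state = make_state([[1], [1]], generation=3)
        with pytest.raises(ExtinctionError):
            selection_step(state, np.array([0.0, 0.0]), rng)

    def test_parentage_proportional_to_fitness(self):
        # fitness (1.0, 0.5) -> expected parentage 2/3 : 1/3; rows are
        # distinguishable so offspring identity reveals the parent.
        rng = np.random.default_rng(42)
        state = make_state([[0], [1]])
        w = np.array([1.0, 0.5])
        draws = 0
        from_first = 0
        for _ in range(5000):
            child = selection_step(state, w, rng)
            draws += child.N
            from_first += (child.counts[:, 0] == 0).sum()
        p_hat = from_first / draws
        se = np.sqrt((2 / 3) * (1 / 3) / draws)
        assert abs(p_hat - 2 / 3) < 3 * se

    def test_uniform_fitness_is_symmetric(self):
        rng = np.random.default_rng(7)
        state = make_state([[0], [1]])
        w = np.array([1.0, 1.0])
        draws = 0
        from_first = 0
        for _ in range(5000):
            child = selection_step(state, w, rng)
            draws += child.N
            from_first += (child.counts[:, 0] == 0).sum()
        se = np.sqrt(0.25 / draws)
        assert abs(from_first / draws - 0.5) < 3 * se


class TestMutationStep:
    def test_zero_rate_leaves_state_unchanged(self, rng):
        params = SimulationParams(N=4, g=3, mu=0.0)
        state = make_state(np.arange(12).reshape(4, 3))
        out = mutation_step(state, params, rng)
        assert np.array_equal(out.counts, state.counts)

    def test_mean_added_mutations_matches_genome_wide_rate(self):
        # U = 0.01 over 1e4 individuals: empirical mean within 3 SE
        rng = np.random.default_rng(3)
        params = SimulationParams(N=10_000, g=100, mu=1e-4)
        state = init_population(params)
        out = mutation_step(state, params, rng)
        added = out.counts.sum() / params.N
        se = np.sqrt(params.U / params.N)
        assert abs(added - params.U) < 3 * se

    def test_single_locus_counts_are_poisson(self):
        # g=1, U=2: all mutations land at locus 1; mean ~ 2 and var ~ 2
        rng = np.random.default_rng(4)
        params = SimulationParams(N=100_000, g=1, U=2.0, mutation_regime="genome_wide")
        out = mutation_step(init_population(params), params, rng)
        per_ind = out.counts[:, 0]
        assert per_ind.mean() == pytest.approx(2.0, abs=0.05)
        assert per_ind.var() == pytest.approx(2.0, abs=0.1)

    def test_never_decreases_any_entry(self, rng, small_params):
        state = make_state(np.ones((10, 5), dtype=np.int64))
        out = mutation_step(state, small_params, rng)
        assert np.all(out.counts >= state.counts)


class TestSegmentLoci:
    def test_wraps_circular_genome(self):
        # g=5, L=2, start at last locus -> segment {last, first}
        assert segment_loci(4, 2, 5).tolist() == [4, 0]

    def test_full_genome_segment_covers_all_loci(self):
        assert sorted(segment_loci(3, 5, 5).tolist()) == [0, 1, 2, 3, 4]

    def test_length_outside_genome_rejected(self):
        with pytest.raises(ParameterError):
            segment_loci(0, 6, 5)


class TestLgtStep:
    def test_zero_rate_leaves_state_unchanged(self, rng):
        params = SimulationParams(N=3, g=4, mu=0.0, lambda_lgt=0.0, L=2)
        state = make_state(np.arange(12).reshape(3, 4))
        donor = make_state(np.zeros((3, 4), dtype=np.int64))
        out = lgt_step(state, donor, params, rng)
        assert np.array_equal(out.counts, state.counts)

    def test_full_length_certain_lgt_copies_whole_donor_rows(self, rng):
        params = SimulationParams(N=5, g=4, mu=0.0, lambda_lgt=1.0, L=4)
        state = make_state(np.full((5, 4), 9))
        donor = make_state(np.arange(20).reshape(5, 4))
        out = lgt_step(state, donor, params, rng)
        donor_rows = {tuple(r) for r in donor.counts}
        assert all(tuple(r) in donor_rows for r in out.counts)

    def test_event_replaces_exactly_L_contiguous_circular_loci(self):
        rng = np.random.default_rng(9)
        params = SimulationParams(N=1, g=7, mu=0.0, lambda_lgt=1.0, L=3)
        state = make_state(np.zeros((1, 7), dtype=np.int64))
        donor = make_state(np.ones((1, 7), dtype=np.int64))
        out = lgt_step(state, donor, params, rng)
        changed = np.flatnonzero(out.counts[0])
        assert changed.size == 3
        # contiguity on the circle: the changed set is some rotation of 3 consecutive loci
        ext = np.concatenate([out.counts[0], out.counts[0]])
        runs = np.flatnonzero(np.convolve(ext, np.ones(3, int), "valid") == 3)
        assert runs.size > 0

    def test_load_can_decrease_through_lgt(self):
        rng = np.random.default_rng(11)
        params = SimulationParams(N=1, g=4, mu=0.0, lambda_lgt=1.0, L=4)
        state = make_state(np.full((1, 4), 5))
        donor = make_state(np.zeros((1, 4), dtype=np.int64))
        out = lgt_step(state, donor, params, rng)
        assert out.counts.sum() < state.counts.sum()

    def test_donor_genome_size_mismatch_rejected(self, rng):
        params = SimulationParams(N=2, g=4, mu=0.0, lambda_lgt=0.5, L=2)
        state = make_state(np.zeros((2, 4), dtype=np.int64))
        donor = make_state(np.zeros((2, 3), dtype=np.int64))
        with pytest.raises(ParameterError, match="donor"):
            lgt_step(state, donor, params, rng)


class TestAdvanceGeneration:
    def test_no_variation_stays_mutation_free(self, rng):
        params = SimulationParams(N=20, g=5, mu=0.0, lambda_lgt=0.0)
        fm = FitnessModel.uniform(5, 1e-3)
        state = init_population(params)
        for _ in range(10):
            state, stats = advance_generation(state, params, fm, rng)
            assert stats.llc_size == params.N
            assert not state.counts.any()

    def test_population_size_constant(self, rng, small_params):
        fm = FitnessModel.uniform(5, 1e-3)
        state = init_population(small_params)
        for _ in range(20):
            state, _ = advance_generation(state, small_params, fm, rng)
            assert state.N == small_params.N

    @pytest.mark.parametrize("event_order", ["methods", "figure1"])
    def test_trajectory_reproducible_bit_for_bit(self, event_order):
        params = SimulationParams(N=30, g=10, mu=0.02, lambda_lgt=0.3, L=3,
                                  generations=60, seed=5, event_order=event_order)
        fm = FitnessModel.uniform(10, 1e-3)
        a = simulate(params, fm)
        b = simulate(params, fm)
        assert np.array_equal(a.final_state.counts, b.final_state.counts)
        assert np.array_equal(a.llc_series, b.llc_series)
        assert a.tracker.text == b.tracker.text
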