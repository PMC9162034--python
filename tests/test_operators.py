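"""Genetic operators: constraint conservation and the documented edge cases."""

import numpy as np
import pytest

import degroot_ga as dg
from degroot_ga.hyperparameters import ControlParameters


class ScriptedRNG:
    """Pops one scalar per draw call and broadcasts it to the requested shape.

    Lets tests pin operator coins, blending factors, positions and noise.
    """

    def __init__(self, values):
        self.queue = list(values)

    def _fill(self, size):
        v = self.queue.pop(0)
        return np.full(size, v) if size is not None else v

    def random(self, size=None):
        return self._fill(size)

    def normal(self, loc=0.0, scale=1.0, size=None):
        return self._fill(size)


def random_population(A, k, seed):
    return dg.initialize_population(A, None, k, np.random.default_rng(seed))


@pytest.fixture
def ring_adjacency():
    a = np.eye(5, dtype=int)
    for i in range(5):
        a[i, (i + 1) % 5] = a[(i + 1) % 5, i] = 1
    return dg.AdjacencyMatrix(a)


class TestInitializePopulation:
    def test_composition_and_validity(self, full_adjacency_3):
        pop = random_population(full_adjacency_3, 5, seed=1)
        assert len(pop) == 5
        for c in pop:
            assert dg.validate_weight_matrix(c.weights, full_adjacency_3) == []
        np.testing.assert_array_equal(pop[-1].weights.entries, np.eye(3))

    def test_structural_zeros_respected(self, ring_adjacency):
        pop = random_population(ring_adjacency, 7, seed=2)
        zeros = ring_adjacency.entries == 0
        for c in pop:
            assert np.all(c.weights.entries[zeros] == 0)

    @pytest.mark.parametrize("k", [2, 4, 1])
    def test_even_or_tiny_population_rejected(self, full_adjacency_3, k):
        with pytest.raises(ValueError):
            random_population(full_adjacency_3, k, seed=0)

    def test_user_fixed_values_held(self, full_adjacency_3):
        pop = dg.initialize_population(
            full_adjacency_3, {(0, 1): 0.25}, 5, np.random.default_rng(3)
        )
        for c in pop[:-1]:
            assert c.weights.entries[0, 1] == 0.25
            assert c.weights.entries.sum(axis=1) == pytest.approx(np.ones(3))


class TestBlending:
    def test_pinned_beta_half_averages_rows(self, full_adjacency_2):
        B = dg.Chromosome(dg.WeightMatrix.from_adjacency([[0.2, 0.8], [0.2, 0.8]], full_adjacency_2))
        C = dg.Chromosome(dg.WeightMatrix.from_adjacency([[0.6, 0.4], [0.6, 0.4]], full_adjacency_2))
        rng = ScriptedRNG([0.0, 0.5])  # all rows fire; beta = 0.5
        b2, c2 = dg.blend_pair(B, C, p_b=1.0, rng=rng)
        np.testing.assert_allclose(b2.weights.entries, [[0.4, 0.6], [0.4, 0.6]])
        np.testing.assert_allclose(c2.weights.entries, [[0.4, 0.6], [0.4, 0.6]])

    def test_beta_one_is_identity(self, full_adjacency_2):
        B = dg.Chromosome(dg.WeightMatrix.from_adjacency([[0.2, 0.8], [0.7, 0.3]], full_adjacency_2))
        C = dg.Chromosome(dg.WeightMatrix.from_adjacency([[0.6, 0.4], [0.1, 0.9]], full_adjacency_2))
        rng = ScriptedRNG([0.0, 1.0])
        b2, c2 = dg.blend_pair(B, C, p_b=1.0, rng=rng)
        np.testing.assert_allclose(b2.weights.entries, B.weights.entries)
        np.testing.assert_allclose(c2.weights.entries, C.weights.entries)

    def test_exact_convex_combination(self, full_adjacency_2):
        B = dg.Chromosome(dg.WeightMatrix.from_adjacency([[0.2, 0.8], [0.7, 0.3]], full_adjacency_2))
        C = dg.Chromosome(dg.WeightMatrix.from_adjacency([[0.6, 0.4], [0.1, 0.9]], full_adjacency_2))
        beta = 0.3
        b2, c2 = dg.blend_pair(B, C, p_b=1.0, rng=ScriptedRNG([0.0, beta]))
        np.testing.assert_allclose(
            b2.weights.entries, beta * B.weights.entries + (1 - beta) * C.weights.entries
        )
        np.testing.assert_allclose(
            c2.weights.entries, (1 - beta) * B.weights.entries + beta * C.weights.entries
        )
        assert b2.weights.entries.sum(axis=1) == pytest.approx(np.ones(2))

    def test_rows_sum_to_one_for_random_betas(self, ring_adjacency, rng):
        pop = random_population(ring_adjacency, 3, seed=4)
        b2, c2 = dg.blend_pair(pop[0], pop[1], p_b=1.0, rng=rng)
        for c in (b2, c2):
            assert dg.validate_weight_matrix(c.weights, ring_adjacency) == []


class TestCrossover:
    def test_permutes_multiset_and_preserves_sum(self, rng):
        A = dg.AdjacencyMatrix(np.ones((3, 3), dtype=int))
        w = dg.WeightMatrix.from_adjacency([[0.1, 0.2, 0.7]] * 3, A)
        out = dg.crossover(dg.Chromosome(w), p_c=1.0, rng=rng)
        for row in out.weights.entries:
            assert sorted(row) == pytest.approx([0.1, 0.2, 0.7])

    def test_single_free_position_unchanged(self):
        a = np.eye(2, dtype=int)
        A = dg.AdjacencyMatrix(a)
        w = dg.WeightMatrix.from_adjacency(np.eye(2), A)
        out = dg.crossover(dg.Chromosome(w), p_c=1.0, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out.weights.entries, np.eye(2))

    def test_probability_zero_is_identity(self, ring_adjacency):
        pop = random_population(ring_adjacency, 3, seed=5)
        out = dg.crossover(pop[0], p_c=0.0, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out.weights.entries, pop[0].weights.entries)

    def test_fixed_values_stay_in_place(self, full_adjacency_3):
        w = dg.WeightMatrix.from_adjacency(
            [[0.25, 0.05, 0.7]] * 3, full_adjacency_3, fixed={(0, 0): 0.25}
        )
        rng = np.random.default_rng(1)
        for _ in range(20):
            out = dg.crossover(dg.Chromosome(w), p_c=1.0, rng=rng)
            assert out.weights.entries[0, 0] == 0.25
            assert sorted(out.weights.entries[0, 1:]) == pytest.approx([0.05, 0.7])


class TestMutation:
    def test_overflow_clamps_to_budget_and_zeroes_others(self, full_adjacency_2):
        # row (0.3, 0.7), select the 0.7, eps = +0.5 -> (0, 1)
        w = dg.WeightMatrix.from_adjacency([[0.3, 0.7], [0.3, 0.7]], full_adjacency_2)
        rng = ScriptedRNG([0.0, 0.6, 0.5])  # coins; u -> slot 1; eps
        out = dg.mutate(dg.Chromosome(w), p_m=1.0, sigma=1.0, rng=rng)
        np.testing.assert_allclose(out.weights.entries, [[0.0, 1.0], [0.0, 1.0]])

    def test_full_budget_weight_spreads_excess_evenly(self, full_adjacency_2):
        # row (0, 1), select the 1, eps = -0.4 -> (0.4, 0.6)
        w = dg.WeightMatrix.from_adjacency([[0.0, 1.0], [0.0, 1.0]], full_adjacency_2)
        rng = ScriptedRNG([0.0, 0.6, -0.4])
        out = dg.mutate(dg.Chromosome(w), p_m=1.0, sigma=1.0, rng=rng)
        np.testing.assert_allclose(out.weights.entries, [[0.4, 0.6], [0.4, 0.6]])

    def test_multiplicative_rescaling_of_other_weights(self, full_adjacency_3):
        # row (0.2, 0.3, 0.5), select the 0.5, eps = -0.1 -> (0.24, 0.36, 0.4)
        w = dg.WeightMatrix.from_adjacency([[0.2, 0.3, 0.5]] * 3, full_adjacency_3)
        rng = ScriptedRNG([0.0, 0.7, -0.1])  # u = 0.7 -> slot 2
        out = dg.mutate(dg.Chromosome(w), p_m=1.0, sigma=1.0, rng=rng)
        np.testing.assert_allclose(out.weights.entries, [[0.24, 0.36, 0.4]] * 3)

    def test_negative_result_clamped_to_zero(self, full_adjacency_2):
        # row (0.3, 0.7), select the 0.3, eps = -0.5 -> (0, 1)
        w = dg.WeightMatrix.from_adjacency([[0.3, 0.7], [0.3, 0.7]], full_adjacency_2)
        rng = ScriptedRNG([0.0, 0.2, -0.5])  # u = 0.2 -> slot 0
        out = dg.mutate(dg.Chromosome(w), p_m=1.0, sigma=1.0, rng=rng)
        np.testing.assert_allclose(out.weights.entries, [[0.0, 1.0], [0.0, 1.0]])

    def test_single_free_position_skipped(self):
        A = dg.AdjacencyMatrix(np.eye(2, dtype=int))
        w = dg.WeightMatrix.from_adjacency(np.eye(2), A)
        out = dg.mutate(dg.Chromosome(w), p_m=1.0, sigma=5.0, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out.weights.entries, np.eye(2))

    def test_validity_conserved_under_large_noise(self, ring_adjacency, rng):
        c = random_population(ring_adjacency, 3, seed=6)[0]
        for _ in range(50):
            c = dg.mutate(c, p_m=1.0, sigma=2.0, rng=rng)
            assert dg.validate_weight_matrix(c.weights, ring_adjacency) == []


class TestGeneSwap:
    @pytest.fixture
    def swap_case(self):
        """Panel generated by a known W; best has a corrupted row, donor holds the truth."""
        scale = dg.OrdinalScale(10)
        truth = np.array([[0.5, 0.5], [0.25, 0.75]])
        latent = dg.degroot_trajectory(truth, [0.05, 0.95], 4)
        observed = dg.forward_transform(dg.back_transform(latent, scale), scale)
        bad = truth.copy()
        bad[0] = [1.0, 0.0]
        best = dg.Chromosome(dg.WeightMatrix(bad))
        donor = dg.Chromosome(dg.WeightMatrix(truth.copy()))
        best_fit = dg.chromosome_fitness(best.weights, observed, scale)
        assert best_fit.total > 0  # precondition: the corrupted row hurts
        return best, donor, observed, scale

    def test_recovers_true_row_from_donor(self, swap_case):
        best, donor, observed, scale = swap_case
        best2, donors2, accepted = dg.gene_swap(best, [donor], observed, scale)
        assert accepted
        assert best2.fitness.total < dg.chromosome_fitness(best.weights, observed, scale).total
        np.testing.assert_array_equal(best2.weights.entries[0], [0.5, 0.5])
        # the donor received the corrupted row in exchange
        np.testing.assert_array_equal(donors2[0].weights.entries[0], [1.0, 0.0])

    def test_no_fitter_gene_leaves_best_unchanged(self, swap_case):
        best, donor, observed, scale = swap_case
        # swap roles: the perfect chromosome has no genes to gain
        best2, donors2, accepted = dg.gene_swap(donor, [best], observed, scale)
        assert not accepted
        np.testing.assert_array_equal(best2.weights.entries, donor.weights.entries)
        np.testing.assert_array_equal(donors2[0].weights.entries, best.weights.entries)

    def test_swap_is_all_or_nothing(self, rng):
        """Non-improving combined swaps revert both chromosomes."""
        scale = dg.OrdinalScale(5)
        truth = np.array([[0.6, 0.4], [0.3, 0.7]])
        latent = dg.degroot_trajectory(truth, [0.1, 0.9], 3)
        observed = dg.forward_transform(dg.back_transform(latent, scale), scale)
        for _ in range(25):
            w1 = rng.random((2, 2))
            w1 /= w1.sum(axis=1, keepdims=True)
            w2 = rng.random((2, 2))
            w2 /= w2.sum(axis=1, keepdims=True)
            c1 = dg.Chromosome(dg.WeightMatrix(w1))
            c2 = dg.Chromosome(dg.WeightMatrix(w2))
            f1 = dg.chromosome_fitness(c1.weights, observed, scale)
            best, donor = (c1, c2) if f1.total <= dg.chromosome_fitness(
                c2.weights, observed, scale
            ).total else (c2, c1)
            before = best.weights.entries.copy()
            donor_before = donor.weights.entries.copy()
            best2, donors2, accepted = dg.gene_swap(best, [donor], observed, scale)
            if accepted:
                assert best2.fitness.total < dg.chromosome_fitness(
                    dg.WeightMatrix(before), observed, scale
                ).total
            else:
                np.testing.assert_array_equal(best2.weights.entries, before)
                np.testing.assert_array_equal(donors2[0].weights.entries, donor_before)


class TestSelectElite:
    def test_zero_fitness_chromosome_is_elite(self, centered_dataset):
        scale = dg.OrdinalScale(centered_dataset.spec.bins)
        observed = dg.forward_transform(centered_dataset.observed, scale)
        pop = random_population(centered_dataset.adjacency, 5, seed=7)
        pop[2] = dg.Chromosome(centered_dataset.true_weights.copy())
        elite, rest = dg.select_elite(pop, observed, scale)
        assert elite.fitness.total == 0.0
        assert len(rest) == 4
        assert all(elite.fitness.total <= c.fitness.total for c in rest)

    def test_tie_breaks_to_lowest_index(self, centered_dataset):
        scale = dg.OrdinalScale(centered_dataset.spec.bins)
        observed = dg.forward_transform(centered_dataset.observed, scale)
        pop = random_population(centered_dataset.adjacency, 5, seed=8)
        pop[1] = dg.Chromosome(centered_dataset.true_weights.copy())
        pop[3] = dg.Chromosome(centered_dataset.true_weights.copy())
        elite, rest = dg.select_elite(pop, observed, scale)
        # both perfect; the earlier one is chosen, the later stays in the rest
        assert elite.fitness.total == 0.0
        assert sum(c.fitness.total == 0.0 for c in rest) == 1


class TestSurvive:
    @pytest.fixture
    def panel_case(self, small_dataset):
        scale = dg.OrdinalScale(small_dataset.spec.bins)
        observed = dg.forward_transform(small_dataset.observed, scale)
        return scale, observed

    def test_survivor_at_least_as_fit_as_both(self, small_dataset, panel_case):
        scale, observed = panel_case
        parents = random_population(small_dataset.adjacency, 9, seed=9)[:-1]
        offspring = random_population(small_dataset.adjacency, 9, seed=10)[:-1]
        out = dg.survive(parents, offspring, observed, scale)
        assert len(out) == len(parents)
        for s, p, o in zip(out, parents, offspring):
            assert s.fitness.total <= min(p.fitness.total, o.fitness.total) + 1e-12

    def test_tie_goes_to_parent(self, centered_dataset):
        scale = dg.OrdinalScale(centered_dataset.spec.bins)
        observed = dg.forward_transform(centered_dataset.observed, scale)
        parent = dg.Chromosome(centered_dataset.true_weights.copy())
        # a second exactly-perfect chromosome whose entries differ: a tiny
        # sum-preserving perturbation keeps every prediction in its bin
        w2 = centered_dataset.true_weights.copy()
        i = 0
        free = np.nonzero(~w2.fixed_mask[i])[0][:2]
        w2.entries[i, free[0]] += 1e-9
        w2.entries[i, free[1]] -= 1e-9
        f_par = dg.chromosome_fitness(parent.weights, observed, scale).total
        f_off = dg.chromosome_fitness(w2, observed, scale).total
        assert f_par == f_off == 0.0
        out = dg.survive([parent], [dg.Chromosome(w2)], observed, scale)
        np.testing.assert_array_equal(out[0].weights.entries, parent.weights.entries)

    def test_length_mismatch_rejected(self, small_dataset, panel_case):
        scale, observed = panel_case
        pop = random_population(small_dataset.adjacency, 5, seed=11)
        with pytest.raises(dg.DimensionError):
            dg.survive(pop[:2], pop[:3], observed, scale)


class TestAdaptControls:
    def test_single_trigger_multiplies_and_clamps(self):
        hp = dg.HyperParameters.from_levels("medium", "moderate", "slow")
        controls = hp.initial_controls
        out = dg.adapt_controls(controls, hp, stagnation=200)
        assert out.p_b == pytest.approx(0.2)  # 0.1 * 2, below maxb = 0.5
        assert out.p_c == pytest.approx(0.05)  # 0.1 * 0.5
        assert out.p_m == pytest.approx(0.05)
        assert out.sigma == pytest.approx(0.25)

    def test_repeated_triggers_saturate_at_bounds(self):
        hp = dg.HyperParameters.from_levels("medium", "moderate", "slow")
        controls = hp.initial_controls
        for k in range(1, 21):
            controls = dg.adapt_controls(controls, hp, stagnation=200 * k)
        assert controls.p_b == 0.5  # maxb
        assert controls.p_c == 0.01  # minc
        assert controls.p_m == 0.01
        assert controls.sigma == 0.01

    def test_no_stagnation_no_change(self):
        hp = dg.HyperParameters()
        controls = ControlParameters(0.2, 0.2, 0.2, 0.4)
        assert dg.adapt_controls(controls, hp, stagnation=0) == controls

    def test_off_multiple_stagnation_no_change(self):
        hp = dg.HyperParameters()
        controls = hp.initial_controls
        assert dg.adapt_controls(controls, hp, stagnation=123) == controls


class TestReintroduce:
    def _evaluated(self, small_dataset):
        scale = dg.OrdinalScale(small_dataset.spec.bins)
        observed = dg.forward_transform(small_dataset.observed, scale)
        pop = random_population(small_dataset.adjacency, 7, seed=12)
        elite, rest = dg.select_elite(pop, observed, scale)
        return elite, rest

    def test_elite_clone_replaces_worst(self, small_dataset):
        elite, rest = self._evaluated(small_dataset)
        worst = max(range(len(rest)), key=lambda i: rest[i].fitness.total)
        out = dg.reintroduce_chromosome(rest, elite, "elite")
        np.testing.assert_array_equal(out[worst].weights.entries, elite.weights.entries)

    def test_identity_mode_inserts_identity(self, small_dataset):
        elite, rest = self._evaluated(small_dataset)
        out = dg.reintroduce_chromosome(rest, elite, "identity")
        assert any(np.array_equal(c.weights.entries, np.eye(4)) for c in out)

    def test_worst_tie_breaks_to_highest_index(self, small_dataset):
        # fabricate fitness values: exact tie for worst between slots 1 and 2
        pop = random_population(small_dataset.adjacency, 7, seed=13)[:3]
        for c, total in zip(pop, (1.0, 5.0, 5.0)):
            c.fitness = dg.FitnessValue(total, np.full(4, total / 4))
        elite = pop[0].copy()
        out = dg.reintroduce_chromosome(pop, elite, "elite")
        np.testing.assert_array_equal(out[2].weights.entries, elite.weights.entries)
        np.testing.assert_array_equal(out[1].weights.entries, pop[1].weights.entries)
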