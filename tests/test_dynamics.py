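"""Asynchronous engine: initialization, single steps, runs, ensembles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from dissentnet.core import CHOICE_A, CHOICE_B
from dissentnet.dynamics import (
    EnvironmentSchedule,
    Subpop,
    async_step,
    init_population,
    run,
    run_ensemble,
)
from dissentnet.metrics import alignment
from dissentnet.netgen import generate_ba

from conftest import make_population

HALF_HALF = [
    Subpop("pref_A", 10.0, 1.0, 0.5),
    Subpop("pref_B", -10.0, 1.0, 0.5),
]


class TestInitPopulation:
    def test_all_A_boundary(self, small_ba, rng):
        pop = init_population(small_ba, None, HALF_HALF, 1.0, rng=rng)
        assert np.all(pop.sigma == CHOICE_A)

    def test_half_half_counts_differ_by_at_most_one(self, small_ba, rng):
        pop = init_population(small_ba, None, HALF_HALF, 1.0, rng=rng)
        counts = np.bincount(pop.subpop_ids)
        assert abs(counts[0] - counts[1]) <= 1
        assert set(np.unique(pop.delta_o)) == {-10.0, 10.0}

    def test_initial_fraction_exact(self, small_ba, rng):
        pop = init_population(small_ba, None, HALF_HALF, 0.37, rng=rng)
        assert int(np.sum(pop.sigma == CHOICE_A)) == round(0.37 * pop.n)

    def test_placed_subpop_sits_on_indicator(self, small_ba, rng):
        indicator = np.zeros(100, bool)
        indicator[:20] = True
        comp = [
            Subpop("conf", 10.0, 1.0, 0.8),
            Subpop("anti", 10.0, -1.0, 0.2),
        ]
        pop = init_population(small_ba, indicator, comp, 0.5, rng=rng)
        assert np.all(pop.w[indicator] == -1.0)
        assert np.all(pop.w[~indicator] == 1.0)

    def test_fixed_seed_identical_state(self, small_ba):
        pops = [
            init_population(small_ba, None, HALF_HALF, 0.5, rng=np.random.default_rng(3))
            for _ in range(2)
        ]
        assert np.array_equal(pops[0].sigma, pops[1].sigma)
        assert np.array_equal(pops[0].delta_o, pops[1].delta_o)

    def test_mismatched_indicator_rejected(self, small_ba, rng):
        indicator = np.zeros(100, bool)
        indicator[:50] = True  # but anti fraction says 20%
        comp = [Subpop("conf", 10.0, 1.0, 0.8), Subpop("anti", 10.0, -1.0, 0.2)]
        with pytest.raises(ValueError):
            init_population(small_ba, indicator, comp, 0.5, rng=rng)

    def test_fractions_must_sum_to_one(self, small_ba, rng):
        with pytest.raises(ValueError):
            init_population(small_ba, None, [Subpop("x", 1.0, 1.0, 0.7)], 0.5, rng=rng)


class TestAsyncStep:
    def test_nonconformist_follows_preference(self, rng):
        pop = make_population(nx.complete_graph(10), 10.0, 0.0, CHOICE_B)
        for t in range(50):
            async_step(pop, EnvironmentSchedule.static(), t, rng)
        updated = pop.sigma == CHOICE_A
        assert updated.sum() > 0  # some agents were picked and all moved to A

    def test_conformist_overridden_by_unanimous_neighborhood(self, rng):
        # star center prefers A (delta_o=10) but 20 B-neighbors give dU = -10
        g = nx.star_graph(20)
        delta_o = np.array([10.0] + [-10.0] * 20)
        w = np.array([1.0] + [0.0] * 20)
        pop = make_population(g, delta_o, w, CHOICE_B)
        pop.sigma[0] = CHOICE_A
        rng_fixed = np.random.default_rng(0)
        for t in range(200):
            async_step(pop, EnvironmentSchedule.static(), t, rng_fixed)
        assert pop.sigma[0] == CHOICE_B

    def test_single_step_changes_at_most_one_node(self, small_ba, rng):
        pop = init_population(small_ba, None, HALF_HALF, 0.5, rng=rng)
        before = pop.sigma.copy()
        flipped = async_step(pop, EnvironmentSchedule.static(), 0.0, rng)
        assert int(np.sum(pop.sigma != before)) == (1 if flipped else 0)


class TestRun:
    def test_conformist_consensus_is_absorbing(self, small_ba, rng):
        pop = make_population(small_ba, 10.0, 1.0, CHOICE_A)
        traj = run(pop, EnvironmentSchedule.static(), 100, rng=rng)
        assert np.all(traj.frac_A == 1.0)
        assert traj.equilibrium

    def test_conformity_trap(self):
        """All-A start with zero anticonformists freezes misaligned."""
        rng = np.random.default_rng(21)
        g = generate_ba(300, 20, rng)
        pop = init_population(g, None, HALF_HALF, 1.0, rng=rng)
        traj = run(pop, EnvironmentSchedule.static(), 500, rng=rng)
        assert traj.frac_A[-1] > 0.95
        res = alignment(pop)
        assert 0.45 <= res.global_alignment <= 0.55

    def test_compiled_kernel_agrees_with_reference_step(self):
        """Deterministic regime: kernel and pure-Python step reach the same fix."""
        g = nx.complete_graph(12)
        rng = np.random.default_rng(5)
        pop1 = make_population(g, 10.0, 0.0, CHOICE_B)
        run(pop1, EnvironmentSchedule.static(), 20, rng=rng)
        pop2 = make_population(g, 10.0, 0.0, CHOICE_B)
        for t in range(20 * 12):
            async_step(pop2, EnvironmentSchedule.static(), t / 12, rng)
        assert np.array_equal(pop1.sigma, pop2.sigma)
        assert np.all(pop1.sigma == CHOICE_A)

    def test_fixed_seed_identical_trajectory(self, small_ba):
        outs = []
        for _ in range(2):
            pop = init_population(
                small_ba, None, HALF_HALF, 0.5, rng=np.random.default_rng(9)
            )
            traj = run(
                pop, EnvironmentSchedule.static(), 50, rng=np.random.default_rng(10)
            )
            outs.append(traj)
        assert np.array_equal(outs[0].frac_A, outs[1].frac_A)
        assert np.array_equal(outs[0].final_sigma, outs[1].final_sigma)

    def test_nonconformists_always_align(self, small_ba, rng):
        comp = [Subpop("nA", 10.0, 0.0, 0.5), Subpop("nB", -10.0, 0.0, 0.5)]
        pop = init_population(small_ba, None, comp, 0.0, rng=rng)
        run(pop, EnvironmentSchedule.static(), 200, rng=rng)
        assert alignment(pop).global_alignment == 1.0

    def test_frozen_configurations_match_zero_switch_probability(self):
        """Large-beta frozen set == configurations with no positive switch probability."""
        from dissentnet.core import DecisionParams, marginal_utility, prob_choose_A
        from dissentnet.dynamics import Population

        g = nx.cycle_graph(8)
        delta_o = np.array([3.0, -3.0] * 4)
        w = np.full(8, 2.0)  # conformists, |w * k| > |delta_o|
        params = DecisionParams(beta=1e4)
        frozen_by_threshold = set()
        frozen_by_probability = set()
        for bits in itertools.product([CHOICE_A, CHOICE_B], repeat=8):
            sigma = np.array(bits)
            pop = Population.from_arrays(g, delta_o, w, sigma, params=params)
            stays_threshold = True
            stays_prob = True
            for i in range(8):
                n_a, n_b = pop.neighbor_counts(i)
                du = marginal_utility(pop.agent(i), n_a, n_b)
                if np.sign(du) != sigma[i] or du == 0:
                    stays_threshold = False
                p_other = (
                    1 - prob_choose_A(du, params)
                    if sigma[i] == CHOICE_A
                    else prob_choose_A(du, params)
                )
                if p_other > 1e-9:
                    stays_prob = False
            if stays_threshold:
                frozen_by_threshold.add(bits)
            if stays_prob:
                frozen_by_probability.add(bits)
        assert frozen_by_threshold == frozen_by_probability
        assert len(frozen_by_threshold) > 0


class TestEnsemble:
    def _factory(self, graph, initial=0.5):
        def factory(ss):
            return init_population(
                graph, None, HALF_HALF, initial, rng=np.random.default_rng(ss)
            )

        return factory

    def test_single_realization_median_is_trajectory(self, small_ba):
        ens = run_ensemble(
            self._factory(small_ba), EnvironmentSchedule.static(), 30, 1, seed=4
        )
        assert np.array_equal(ens.median_frac_A(), ens.frac_A[0])

    def test_initial_median_matches_configured_fraction(self, small_ba):
        ens = run_ensemble(
            self._factory(small_ba, 0.3), EnvironmentSchedule.static(), 10, 8, seed=4
        )
        assert abs(ens.median_frac_A()[0] - 0.3) <= 1.0 / 100

    def test_disjoint_seed_lists_differ_bitwise(self, small_ba):
        e1 = run_ensemble(
            self._factory(small_ba), EnvironmentSchedule.static(), 20, 3, seeds=[1, 2, 3]
        )
        e2 = run_ensemble(
            self._factory(small_ba), EnvironmentSchedule.static(), 20, 3, seeds=[4, 5, 6]
        )
        assert not np.array_equal(e1.frac_A, e2.frac_A)

    def test_mirror_symmetry_of_median_curves(self):
        """Negating preferences and initial majority complements the A-fraction."""
        g = generate_ba(200, 10, np.random.default_rng(2))
        comp_mirror = [
            Subpop("pref_A", -10.0, 1.0, 0.5),
            Subpop("pref_B", 10.0, 1.0, 0.5),
        ]

        def factory(comp, x0):
            def f(ss):
                return init_population(g, None, comp, x0, rng=np.random.default_rng(ss))

            return f

        e1 = run_ensemble(
            factory(HALF_HALF, 0.8), EnvironmentSchedule.static(), 150, 15, seed=6
        )
        e2 = run_ensemble(
            factory(comp_mirror, 0.2), EnvironmentSchedule.static(), 150, 15, seed=60
        )
        diff = np.abs(e1.median_frac_A() - (1.0 - e2.median_frac_A()))
        assert diff.max() < 0.12  # Monte-Carlo error at 15 realizations


class TestSchedules:
    def test_linear_zero_crossing(self):
        s = EnvironmentSchedule.linear(10.0, 0.1)
        assert s.zero_crossing() == pytest.approx(100.0)
        assert s.value(0) == 10.0
        assert s.value(200) == -10.0

    def test_sinusoidal_crossings_alternate(self):
        s = EnvironmentSchedule.sinusoidal(10.0, 200.0)
        cr = s.zero_crossings(500)
        assert [round(t) for t, _ in cr] == [100, 200, 300, 400, 500]
        assert [d for _, d in cr] == [-1, 1, -1, 1, -1]

    def test_static_value_is_nan(self):
        assert np.isnan(EnvironmentSchedule.static().value(3.0))
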