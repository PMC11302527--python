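"""Outcome statistics on constructed states and trajectories."""

import networkx as nx
import numpy as np
import pytest

from dissentnet.core import CHOICE_A, CHOICE_B
from dissentnet.dynamics import EnvironmentSchedule, Trajectory
from dissentnet.metrics import (
    alignment,
    alignment_trajectory,
    changers_fraction,
    lead_time,
    tipping_time,
    tracking_alignment,
    volatility,
    welfare,
)

from conftest import make_population


def make_trajectory(
    times,
    frac_A,
    schedule=None,
    n_agents=100,
    cum_flips=None,
    subpop_frac_A=None,
    subpop_names=None,
    subpop_sizes=None,
    subpop_delta_o=None,
    agent_flips=None,
    snapshot_flips=None,
):
    times = np.asarray(times, float)
    frac_A = np.asarray(frac_A, float)
    if subpop_names is None:
        subpop_names = ["all"]
        subpop_frac_A = frac_A[:, None]
        subpop_sizes = np.array([n_agents])
        subpop_delta_o = np.array([10.0])
    schedule = schedule or EnvironmentSchedule.static()
    delta_o_t = np.array([schedule.value(t) for t in times])
    return Trajectory(
        times=times,
        frac_A=frac_A,
        subpop_frac_A=np.asarray(subpop_frac_A, float),
        delta_o_t=delta_o_t,
        cum_flips=np.zeros_like(times, int) if cum_flips is None else np.asarray(cum_flips),
        agent_flips=np.zeros(n_agents, int) if agent_flips is None else agent_flips,
        snapshot_flips=np.zeros(n_agents, int) if snapshot_flips is None else snapshot_flips,
        snapshot_sweep=0,
        final_sigma=np.full(n_agents, CHOICE_A),
        subpop_names=list(subpop_names),
        subpop_sizes=np.asarray(subpop_sizes),
        subpop_delta_o=np.asarray(subpop_delta_o, float),
        schedule=schedule,
        n_agents=n_agents,
        equilibrium=True,
        sweeps_run=int(times[-1]),
    )


class TestAlignment:
    def test_full_match_is_one(self):
        pop = make_population(nx.path_graph(6), [10, -10, 10, -10, 10, -10], 1.0,
                              [1, -1, 1, -1, 1, -1])
        assert alignment(pop).global_alignment == 1.0

    def test_consensus_with_split_preferences_is_half(self):
        pop = make_population(nx.path_graph(6), [10, -10, 10, -10, 10, -10], 1.0, CHOICE_A)
        assert alignment(pop).global_alignment == 0.5

    def test_mirrored_population_identical_alignment(self, rng):
        d = rng.choice([-10.0, 10.0], 50)
        s = rng.choice([CHOICE_A, CHOICE_B], 50)
        g = nx.gnp_random_graph(50, 0.2, seed=4)
        a1 = alignment(make_population(g, d, 1.0, s)).global_alignment
        a2 = alignment(make_population(g, -d, 1.0, -s)).global_alignment
        assert a1 == a2

    def test_zero_preference_agents_excluded_and_counted(self):
        pop = make_population(nx.path_graph(4), [0.0, 0.0, 10.0, -10.0], 1.0, CHOICE_A)
        res = alignment(pop)
        assert res.n_excluded == 2
        assert res.global_alignment == 0.5

    def test_all_zero_preferences_error(self):
        pop = make_population(nx.path_graph(3), 0.0, 1.0, CHOICE_A)
        with pytest.raises(ValueError):
            alignment(pop)

    def test_trajectory_window_matches_final_state(self):
        """A frozen trajectory's last-window alignment equals the state alignment."""
        traj = make_trajectory(
            [0, 10, 20],
            [1.0, 0.6, 0.6],
            subpop_names=["pA", "pB"],
            subpop_frac_A=[[1, 1], [0.8, 0.4], [0.8, 0.4]],
            subpop_sizes=[50, 50],
            subpop_delta_o=[10.0, -10.0],
        )
        res = alignment_trajectory(traj, window=(20, 20))
        assert res.global_alignment == pytest.approx(0.5 * 0.8 + 0.5 * 0.6)
        assert res.per_subpop["pB"] == pytest.approx(0.6)

    def test_trajectory_rejects_shared_schedule(self):
        traj = make_trajectory([0, 1], [1.0, 1.0], EnvironmentSchedule.linear())
        with pytest.raises(ValueError):
            alignment_trajectory(traj)


class TestVolatility:
    def test_frozen_trajectory_zero(self):
        traj = make_trajectory([0, 50, 100, 150], [1, 1, 1, 1], cum_flips=[0, 5, 5, 5])
        assert volatility(traj, burn_in_sweeps=50) == 0.0

    def test_one_flip_per_sweep_counts(self):
        traj = make_trajectory(
            [0, 100, 200], [1, 1, 1], n_agents=100, cum_flips=[0, 100, 200]
        )
        assert volatility(traj, burn_in_sweeps=100) == pytest.approx(1.0 / 100)

    def test_burn_in_past_end_rejected(self):
        traj = make_trajectory([0, 10], [1, 1])
        with pytest.raises(ValueError):
            volatility(traj, burn_in_sweeps=10)

    def test_changers_fraction_counts_individuals(self):
        agent_flips = np.zeros(100, int)
        agent_flips[:30] = 5
        snapshot = np.zeros(100, int)
        snapshot[:10] = 5  # ten agents did all their flipping before burn-in
        traj = make_trajectory(
            [0, 100], [1, 1], agent_flips=agent_flips, snapshot_flips=snapshot
        )
        assert changers_fraction(traj) == pytest.approx(0.2)


class TestTipping:
    SCHED = EnvironmentSchedule.linear(10.0, 0.1)  # crosses zero at t=100

    def test_never_tipped_sentinel(self):
        traj = make_trajectory(np.arange(0, 201, 10), np.ones(21), self.SCHED)
        res = tipping_time(traj, self.SCHED)
        assert not res.tipped and res.tipping_time is None and res.lag is None

    def test_lag_is_first_threshold_crossing_minus_zero_crossing(self):
        times = np.arange(0, 201, 10.0)
        frac = np.where(times < 150, 1.0, 0.2)
        res = tipping_time(make_trajectory(times, frac, self.SCHED), self.SCHED)
        assert res.tipped and res.tipping_time == 150 and res.lag == pytest.approx(50)

    def test_nonmonotone_schedule_requires_explicit_crossing(self):
        traj = make_trajectory([0, 10], [1, 0], EnvironmentSchedule.sinusoidal())
        with pytest.raises(ValueError):
            tipping_time(traj, EnvironmentSchedule.sinusoidal())
        res = tipping_time(traj, crossing_time=5.0)
        assert res.tipped


class TestLeadTime:
    SCHED = EnvironmentSchedule.sinusoidal(10.0, 200.0)

    def test_switch_exactly_at_crossings_gives_zero_lead(self):
        times = np.arange(0, 601.0)
        # follows sign(delta_o) instantaneously
        frac = (np.array([self.SCHED.value(t) for t in times]) > 0).astype(float)
        frac[0] = 1.0
        lead = lead_time(make_trajectory(times, frac, self.SCHED), self.SCHED)
        assert abs(lead) <= 1.0

    def test_early_switcher_has_negative_lead(self):
        times = np.arange(0, 601.0)
        frac = (np.array([self.SCHED.value(t + 30) for t in times]) > 0).astype(float)
        lead = lead_time(make_trajectory(times, frac, self.SCHED), self.SCHED)
        assert lead == pytest.approx(-30, abs=1.5)

    def test_incomplete_half_cycle_rejected(self):
        times = np.arange(0, 50.0)
        traj = make_trajectory(times, np.ones_like(times), self.SCHED)
        with pytest.raises(ValueError):
            lead_time(traj, self.SCHED)

    def test_tracking_alignment_perfect_follower(self):
        times = np.arange(0, 601.0)
        frac = (np.array([self.SCHED.value(t) for t in times]) > 0).astype(float)
        traj = make_trajectory(times, frac, self.SCHED)
        assert tracking_alignment(traj) > 0.99


class TestWelfare:
    def test_full_alignment_preference_utility(self):
        pop = make_population(
            nx.empty_graph(4), [10, 10, -10, -10], 1.0, [1, 1, -1, -1]
        )
        res = welfare(pop)
        assert res.preference_utility == pytest.approx(5.0)
        assert res.total == res.preference_utility + res.social_utility

    def test_conformist_consensus_maximizes_social_utility(self, rng):
        g = nx.complete_graph(10)
        consensus = welfare(make_population(g, 0.0, 1.0, CHOICE_A)).social_utility
        for _ in range(10):
            s = rng.choice([CHOICE_A, CHOICE_B], 10)
            if np.all(s == s[0]):
                continue
            assert welfare(make_population(g, 0.0, 1.0, s)).social_utility < consensus

    def test_preference_utility_affine_in_alignment(self):
        # constant |delta_o|: pref utility = |delta_o| (2 * alignment - 1) / 2
        g = nx.empty_graph(10)
        d = np.array([10.0] * 5 + [-10.0] * 5)
        for n_aligned in [0, 3, 7, 10]:
            s = np.where(np.arange(10) < n_aligned, np.sign(d), -np.sign(d)).astype(int)
            pop = make_population(g, d, 1.0, s)
            a = alignment(pop).global_alignment
            assert welfare(pop).preference_utility == pytest.approx(10.0 * (2 * a - 1) / 2)
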