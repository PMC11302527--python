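"""Outcome statistics: alignment, volatility, tipping and lead times, welfare.

Alignment is the fraction of agents whose choice matches the sign of
their net preference (A for delta_o > 0); agents with delta_o = 0 have
no defined preference and are excluded (their count is reported).
Volatility is the post-burn-in rate of choice changes per agent per
sweep, a proximity signal for the critical point.  Tipping and lead
times compare population switches against the environment's
zero-crossings in dynamic scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dissentnet.core import CHOICE_A
from dissentnet.dynamics import EnvironmentSchedule, Population, Trajectory


@dataclass
class AlignmentResult:
    """Choice-preference alignment, globally and per subpopulation."""

    global_alignment: float
    per_subpop: dict[str, float]
    n_excluded: int


def alignment(pop: Population) -> AlignmentResult:
    """Alignment of the population's current state with its preferences."""
    mask = pop.delta_o != 0
    n_excluded = int(np.count_nonzero(~mask))
    if not mask.any():
        raise ValueError("alignment undefined: every agent has delta_o = 0")
    match = np.sign(pop.delta_o) == pop.sigma
    per = {}
    for s, name in enumerate(pop.subpop_names):
        m = (pop.subpop_ids == s) & mask
        per[name] = float(match[m].mean()) if m.any() else float("nan")
    return AlignmentResult(
        global_alignment=float(match[mask].mean()),
        per_subpop=per,
        n_excluded=n_excluded,
    )


def alignment_trajectory(
    traj: Trajectory, window: tuple[float, float] | None = None
) -> AlignmentResult:
    """Alignment averaged over a trajectory window (static environments).

    Subpopulations are homogeneous in preference, so the aligned
    fraction of each is its A-fraction (delta_o > 0) or B-fraction
    (delta_o < 0), averaged over the records in ``window`` (default:
    the final 10 sweeps recorded).
    """
    if traj.schedule.shared:
        raise ValueError(
            "trajectory alignment needs per-agent static preferences; "
            "use tracking_alignment for shared dynamic environments"
        )
    if window is None:
        window = (traj.times[-1] - 10.0, traj.times[-1])
    t0, t1 = window
    rows = (traj.times >= t0) & (traj.times <= t1)
    if not rows.any():
        raise ValueError(f"no records in window [{t0}, {t1}]")
    per = {}
    num = 0.0
    den = 0
    n_excluded = 0
    for s, name in enumerate(traj.subpop_names):
        d_o = traj.subpop_delta_o[s]
        size = int(traj.subpop_sizes[s])
        if d_o == 0:
            per[name] = float("nan")
            n_excluded += size
            continue
        frac_a = traj.subpop_frac_A[rows, s].mean()
        aligned = frac_a if d_o > 0 else 1.0 - frac_a
        per[name] = float(aligned)
        num += aligned * size
        den += size
    if den == 0:
        raise ValueError("alignment undefined: every agent has delta_o = 0")
    return AlignmentResult(global_alignment=num / den, per_subpop=per, n_excluded=n_excluded)


def tracking_alignment(
    traj: Trajectory, subpop: str | None = None, burn_in: float = 0.0
) -> float:
    """Mean alignment with the shared time-varying preference sign.

    At each recorded time with delta_o(t) != 0 the aligned fraction is
    the A-fraction when delta_o(t) > 0 and the B-fraction otherwise;
    the average over records after ``burn_in`` is returned.
    """
    if not traj.schedule.shared:
        raise ValueError("tracking_alignment requires a shared dynamic schedule")
    series = (
        traj.frac_A if subpop is None else traj.subpop_frac_A[:, traj.subpop_index(subpop)]
    )
    rows = (traj.times >= burn_in) & (traj.delta_o_t != 0)
    if not rows.any():
        raise ValueError("no usable records after burn_in")
    aligned = np.where(traj.delta_o_t[rows] > 0, series[rows], 1.0 - series[rows])
    return float(aligned.mean())


def volatility(traj: Trajectory, burn_in_sweeps: float = 100.0) -> float:
    """Choice changes per agent per sweep after the burn-in period."""
    t_end = traj.times[-1]
    if burn_in_sweeps >= t_end:
        raise ValueError(
            f"burn_in ({burn_in_sweeps}) must precede the trajectory end ({t_end})"
        )
    pos = int(np.searchsorted(traj.times, burn_in_sweeps, side="right") - 1)
    flips = traj.cum_flips[-1] - traj.cum_flips[pos]
    elapsed = t_end - traj.times[pos]
    return float(flips / (traj.n_agents * elapsed))


def changers_fraction(traj: Trajectory) -> float:
    """Fraction of individuals who changed their choice after the burn-in.

    Counts agents with at least one flip after the trajectory's
    snapshot sweep (the burn-in mark set when the run was launched);
    an alternative volatility measure expressed in individuals rather
    than flip rate.
    """
    if traj.snapshot_sweep < 0 or traj.snapshot_sweep > traj.sweeps_run:
        raise ValueError("trajectory has no burn-in snapshot inside the run")
    return float(np.mean(traj.agent_flips - traj.snapshot_flips > 0))


@dataclass
class TippingResult:
    """Environment crossing vs. population majority switch (linear schedules)."""

    crossing_time: float
    tipping_time: float | None  # first time the B-fraction exceeds the threshold
    lag: float | None  # tipping_time - crossing_time, when both exist
    tipped: bool


def tipping_time(
    traj: Trajectory,
    schedule: EnvironmentSchedule | None = None,
    threshold: float = 0.5,
    crossing_time: float | None = None,
) -> TippingResult:
    """Cultural lag between the environment flip and the social tip.

    The crossing time comes from a linear schedule (or is supplied
    explicitly); the tipping time is the first record where the global
    B-fraction reaches ``threshold``.
    """
    if crossing_time is None:
        if schedule is None:
            schedule = traj.schedule
        crossing_time = schedule.zero_crossing()
    frac_b = 1.0 - traj.frac_A
    hits = np.flatnonzero(frac_b >= threshold)
    if hits.size == 0:
        return TippingResult(crossing_time, None, None, False)
    tip = float(traj.times[hits[0]])
    lag = tip - crossing_time if crossing_time <= traj.times[-1] else None
    return TippingResult(crossing_time, tip, lag, True)


def _series_crossings(times: np.ndarray, series: np.ndarray) -> list[tuple[float, int]]:
    """(time, direction) crossings of a series through 0.5, linearly interpolated."""
    out = []
    above = series >= 0.5
    for i in range(1, len(series)):
        if above[i] == above[i - 1]:
            continue
        y0, y1 = series[i - 1], series[i]
        t = times[i - 1] + (0.5 - y0) / (y1 - y0) * (times[i] - times[i - 1])
        out.append((float(t), 1 if y1 > y0 else -1))
    return out


def lead_time(
    traj: Trajectory, schedule: EnvironmentSchedule | None = None, subpop: str | None = None
) -> float:
    """Signed time by which a subpopulation's majority switch leads the environment.

    For each zero-crossing of a sinusoidal schedule with a complete
    half-cycle of data, the nearest majority switch of the
    subpopulation in the same direction (within half a period) is
    matched; the mean of (switch time - crossing time) is returned.
    Negative values mean the group switches before the environment
    does.
    """
    if schedule is None:
        schedule = traj.schedule
    if schedule.kind != "sinusoidal":
        raise ValueError("lead_time requires a sinusoidal schedule")
    horizon = float(traj.times[-1])
    half = schedule.period / 2.0
    crossings = [
        (t, d) for (t, d) in schedule.zero_crossings(horizon) if t + half <= horizon
    ]
    if not crossings:
        raise ValueError("horizon contains no complete half-cycle")
    series = (
        traj.frac_A if subpop is None else traj.subpop_frac_A[:, traj.subpop_index(subpop)]
    )
    switches = _series_crossings(traj.times, series)
    leads = []
    for c, d in crossings:
        candidates = [t for (t, sd) in switches if sd == d and abs(t - c) <= half]
        if candidates:
            best = min(candidates, key=lambda t: abs(t - c))
            leads.append(best - c)
    if not leads:
        return float("nan")
    return float(np.mean(leads))


@dataclass
class WelfareResult:
    """Decomposed mean utility of the current configuration.

    These are package-local definitions: with spins sigma_i in {+1,-1},
    the preference term is mean_i sigma_i * delta_o_i / 2 and the social
    term is mean_i (w_i / 2) * sum_{j in N(i)} sigma_i sigma_j; the
    total is their sum exactly.
    """

    preference_utility: float
    social_utility: float
    total: float


def welfare(pop: Population) -> WelfareResult:
    sigma = pop.sigma.astype(np.float64)
    pref = float(np.mean(sigma * pop.delta_o / 2.0))
    # sum_j sigma_j over neighbors via the CSR adjacency
    src = np.repeat(np.arange(pop.n), np.diff(pop.indptr))
    neigh_sum = np.bincount(src, weights=sigma[pop.indices], minlength=pop.n)
    social = float(np.mean(pop.w / 2.0 * sigma * neigh_sum))
    return WelfareResult(pref, social, pref + social)


def spin_to_choice_fraction(sigma: np.ndarray) -> float:
    """Fraction of agents on A for a spin array."""
    return float(np.mean(sigma == CHOICE_A))
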