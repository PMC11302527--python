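"""Asynchronous simulation engine on networked populations.

Time is measured in sweeps: one sweep = N single-agent updates, each
picking a uniformly random agent that resamples its choice from the
Fermi rule given its current neighborhood tally and the (possibly
time-varying) net preference.  This asynchronous scheme mimics
continuous time and is N-independent when expressed in sweeps.

The hot loop is compiled with numba; a pure-Python single step
(:func:`async_step`) is provided both as the reference semantics and
for small-scale exact checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit

from dissentnet.core import CHOICE_A, CHOICE_B, AgentState, DecisionParams, sample_choice

_KIND_STATIC = 0  # per-agent fixed delta_o
_KIND_CONSTANT = 1  # shared fixed delta_o
_KIND_LINEAR = 2
_KIND_SINUSOIDAL = 3

_KIND_CODES = {
    "static": _KIND_STATIC,
    "constant": _KIND_CONSTANT,
    "linear": _KIND_LINEAR,
    "sinusoidal": _KIND_SINUSOIDAL,
}


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Deterministic map from time (sweeps) to the net preference.

    Kinds
    -----
    static
        Each agent keeps its own fixed ``delta_o`` (heterogeneous,
        constant environment).
    constant
        A shared fixed value ``delta_o0`` for every agent.
    linear
        Shared ``delta_o(t) = delta_o0 - rate * t`` (e.g. a falling cost
        of the alternative); crosses zero at ``delta_o0 / rate``.
    sinusoidal
        Shared ``delta_o(t) = amplitude * sin(2 pi t / period + phase)``.
    """

    kind: str = "static"
    delta_o0: float = 10.0
    rate: float = 0.1
    amplitude: float = 10.0
    period: float = 200.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODES:
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "sinusoidal" and self.period <= 0:
            raise ValueError("period must be positive")

    # -- constructors -------------------------------------------------
    @staticmethod
    def static() -> "EnvironmentSchedule":
        return EnvironmentSchedule(kind="static")

    @staticmethod
    def constant(delta_o0: float) -> "EnvironmentSchedule":
        return EnvironmentSchedule(kind="constant", delta_o0=delta_o0)

    @staticmethod
    def linear(delta_o0: float = 10.0, rate: float = 0.1) -> "EnvironmentSchedule":
        return EnvironmentSchedule(kind="linear", delta_o0=delta_o0, rate=rate)

    @staticmethod
    def sinusoidal(
        amplitude: float = 10.0, period: float = 200.0, phase: float = 0.0
    ) -> "EnvironmentSchedule":
        return EnvironmentSchedule(
            kind="sinusoidal", amplitude=amplitude, period=period, phase=phase
        )

    # -- queries ------------------------------------------------------
    @property
    def shared(self) -> bool:
        """True when all agents see the same time-varying preference."""
        return self.kind != "static"

    def value(self, t: float) -> float:
        """Shared net preference at time t (NaN for the static kind)."""
        if self.kind == "static":
            return float("nan")
        if self.kind == "constant":
            return self.delta_o0
        if self.kind == "linear":
            return self.delta_o0 - self.rate * t
        return self.amplitude * math.sin(2 * math.pi * t / self.period + self.phase)

    def zero_crossing(self) -> float:
        """Zero-crossing time of a linear schedule."""
        if self.kind != "linear":
            raise ValueError("zero_crossing is defined for linear schedules")
        if self.rate <= 0:
            raise ValueError("linear schedule with rate <= 0 never crosses zero")
        return self.delta_o0 / self.rate

    def zero_crossings(self, horizon: float) -> list[tuple[float, int]]:
        """(time, direction) zero crossings in (0, horizon].

        Direction +1 means delta_o turns positive (A becomes preferred),
        -1 means it turns negative.
        """
        if self.kind == "linear":
            t0 = self.zero_crossing()
            return [(t0, -1)] if 0 < t0 <= horizon else []
        if self.kind != "sinusoidal":
            return []
        out = []
        k = math.ceil(self.phase / math.pi - 1e-12)
        while True:
            t = (k * math.pi - self.phase) * self.period / (2 * math.pi)
            if t > horizon:
                break
            if t > 1e-12:
                direction = 1 if math.cos(k * math.pi) * self.amplitude > 0 else -1
                out.append((t, direction))
            k += 1
        return out

    def _kernel_args(self) -> tuple[int, float, float, float]:
        code = _KIND_CODES[self.kind]
        if self.kind == "sinusoidal":
            return code, self.amplitude, self.period, self.phase
        if self.kind == "linear":
            return code, self.delta_o0, self.rate, 0.0
        return code, self.delta_o0, 0.0, 0.0


@dataclass
class Subpop:
    """A homogeneous subpopulation: shared preference and conformity weight.

    ``placed`` marks subpopulations whose members must sit on the nodes
    flagged by the placement indicator (degree-correlated placement);
    by default this is the anticonformist subpopulations (w < 0).
    """

    name: str
    delta_o: float
    w: float
    fraction: float
    placed: bool | None = None

    def __post_init__(self) -> None:
        if self.placed is None:
            self.placed = self.w < 0


@dataclass
class Population:
    """Undirected simple graph plus per-node agent state (array form)."""

    graph: nx.Graph
    indptr: np.ndarray
    indices: np.ndarray
    delta_o: np.ndarray
    w: np.ndarray
    sigma: np.ndarray  # spin choices, +1 = A
    subpop_ids: np.ndarray
    subpop_names: list[str]
    params: DecisionParams = field(default_factory=DecisionParams)

    @property
    def n(self) -> int:
        return self.sigma.size

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    @property
    def frac_A(self) -> float:
        return float(np.mean(self.sigma == CHOICE_A))

    def subpop_sizes(self) -> np.ndarray:
        return np.bincount(self.subpop_ids, minlength=len(self.subpop_names))

    def neighbor_counts(self, i: int) -> tuple[int, int]:
        """(n_A, n_B) among node i's neighbors."""
        neigh = self.indices[self.indptr[i] : self.indptr[i + 1]]
        n_a = int(np.count_nonzero(self.sigma[neigh] == CHOICE_A))
        return n_a, neigh.size - n_a

    def agent(self, i: int) -> AgentState:
        return AgentState(
            delta_o=float(self.delta_o[i]), w=float(self.w[i]), choice=int(self.sigma[i])
        )

    @staticmethod
    def from_arrays(
        graph: nx.Graph,
        delta_o: np.ndarray,
        w: np.ndarray,
        sigma: np.ndarray,
        subpop_ids: np.ndarray | None = None,
        subpop_names: list[str] | None = None,
        params: DecisionParams | None = None,
    ) -> "Population":
        n = graph.number_of_nodes()
        adj = nx.to_scipy_sparse_array(graph, nodelist=range(n), format="csr")
        if subpop_ids is None:
            subpop_ids = np.zeros(n, dtype=np.int64)
            subpop_names = subpop_names or ["all"]
        for name, arr in (("delta_o", delta_o), ("w", w), ("sigma", sigma)):
            if len(arr) != n:
                raise ValueError(f"{name} must have one entry per node")
        return Population(
            graph=graph,
            indptr=adj.indptr.astype(np.int64),
            indices=adj.indices.astype(np.int64),
            delta_o=np.asarray(delta_o, dtype=np.float64).copy(),
            w=np.asarray(w, dtype=np.float64).copy(),
            sigma=np.asarray(sigma, dtype=np.int64).copy(),
            subpop_ids=np.asarray(subpop_ids, dtype=np.int64),
            subpop_names=list(subpop_names or []),
            params=params or DecisionParams(),
        )


def _allocate_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to `total`, largest-remainder rounding."""
    ideal = fractions / fractions.sum() * total
    counts = np.floor(ideal).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(ideal - counts))
    counts[order[:rem]] += 1
    return counts


def init_population(
    net: nx.Graph,
    assignment: np.ndarray | None,
    composition: list[Subpop],
    initial_fraction_A: float = 0.5,
    init_mode: str = "random",
    params: DecisionParams | None = None,
    rng: np.random.Generator | None = None,
) -> Population:
    """Assign subpopulations and initial choices on a network.

    Subpopulations with ``placed=True`` (by default the anticonformists)
    are distributed over the nodes flagged in ``assignment``; the rest
    fill the remaining nodes, both uniformly at random.  Choices are
    drawn without replacement so the realized initial A-count equals
    ``round(initial_fraction_A * N)`` globally (``init_mode="random"``)
    or per subpopulation (``init_mode="by-subpopulation"``).
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0.0 <= initial_fraction_A <= 1.0:
        raise ValueError("initial_fraction_A must be in [0, 1]")
    if init_mode not in ("random", "by-subpopulation"):
        raise ValueError(f"unknown init_mode {init_mode!r}")
    fracs = np.array([s.fraction for s in composition], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-8:
        raise ValueError(f"composition fractions must sum to 1, got {fracs.sum()}")
    n = net.number_of_nodes()
    if assignment is None:
        assignment = np.zeros(n, dtype=bool)
    assignment = np.asarray(assignment, dtype=bool)
    if assignment.size != n:
        raise ValueError("assignment must cover all nodes")

    placed_idx = [i for i, s in enumerate(composition) if s.placed]
    other_idx = [i for i, s in enumerate(composition) if not s.placed]
    n_flagged = int(assignment.sum())
    placed_frac = fracs[placed_idx].sum() if placed_idx else 0.0
    if abs(placed_frac * n - n_flagged) > 1.5:
        raise ValueError(
            f"placement indicator marks {n_flagged} nodes but placed subpopulations "
            f"sum to fraction {placed_frac:.4f} of N={n}"
        )
    if placed_idx and n_flagged == 0 and placed_frac > 0:
        raise ValueError("placed subpopulations present but indicator is empty")

    subpop_ids = np.empty(n, dtype=np.int64)
    flagged_nodes = rng.permutation(np.flatnonzero(assignment))
    free_nodes = rng.permutation(np.flatnonzero(~assignment))
    if placed_idx:
        counts = _allocate_counts(fracs[placed_idx], n_flagged)
        pos = 0
        for idx, c in zip(placed_idx, counts):
            subpop_ids[flagged_nodes[pos : pos + c]] = idx
            pos += c
    if other_idx:
        counts = _allocate_counts(fracs[other_idx], n - n_flagged)
        pos = 0
        for idx, c in zip(other_idx, counts):
            subpop_ids[free_nodes[pos : pos + c]] = idx
            pos += c

    delta_o = np.array([composition[i].delta_o for i in subpop_ids])
    w = np.array([composition[i].w for i in subpop_ids])

    sigma = np.full(n, CHOICE_B, dtype=np.int64)
    if init_mode == "random":
        n_a = int(round(initial_fraction_A * n))
        sigma[rng.choice(n, size=n_a, replace=False)] = CHOICE_A
    else:
        for idx in range(len(composition)):
            members = np.flatnonzero(subpop_ids == idx)
            n_a = int(round(initial_fraction_A * members.size))
            sigma[rng.choice(members, size=n_a, replace=False)] = CHOICE_A

    return Population.from_arrays(
        net,
        delta_o,
        w,
        sigma,
        subpop_ids,
        [s.name for s in composition],
        params or DecisionParams(),
    )


# ---------------------------------------------------------------------------
# single-step reference semantics


def async_step(
    pop: Population,
    schedule: EnvironmentSchedule,
    t: float,
    rng: np.random.Generator,
) -> bool:
    """One asynchronous update: a random agent resamples its choice.

    Mutates ``pop`` in place; returns True when the chosen agent's
    choice changed.  This is the reference (pure Python) semantics of
    the compiled sweep loop.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    i = int(rng.integers(0, pop.n))
    n_a, n_b = pop.neighbor_counts(i)
    d_o = pop.delta_o[i] if not schedule.shared else schedule.value(t)
    agent = AgentState(delta_o=float(d_o), w=float(pop.w[i]), choice=int(pop.sigma[i]))
    new = sample_choice(agent, n_a, n_b, pop.params, rng)
    flipped = new != pop.sigma[i]
    pop.sigma[i] = new
    return flipped


# ---------------------------------------------------------------------------
# compiled sweep engine


@njit(cache=True)
def _simulate_kernel(
    indptr,
    indices,
    sigma,
    delta_o,
    w,
    subpop_ids,
    n_subpops,
    beta,
    kind,
    p0,
    p1,
    p2,
    n_sweeps,
    record_every,
    freeze_sweeps,
    snapshot_sweep,
    gen,
):
    n = sigma.size
    deg = np.empty(n, np.int64)
    n_a = np.zeros(n, np.int64)
    for i in range(n):
        deg[i] = indptr[i + 1] - indptr[i]
        c = 0
        for jj in range(indptr[i], indptr[i + 1]):
            if sigma[indices[jj]] == 1:
                c += 1
        n_a[i] = c
    count_a = 0
    sub_a = np.zeros(n_subpops, np.int64)
    sub_n = np.zeros(n_subpops, np.int64)
    for i in range(n):
        sub_n[subpop_ids[i]] += 1
        if sigma[i] == 1:
            count_a += 1
            sub_a[subpop_ids[i]] += 1

    max_rec = n_sweeps // record_every + 2
    rec_t = np.empty(max_rec, np.float64)
    rec_frac = np.empty(max_rec, np.float64)
    rec_sub = np.empty((max_rec, n_subpops), np.float64)
    rec_sched = np.empty(max_rec, np.float64)
    rec_flips = np.empty(max_rec, np.int64)
    agent_flips = np.zeros(n, np.int64)
    snapshot_flips = np.zeros(n, np.int64)

    def _sched(tt):
        if kind == 0:
            return np.nan
        if kind == 1:
            return p0
        if kind == 2:
            return p0 - p1 * tt
        return p0 * np.sin(2.0 * np.pi * tt / p1 + p2)

    nrec = 0
    rec_t[nrec] = 0.0
    rec_frac[nrec] = count_a / n
    for s in range(n_subpops):
        rec_sub[nrec, s] = sub_a[s] / sub_n[s] if sub_n[s] > 0 else np.nan
    rec_sched[nrec] = _sched(0.0)
    rec_flips[nrec] = 0
    nrec += 1

    total_flips = 0
    frozen = False
    freeze_count = 0
    sweeps_done = 0
    for sweep in range(n_sweeps):
        flips_this = 0
        for step in range(n):
            t = sweep + step / n
            i = gen.integers(0, n)
            if kind == 0:
                dv = delta_o[i]
            else:
                dv = _sched(t)
            du = dv + w[i] * (2 * n_a[i] - deg[i])
            z = beta * du
            if z > 36.0:
                p = 1.0
            elif z < -36.0:
                p = 0.0
            else:
                p = 1.0 / (1.0 + np.exp(-z))
            new = 1 if gen.random() < p else -1
            if new != sigma[i]:
                sigma[i] = new
                d = 1 if new == 1 else -1
                count_a += d
                sub_a[subpop_ids[i]] += d
                for jj in range(indptr[i], indptr[i + 1]):
                    n_a[indices[jj]] += d
                flips_this += 1
                agent_flips[i] += 1
                total_flips += 1
        sweeps_done = sweep + 1
        if sweep + 1 == snapshot_sweep:
            snapshot_flips[:] = agent_flips
        if (sweep + 1) % record_every == 0:
            rec_t[nrec] = sweep + 1.0
            rec_frac[nrec] = count_a / n
            for s in range(n_subpops):
                rec_sub[nrec, s] = sub_a[s] / sub_n[s] if sub_n[s] > 0 else np.nan
            rec_sched[nrec] = _sched(sweep + 1.0)
            rec_flips[nrec] = total_flips
            nrec += 1
        if kind <= 1 and freeze_sweeps > 0:
            if flips_this == 0:
                freeze_count += 1
                if freeze_count >= freeze_sweeps:
                    frozen = True
                    break
            else:
                freeze_count = 0
    if rec_t[nrec - 1] != sweeps_done:
        rec_t[nrec] = float(sweeps_done)
        rec_frac[nrec] = count_a / n
        for s in range(n_subpops):
            rec_sub[nrec, s] = sub_a[s] / sub_n[s] if sub_n[s] > 0 else np.nan
        rec_sched[nrec] = _sched(float(sweeps_done))
        rec_flips[nrec] = total_flips
        nrec += 1
    return (
        nrec,
        rec_t,
        rec_frac,
        rec_sub,
        rec_sched,
        rec_flips,
        agent_flips,
        snapshot_flips,
        frozen,
        sweeps_done,
    )


@dataclass
class Trajectory:
    """Time-indexed record of a single realization.

    Sampling times are in sweeps; fractions are of agents choosing A.
    ``cum_flips`` is the cumulative number of choice changes up to each
    record; ``equilibrium`` flags early stop by the quasi-equilibrium
    criterion (no flips for ``freeze_sweeps`` consecutive sweeps, only
    applied to constant environments).
    """

    times: np.ndarray
    frac_A: np.ndarray
    subpop_frac_A: np.ndarray
    delta_o_t: np.ndarray
    cum_flips: np.ndarray
    agent_flips: np.ndarray
    snapshot_flips: np.ndarray
    snapshot_sweep: int
    final_sigma: np.ndarray
    subpop_names: list[str]
    subpop_sizes: np.ndarray
    subpop_delta_o: np.ndarray
    schedule: EnvironmentSchedule
    n_agents: int
    equilibrium: bool
    sweeps_run: int

    def subpop_index(self, name: str) -> int:
        return self.subpop_names.index(name)

    def frac_A_at(self, grid: np.ndarray, subpop: str | None = None) -> np.ndarray:
        """Step-function sample of the A-fraction on an arbitrary time grid.

        Beyond the recorded horizon the last value is carried forward
        (frozen trajectories remain at their final state).
        """
        series = (
            self.frac_A
            if subpop is None
            else self.subpop_frac_A[:, self.subpop_index(subpop)]
        )
        pos = np.searchsorted(self.times, np.asarray(grid, dtype=float), side="right") - 1
        return series[np.clip(pos, 0, series.size - 1)]


def run(
    pop: Population,
    schedule: EnvironmentSchedule,
    horizon_sweeps: int,
    record_every: int = 1,
    rng: np.random.Generator | None = None,
    freeze_sweeps: int = 50,
    snapshot_sweep: int = 0,
) -> Trajectory:
    """Simulate ``horizon_sweeps`` sweeps of asynchronous updates.

    For constant environments (kinds ``static`` and ``constant``) the
    run stops early once no agent has flipped for ``freeze_sweeps``
    consecutive sweeps (quasi-equilibrium); pass ``freeze_sweeps=0`` to
    disable.  ``snapshot_sweep`` marks the end of a burn-in period at
    which per-agent flip counts are snapshotted (for the
    individuals-changing volatility measure).  ``pop.sigma`` is updated
    in place.
    """
    if horizon_sweeps < 1:
        raise ValueError("horizon_sweeps must be >= 1")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    kind, p0, p1, p2 = schedule._kernel_args()
    n_subpops = max(1, len(pop.subpop_names))
    (
        nrec,
        rec_t,
        rec_frac,
        rec_sub,
        rec_sched,
        rec_flips,
        agent_flips,
        snapshot_flips,
        frozen,
        sweeps_done,
    ) = _simulate_kernel(
        pop.indptr,
        pop.indices,
        pop.sigma,
        pop.delta_o,
        pop.w,
        pop.subpop_ids,
        n_subpops,
        pop.params.beta,
        kind,
        p0,
        p1,
        p2,
        horizon_sweeps,
        record_every,
        freeze_sweeps,
        snapshot_sweep,
        rng,
    )
    sizes = pop.subpop_sizes()
    sub_do = np.full(n_subpops, np.nan)
    if not schedule.shared:
        for s in range(n_subpops):
            members = pop.subpop_ids == s
            if members.any():
                sub_do[s] = pop.delta_o[members][0]
    return Trajectory(
        times=rec_t[:nrec].copy(),
        frac_A=rec_frac[:nrec].copy(),
        subpop_frac_A=rec_sub[:nrec].copy(),
        delta_o_t=rec_sched[:nrec].copy(),
        cum_flips=rec_flips[:nrec].copy(),
        agent_flips=agent_flips,
        snapshot_flips=snapshot_flips,
        snapshot_sweep=snapshot_sweep,
        final_sigma=pop.sigma.copy(),
        subpop_names=list(pop.subpop_names) or ["all"],
        subpop_sizes=sizes,
        subpop_delta_o=sub_do,
        schedule=schedule,
        n_agents=pop.n,
        equilibrium=bool(frozen),
        sweeps_run=int(sweeps_done),
    )


@dataclass
class EnsembleResult:
    """Independent realizations of one scenario on a common time grid."""

    trajectories: list[Trajectory]
    times: np.ndarray
    frac_A: np.ndarray  # (n_realizations, n_times), step-sampled

    def median_frac_A(self) -> np.ndarray:
        return np.median(self.frac_A, axis=0)

    def quantile_frac_A(self, q: float) -> np.ndarray:
        return np.quantile(self.frac_A, q, axis=0)

    def subpop_frac_A(self, name: str) -> np.ndarray:
        rows = [t.frac_A_at(self.times, subpop=name) for t in self.trajectories]
        return np.vstack(rows)

    def median_subpop_frac_A(self, name: str) -> np.ndarray:
        return np.median(self.subpop_frac_A(name), axis=0)


def run_ensemble(
    factory,
    schedule: EnvironmentSchedule,
    horizon_sweeps: int,
    n_realizations: int,
    seed: int | np.random.SeedSequence | None = None,
    seeds: list[int] | None = None,
    record_every: int = 1,
    freeze_sweeps: int = 50,
    snapshot_sweep: int = 0,
) -> EnsembleResult:
    """Run independent realizations and aggregate on a common grid.

    ``factory(seed_sequence)`` must build a fresh :class:`Population`
    (network, placement, initialization) from the given seed stream;
    each realization then receives an independent dynamics stream.
    Fully reproducible from ``seed`` (or an explicit ``seeds`` list).
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if seeds is not None:
        if len(seeds) != n_realizations:
            raise ValueError("seeds must have one entry per realization")
        children = [np.random.SeedSequence(s) for s in seeds]
    else:
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        children = ss.spawn(n_realizations)
    trajectories = []
    for child in children:
        pop_ss, dyn_ss = child.spawn(2)
        pop = factory(pop_ss)
        traj = run(
            pop,
            schedule,
            horizon_sweeps,
            record_every=record_every,
            rng=np.random.default_rng(dyn_ss),
            freeze_sweeps=freeze_sweeps,
            snapshot_sweep=snapshot_sweep,
        )
        trajectories.append(traj)
    grid = np.arange(0, horizon_sweeps + 1, record_every, dtype=float)
    frac = np.vstack([t.frac_A_at(grid) for t in trajectories])
    return EnsembleResult(trajectories=trajectories, times=grid, frac_A=frac)
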