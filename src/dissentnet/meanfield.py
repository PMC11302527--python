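"""Well-mixed (mean-field) companion of the network model.

In the annealed approximation every agent sees the global A-fraction X
through an effective degree k: a member of subpopulation s feels

    dU_s(X) = delta_o_s + w_s * k * (2X - 1)

and resamples A with the Fermi probability p_s(X).  The aggregate
self-consistency map is G(X) = sum_s n_s p_s(X); its fixed points are
the macroscopic equilibria, stable when G'(X*) < 1.  The module also
locates the critical anticonformist fraction at which the misaligned
(consensus) branch disappears in a discontinuous jump, and provides an
exact finite-N Markov-chain oracle on the complete graph for validating
the stochastic engine.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit


@dataclass(frozen=True)
class MeanFieldModel:
    """Subpopulation composition with an effective degree.

    ``subpops`` is a sequence of (fraction, delta_o, w) triples with
    fractions summing to 1; ``k`` is the effective number of neighbors
    (for a graph, typically the mean degree); ``beta`` the inverse
    temperature.
    """

    subpops: tuple[tuple[float, float, float], ...]
    k: float
    beta: float = 100.0

    def __post_init__(self) -> None:
        subpops = tuple(
            (float(n), float(d), float(w)) for (n, d, w) in self.subpops if n > 0
        )
        object.__setattr__(self, "subpops", subpops)
        total = sum(n for n, _, _ in subpops)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"subpopulation fractions must sum to 1, got {total}")
        if self.k <= 0:
            raise ValueError("effective degree k must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def delta_U(self, s: int, X) -> np.ndarray | float:
        _, d_o, w = self.subpops[s]
        return d_o + w * self.k * (2.0 * np.asarray(X, dtype=float) - 1.0)

    def subpop_response(self, X) -> np.ndarray:
        """p_s(X) for every subpopulation; shape (n_subpops,) + shape(X)."""
        return np.array([expit(self.beta * self.delta_U(s, X)) for s in range(len(self.subpops))])

    def response_map(self, X) -> np.ndarray | float:
        """G(X) = sum_s n_s p_s(X); the drift of the macro-dynamics is G(X) - X."""
        fracs = np.array([n for n, _, _ in self.subpops])
        g = np.tensordot(fracs, self.subpop_response(X), axes=(0, 0))
        return float(g) if np.isscalar(X) or np.ndim(X) == 0 else g


def response_map(model: MeanFieldModel, X) -> np.ndarray | float:
    return model.response_map(X)


@dataclass
class FixedPoint:
    """A root of G(X) - X with its stability classification."""

    X_star: float
    x_subpops: np.ndarray
    stability: str  # "stable" | "unstable"
    residual: float


def _stability(model: MeanFieldModel, x: float, h: float = 1e-6) -> str:
    if x < h:  # boundary root: one-sided drift
        return "stable" if model.response_map(x + h) - (x + h) < 0 else "unstable"
    if x > 1 - h:
        return "stable" if model.response_map(x - h) - (x - h) > 0 else "unstable"
    gp = (model.response_map(x + h) - model.response_map(x - h)) / (2 * h)
    return "stable" if gp < 1.0 else "unstable"


def find_fixed_points(
    model: MeanFieldModel, grid_size: int = 2000, tol: float = 1e-12
) -> list[FixedPoint]:
    """All roots of G(X) = X on [0, 1], by sign-change scan plus Brent refinement.

    G maps [0, 1] into itself, so at least one root always exists.
    Stability is classified by a central finite-difference derivative
    (one-sided drift at the boundaries).
    """
    if grid_size < 100:
        raise ValueError("grid_size must be >= 100")
    xs = np.linspace(0.0, 1.0, grid_size + 1)
    h = model.response_map(xs) - xs
    roots: list[float] = []
    for i in range(grid_size):
        a, b = xs[i], xs[i + 1]
        ha, hb = h[i], h[i + 1]
        if abs(ha) < 1e-14:
            roots.append(float(a))
        elif ha * hb < 0:
            roots.append(float(brentq(lambda x: model.response_map(x) - x, a, b, xtol=tol)))
    if abs(h[-1]) < 1e-14:
        roots.append(1.0)
    # dedupe (a grid point counted as root could also terminate a bracket)
    roots.sort()
    dedup: list[float] = []
    for r in roots:
        if not dedup or r - dedup[-1] > 1e-9:
            dedup.append(r)
    assert dedup, "G maps [0,1] into itself, a fixed point must exist"
    out = []
    for r in dedup:
        out.append(
            FixedPoint(
                X_star=r,
                x_subpops=model.subpop_response(r),
                stability=_stability(model, r),
                residual=float(model.response_map(r) - r),
            )
        )
    return out


def stable_roots(model: MeanFieldModel, grid_size: int = 2000) -> list[float]:
    return [fp.X_star for fp in find_fixed_points(model, grid_size) if fp.stability == "stable"]


def with_anticonformists(
    base: MeanFieldModel,
    f: float,
    anti: tuple[float, float] | list[tuple[float, float, float]],
    mode: str = "proportional",
) -> MeanFieldModel:
    """Replace a fraction f of the base composition with anticonformists.

    ``mode="proportional"`` scales every base subpopulation by (1 - f).
    ``anti`` is either a single (delta_o, w) pair or a list of
    (share_within_f, delta_o, w) triples (shares summing to 1), letting
    the anticonformists mirror the base preference split.
    """
    if not 0 <= f < 1 + 1e-12:
        raise ValueError("f must be in [0, 1]")
    if mode != "proportional":
        raise ValueError(f"unknown replacement mode {mode!r}")
    if isinstance(anti, tuple) and len(anti) == 2:
        anti_list = [(1.0, anti[0], anti[1])]
    else:
        anti_list = list(anti)
        if abs(sum(a[0] for a in anti_list) - 1.0) > 1e-8:
            raise ValueError("anticonformist shares must sum to 1")
    subpops = [(n * (1 - f), d, w) for (n, d, w) in base.subpops]
    subpops += [(share * f, d, w) for (share, d, w) in anti_list]
    return replace(base, subpops=tuple(subpops))


@dataclass
class CriticalFractionResult:
    """Smallest anticonformist fraction destroying the misaligned branch."""

    f_star: float | None
    found: bool
    X_before: float | None  # followed (largest) stable root just below f*
    X_after: float | None  # largest stable root just above f*
    jump: float | None  # discontinuity size in the followed branch


def critical_fraction(
    base_model: MeanFieldModel,
    anti: tuple[float, float] | list[tuple[float, float, float]],
    f_range: tuple[float, float] = (0.0, 0.8),
    tol_f: float = 1e-4,
    grid_size: int = 2000,
) -> CriticalFractionResult:
    """Bisect in f for the loss of bistability of the self-consistency map.

    The base model must be bistable at f = f_range[0] (two stable
    roots); otherwise preferences already dominate and f* = f_range[0].
    Returns the bifurcation point together with the jump in the
    followed (misaligned) stable branch.
    """

    def n_stable(f: float) -> list[float]:
        return stable_roots(with_anticonformists(base_model, f, anti), grid_size)

    f_lo, f_hi = f_range
    roots_lo = n_stable(f_lo)
    if len(roots_lo) < 2:
        return CriticalFractionResult(f_lo, True, None, max(roots_lo), None)
    if len(n_stable(f_hi)) >= 2:
        return CriticalFractionResult(None, False, None, None, None)
    lo, hi = f_lo, f_hi
    while hi - lo > tol_f:
        mid = 0.5 * (lo + hi)
        if len(n_stable(mid)) >= 2:
            lo = mid
        else:
            hi = mid
    x_before = max(n_stable(lo))
    x_after = max(n_stable(hi))
    f_star = 0.5 * (lo + hi)
    return CriticalFractionResult(f_star, True, x_before, x_after, x_before - x_after)


# ---------------------------------------------------------------------------
# exact finite-N Markov chain on the complete graph


@dataclass
class MarkovResult:
    """Stationary (or absorption) distribution over macro-states.

    ``states`` are tuples of per-subpopulation A-counts; ``probs`` is
    the stationary distribution when the single-update chain is
    ergodic, or — when absorbing states exist (the effectively
    deterministic large-beta regime) — the absorption probabilities
    from the supplied initial distribution, with mass only on the
    absorbing states and ``absorbing=True``.
    """

    states: list[tuple[int, ...]]
    probs: np.ndarray
    absorbing: bool
    subpop_sizes: tuple[int, ...]

    def marginal_total_A(self) -> np.ndarray:
        """Distribution of the total A-count."""
        n_total = sum(self.subpop_sizes)
        out = np.zeros(n_total + 1)
        for st, p in zip(self.states, self.probs):
            out[sum(st)] += p
        return out


def _subpop_sizes(model: MeanFieldModel, n_small: int) -> tuple[int, ...]:
    fracs = np.array([n for n, _, _ in model.subpops])
    ideal = fracs * n_small
    sizes = np.floor(ideal).astype(int)
    rem = n_small - sizes.sum()
    order = np.argsort(-(ideal - sizes))
    sizes[order[:rem]] += 1
    return tuple(int(s) for s in sizes)


def transition_matrix(
    model: MeanFieldModel, n_small: int
) -> tuple[list[tuple[int, ...]], np.ndarray, tuple[int, ...]]:
    """Exact single-update transition matrix on the complete graph.

    States are per-subpopulation A-counts; one update picks a uniform
    agent whose neighbors are the other N-1 agents (self excluded) and
    resamples its choice with the Fermi rule.  ``model.k`` is ignored
    here — the complete graph fixes the neighborhood exactly.
    """
    sizes = _subpop_sizes(model, n_small)
    n_states = int(np.prod([s + 1 for s in sizes]))
    if n_states > 100_000:
        raise ValueError(f"state space of size {n_states} exceeds the 1e5 limit")
    states = list(itertools.product(*[range(s + 1) for s in sizes]))
    index = {st: i for i, st in enumerate(states)}
    n = n_small
    params = [(d, w) for (_, d, w) in model.subpops]
    p_mat = np.zeros((n_states, n_states))
    for st, i in index.items():
        total_a = sum(st)
        stay = 1.0
        for s, (d_o, w) in enumerate(params):
            a_s, n_s = st[s], sizes[s]
            if a_s > 0:  # an A-agent of subpop s is picked and flips to B
                n_a = total_a - 1
                du = d_o + w * (n_a - (n - 1 - n_a))
                p_flip = (a_s / n) * (1.0 - expit(model.beta * du))
                if p_flip > 0:
                    dst = list(st)
                    dst[s] -= 1
                    p_mat[i, index[tuple(dst)]] += p_flip
                    stay -= p_flip
            if a_s < n_s:  # a B-agent of subpop s is picked and flips to A
                n_a = total_a
                du = d_o + w * (n_a - (n - 1 - n_a))
                p_flip = ((n_s - a_s) / n) * expit(model.beta * du)
                if p_flip > 0:
                    dst = list(st)
                    dst[s] += 1
                    p_mat[i, index[tuple(dst)]] += p_flip
                    stay -= p_flip
        p_mat[i, i] += stay
    return states, p_mat, sizes


def finite_markov_stationary(
    model: MeanFieldModel,
    n_small: int,
    init: np.ndarray | str = "uniform",
    absorbing_tol: float = 1e-12,
) -> MarkovResult:
    """Stationary distribution of the exact finite-N single-update chain.

    When absorbing macro-states exist (at large beta consensus states
    of all-conformist compositions absorb), the stationary distribution
    is degenerate; absorption probabilities from ``init`` (default
    uniform over all states) are returned instead and flagged.
    """
    states, p_mat, sizes = transition_matrix(model, n_small)
    n_states = len(states)
    absorbing_idx = np.flatnonzero(np.diag(p_mat) >= 1.0 - absorbing_tol)
    if isinstance(init, str):
        if init != "uniform":
            raise ValueError(f"unknown init {init!r}")
        init_dist = np.full(n_states, 1.0 / n_states)
    else:
        init_dist = np.asarray(init, dtype=float)
        if init_dist.shape != (n_states,) or abs(init_dist.sum() - 1.0) > 1e-8:
            raise ValueError("init must be a probability vector over the states")
    if absorbing_idx.size > 0:
        transient = np.setdiff1d(np.arange(n_states), absorbing_idx)
        q = p_mat[np.ix_(transient, transient)]
        r = p_mat[np.ix_(transient, absorbing_idx)]
        b = np.linalg.solve(np.eye(transient.size) - q, r)  # absorption probs
        probs = np.zeros(n_states)
        probs[absorbing_idx] += init_dist[absorbing_idx]
        probs[absorbing_idx] += init_dist[transient] @ b
        return MarkovResult(states, probs, True, sizes)
    # ergodic chain: left eigenvector of P at eigenvalue 1
    a = np.vstack([p_mat.T - np.eye(n_states), np.ones(n_states)])
    rhs = np.zeros(n_states + 1)
    rhs[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return MarkovResult(states, pi, False, sizes)
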