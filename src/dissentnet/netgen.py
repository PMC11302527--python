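"""Network generation, anticonformist placement, and assortativity tuning.

Two synthetic families are supported: Erdos-Renyi random graphs (Poisson
degrees) and Barabasi-Albert preferential attachment (scale-free, hubs).
Anticonformists are placed on nodes so that the Pearson (point-biserial)
correlation between node degree and the anticonformist indicator hits a
requested target: the loop starts from the extremal assignment
(anticonformists on the highest- or lowest-degree nodes) and greedily
swaps the attributes of random node pairs until the correlation is
within tolerance.  Degree assortativity is tuned by degree-ordered
two-edge rewiring that preserves the degree sequence exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


class PlacementError(RuntimeError):
    """Swap loop exhausted before reaching the target correlation."""

    def __init__(self, message: str, achieved_corr: float):
        super().__init__(message)
        self.achieved_corr = achieved_corr


# ---------------------------------------------------------------------------
# generators


def generate_er(n: int, mean_degree: float, rng: np.random.Generator) -> nx.Graph:
    """Erdos-Renyi graph G(n, p) with p = mean_degree / (n - 1).

    Above the connectivity threshold (mean_degree >= ln n) the draw is
    repeated up to 100 times until the graph is connected; below it the
    giant component is extracted and relabeled to 0..n_giant-1 (the
    reduced size is available as ``G.graph["giant_of"]``).
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if not 0 < mean_degree < n:
        raise ValueError(f"need 0 < mean_degree < n, got {mean_degree}")
    p = min(1.0, mean_degree / (n - 1))
    if mean_degree >= math.log(n):
        for _ in range(100):
            g = nx.fast_gnp_random_graph(n, p, seed=rng)
            if nx.is_connected(g):
                return g
        raise RuntimeError(
            f"no connected G({n}, {p:.4g}) in 100 draws; "
            "mean_degree is too close to the connectivity threshold"
        )
    g = nx.fast_gnp_random_graph(n, p, seed=rng)
    giant = max(nx.connected_components(g), key=len)
    sub = nx.convert_node_labels_to_integers(g.subgraph(giant), ordering="sorted")
    sub.graph["giant_of"] = n
    return sub


def generate_ba(n: int, m: int, rng: np.random.Generator) -> nx.Graph:
    """Barabasi-Albert graph: each arriving node attaches m edges.

    The seed graph is the complete graph on m nodes, so every node
    outside the seed has degree >= m (minimum degree k_min = m) and the
    graph is connected.
    """
    if not 1 <= m < n:
        raise ValueError(f"need 1 <= m < n, got m={m}, n={n}")
    seed_graph = nx.complete_graph(m)
    return nx.barabasi_albert_graph(n, m, seed=rng, initial_graph=seed_graph)


# ---------------------------------------------------------------------------
# degree / type correlation


def corr_degree_type(net: nx.Graph, assignment: np.ndarray) -> float:
    """Pearson correlation between node degree and the 0/1 type indicator.

    Returns 0.0 by convention when either vector is constant.
    """
    deg = degree_array(net)
    x = np.asarray(assignment, dtype=float)
    if x.shape != deg.shape:
        raise ValueError("assignment must cover all nodes")
    if np.ptp(deg) == 0 or np.ptp(x) == 0:
        return 0.0
    return float(np.corrcoef(deg, x)[0, 1])


def degree_array(net: nx.Graph) -> np.ndarray:
    """Degrees indexed by node id 0..N-1."""
    n = net.number_of_nodes()
    deg = np.zeros(n, dtype=np.int64)
    for v, d in net.degree():
        deg[v] = d
    return deg


def _corr_from_sum(deg: np.ndarray, n_anti: int, s: float) -> float:
    """Pearson rho(degree, indicator) as a function of S = sum of anticonformist degrees."""
    n = deg.size
    p = n_anti / n
    sd_deg = deg.std()
    sd_x = math.sqrt(p * (1 - p))
    if sd_deg == 0 or sd_x == 0:
        return 0.0
    cov = s / n - deg.mean() * p
    return cov / (sd_deg * sd_x)


def attainable_corr_range(net: nx.Graph, n_anti: int) -> tuple[float, float]:
    """[rho_min, rho_max] achievable for n_anti anticonformists on this degree sequence."""
    deg = degree_array(net)
    if n_anti == 0 or n_anti == deg.size:
        return (0.0, 0.0)
    srt = np.sort(deg)
    lo = _corr_from_sum(deg, n_anti, float(srt[:n_anti].sum()))
    hi = _corr_from_sum(deg, n_anti, float(srt[-n_anti:].sum()))
    return (lo, hi)


@dataclass
class PlacementSpec:
    """Target for degree-correlated anticonformist placement.

    Parameters
    ----------
    fraction_anti
        Fraction of nodes to mark anticonformist, in [0, 1]; the realized
        count is round(fraction_anti * N).
    target_corr
        Desired Pearson correlation between degree and the indicator.
        Pass ``"max"`` / ``"min"`` to request the extremal attainable value.
    tolerance
        Accepted |achieved - target| (ignored for extremal targets).
    max_iters
        Swap budget before giving up.
    """

    fraction_anti: float
    target_corr: float | str = 0.0
    tolerance: float = 0.01
    max_iters: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_anti <= 1.0:
            raise ValueError(f"fraction_anti must be in [0, 1], got {self.fraction_anti}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class PlacementResult:
    """Outcome of :func:`place_types`."""

    indicator: np.ndarray  # bool, True = anticonformist
    achieved_corr: float
    iterations: int


def place_types(
    net: nx.Graph, spec: PlacementSpec, rng: np.random.Generator
) -> PlacementResult:
    """Assign the anticonformist indicator with a target degree correlation.

    Initialization puts anticonformists on the round(f*N) highest-degree
    nodes for non-negative targets (lowest-degree for negative ones),
    ties broken by node id, then greedily swaps the attribute of a
    random (anticonformist, other) pair whenever the swap does not move
    the achieved correlation away from the target.  The graph itself is
    never modified.
    """
    n = net.number_of_nodes()
    n_anti = int(round(spec.fraction_anti * n))
    if spec.fraction_anti > 0 and n_anti == 0:
        raise ValueError(
            f"fraction_anti={spec.fraction_anti} rounds to zero anticonformists at N={n}"
        )
    indicator = np.zeros(n, dtype=bool)
    if n_anti == 0:
        return PlacementResult(indicator, 0.0, 0)
    if n_anti == n:
        return PlacementResult(np.ones(n, dtype=bool), 0.0, 0)

    deg = degree_array(net)
    lo, hi = attainable_corr_range(net, n_anti)
    if spec.target_corr == "max":
        target = hi
    elif spec.target_corr == "min":
        target = lo
    else:
        target = float(spec.target_corr)
        if not lo - 1e-12 <= target <= hi + 1e-12:
            raise ValueError(
                f"target correlation {target:.4f} outside attainable "
                f"range [{lo:.4f}, {hi:.4f}] for this degree sequence"
            )

    # order by (degree, id): extremal initialization with id tie-break
    order = np.lexsort((np.arange(n), deg))
    if target >= 0:
        anti_nodes = order[-n_anti:]
    else:
        anti_nodes = order[:n_anti]
    indicator[anti_nodes] = True

    # rho is a monotone affine function of S = sum of anticonformist degrees,
    # so swaps can be accepted on the incremental S alone.
    s = float(deg[indicator].sum())
    rho = _corr_from_sum(deg, n_anti, s)
    iters = 0
    if abs(rho - target) > spec.tolerance and spec.target_corr not in ("max", "min"):
        anti_list = np.flatnonzero(indicator)
        other_list = np.flatnonzero(~indicator)
        for iters in range(1, spec.max_iters + 1):
            ia = rng.integers(0, anti_list.size)
            io = rng.integers(0, other_list.size)
            u, v = anti_list[ia], other_list[io]
            s_new = s + deg[v] - deg[u]
            rho_new = _corr_from_sum(deg, n_anti, s_new)
            if abs(rho_new - target) <= abs(rho - target):
                anti_list[ia], other_list[io] = v, u
                s, rho = s_new, rho_new
                if abs(rho - target) <= spec.tolerance:
                    break
        else:
            indicator = np.zeros(n, dtype=bool)
            indicator[anti_list] = True
            achieved = corr_degree_type(net, indicator)
            raise PlacementError(
                f"target {target:.4f} not reached in {spec.max_iters} swaps "
                f"(achieved {achieved:.4f})",
                achieved,
            )
        indicator = np.zeros(n, dtype=bool)
        indicator[anti_list] = True

    achieved = corr_degree_type(net, indicator)
    return PlacementResult(indicator, achieved, iters)


# ---------------------------------------------------------------------------
# assortativity rewiring


def rewire_assortative(
    net: nx.Graph,
    mode: str,
    steps: int,
    rng: np.random.Generator,
    target_r: float | None = None,
    check_every: int | None = None,
) -> nx.Graph:
    """Tune degree assortativity by degree-ordered two-edge rewiring.

    Each step draws two random edges with four distinct endpoints and
    rewires them according to ``mode``: ``"assortative"`` joins the two
    highest-degree endpoints together (and the two lowest),
    ``"disassortative"`` joins the highest to the lowest, ``"neutral"``
    picks one of the two alternative pairings at random.  Proposals that
    would create a self-loop or a multi-edge are rejected, so the degree
    sequence is preserved exactly.  Returns a new graph.

    With ``target_r`` set, Newman's assortativity coefficient is
    recomputed every ``check_every`` accepted rewirings (default: one
    tenth of the edge count) and the loop stops once the coefficient
    has reached or passed the target in the mode's direction; running
    to exhaustion otherwise returns the network with whatever r was
    achieved.
    """
    if mode not in ("assortative", "disassortative", "neutral"):
        raise ValueError(f"unknown mode {mode!r}")
    if net.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to rewire")
    g = net.copy()
    deg = degree_array(g)  # invariant under rewiring
    edges = [tuple(e) for e in g.edges()]
    edge_set = {frozenset(e) for e in edges}
    n_edges = len(edges)
    if check_every is None:
        check_every = max(1, n_edges // 10)
    accepted = 0

    def _current_r() -> float:
        h = nx.Graph()
        h.add_nodes_from(range(net.number_of_nodes()))
        h.add_edges_from(edges)
        return float(nx.degree_assortativity_coefficient(h))

    for _ in range(steps):
        i = rng.integers(0, n_edges)
        j = rng.integers(0, n_edges)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) < 4:
            continue
        nodes = sorted((a, b, c, d), key=lambda v: (deg[v], v))
        if mode == "assortative":
            new1, new2 = (nodes[0], nodes[1]), (nodes[2], nodes[3])
        elif mode == "disassortative":
            new1, new2 = (nodes[0], nodes[3]), (nodes[1], nodes[2])
        else:
            if rng.random() < 0.5:
                new1, new2 = (a, c), (b, d)
            else:
                new1, new2 = (a, d), (b, c)
        f1, f2 = frozenset(new1), frozenset(new2)
        if f1 == f2:
            continue
        old1, old2 = frozenset((a, b)), frozenset((c, d))
        if {f1, f2} == {old1, old2}:
            continue
        if (f1 in edge_set and f1 not in (old1, old2)) or (
            f2 in edge_set and f2 not in (old1, old2)
        ):
            continue
        edge_set.discard(old1)
        edge_set.discard(old2)
        edge_set.add(f1)
        edge_set.add(f2)
        edges[i], edges[j] = new1, new2
        accepted += 1
        if target_r is not None and accepted % check_every == 0:
            r = _current_r()
            if (mode == "assortative" and r >= target_r) or (
                mode == "disassortative" and r <= target_r
            ) or (mode == "neutral" and abs(r) <= abs(target_r)):
                break
    out = nx.Graph()
    out.add_nodes_from(range(net.number_of_nodes()))
    out.add_edges_from(edges)
    return out


# ---------------------------------------------------------------------------
# i/o


def write_edgelist(net: nx.Graph, path: str) -> None:
    """Whitespace-delimited edge list, no attributes."""
    nx.write_edgelist(net, path, data=False)


def read_edgelist(path: str) -> nx.Graph:
    """Read an undirected edge list with integer node ids."""
    g = nx.read_edgelist(path, nodetype=int)
    out = nx.Graph()
    out.add_nodes_from(range(max(g.nodes) + 1))
    out.add_edges_from(g.edges())
    return out


def write_node_attributes(
    path: str,
    indicator: np.ndarray,
    delta_o: np.ndarray | None = None,
    w: np.ndarray | None = None,
) -> None:
    """Companion CSV of per-node attributes keyed by 0-based node id."""
    data = {"node": np.arange(len(indicator)), "anticonformist": np.asarray(indicator, int)}
    if delta_o is not None:
        data["delta_o"] = delta_o
    if w is not None:
        data["w"] = w
    pd.DataFrame(data).to_csv(path, index=False)


def read_node_attributes(path: str) -> pd.DataFrame:
    return pd.read_csv(path).set_index("node")
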