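"""Config-driven scenarios, canned experiments, and parameter sweeps.

A :class:`Scenario` bundles everything needed to reproduce an ensemble:
network family and size, anticonformist placement, subpopulation
composition, environment schedule, decision parameters, horizon,
ensemble size, and seed.  It round-trips losslessly through YAML/JSON.

The canned scenarios (``fig2a`` .. ``fig4``) are desk-scale versions of
the package's four headline experiments: the conformity trap and its
breakdown with anticonformist fraction and centrality under static
heterogeneous preferences, social tipping under a linearly drifting
shared preference, and lead/lag behavior under a sinusoidally
fluctuating one.  Defaults use N = 500 and 20 realizations (scaled from
the reference sizes of 1,000-2,000 and 100 realizations) so every
scenario runs in well under a minute.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

import dissentnet
from dissentnet.core import DecisionParams
from dissentnet.dynamics import (
    EnsembleResult,
    EnvironmentSchedule,
    Population,
    Subpop,
    init_population,
    run_ensemble,
)
from dissentnet.meanfield import MeanFieldModel, critical_fraction, with_anticonformists
from dissentnet.metrics import (
    alignment_trajectory,
    lead_time,
    tipping_time,
    tracking_alignment,
    volatility,
)
from dissentnet.netgen import (
    PlacementSpec,
    generate_ba,
    generate_er,
    place_types,
    read_edgelist,
    rewire_assortative,
)

log = logging.getLogger("dissentnet")

CONFIG_VERSION = 1


@dataclass
class Scenario:
    """A fully specified, reproducible simulation experiment."""

    name: str
    network: dict
    placement: dict
    composition: list[dict]
    schedule: dict
    beta: float = 100.0
    horizon_sweeps: int = 2000
    record_every: int = 1
    n_realizations: int = 20
    seed: int = 0
    initial_fraction_A: float = 1.0
    init_mode: str = "random"
    freeze_sweeps: int = 50
    assortative: dict | None = None
    thresholds: dict = field(
        default_factory=lambda: {"expression": 0.9, "tipping": 0.5, "burn_in": 100.0}
    )

    REQUIRED = ("name", "network", "placement", "composition", "schedule")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["config_version"] = CONFIG_VERSION
        d["package_version"] = dissentnet.__version__
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = copy.deepcopy(d)
        d.pop("config_version", None)
        d.pop("package_version", None)
        missing = [k for k in cls.REQUIRED if k not in d]
        if missing:
            raise ValueError(f"config missing required field(s): {', '.join(missing)}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"config has unknown field(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "Scenario":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    # -- pieces -------------------------------------------------------
    def environment(self) -> EnvironmentSchedule:
        return EnvironmentSchedule(**self.schedule)

    def subpops(self) -> list[Subpop]:
        """Composition with the dissenter share tied to the placement spec.

        ``placement.fraction_anti`` is the single source of truth for
        the placed (dissenter) share: placed subpopulations are rescaled
        to sum to it and the rest to its complement, preserving relative
        proportions within each class.  This keeps a sweep over
        ``placement.fraction_anti`` consistent without editing the
        composition alongside it.
        """
        subs = [Subpop(**c) for c in self.composition]
        f = float(self.placement.get("fraction_anti", 0.0))
        placed_total = sum(s.fraction for s in subs if s.placed)
        free_total = sum(s.fraction for s in subs if not s.placed)
        if f > 0 and placed_total == 0:
            raise ValueError(
                "placement.fraction_anti > 0 but composition has no placed subpopulation"
            )
        if f < 1 and free_total == 0:
            raise ValueError(
                "placement.fraction_anti < 1 but composition has no unplaced subpopulation"
            )
        out = []
        for s in subs:
            scale = f / placed_total if s.placed else (1 - f) / free_total
            frac = s.fraction * scale
            if frac > 0:
                out.append(Subpop(s.name, s.delta_o, s.w, frac, s.placed))
        return out

    def build_graph(self, rng: np.random.Generator):
        net = dict(self.network)
        family = net.pop("family")
        if family == "ba":
            g = generate_ba(net["n"], net["m"], rng)
        elif family == "er":
            g = generate_er(net["n"], net["mean_degree"], rng)
        elif family == "edgelist":
            g = read_edgelist(net["path"])
        else:
            raise ValueError(f"unknown network family {family!r}")
        if self.assortative is not None:
            g = rewire_assortative(
                g,
                self.assortative["mode"],
                int(self.assortative.get("steps", 20 * g.number_of_edges())),
                rng,
                target_r=self.assortative.get("target_r"),
            )
        return g

    def build_population(self, seed_seq: np.random.SeedSequence) -> Population:
        """Network -> placement -> initialization, on independent substreams."""
        net_ss, place_ss, init_ss = seed_seq.spawn(3)
        g = self.build_graph(np.random.default_rng(net_ss))
        spec = PlacementSpec(**self.placement)
        placement = place_types(g, spec, np.random.default_rng(place_ss))
        log.debug(
            "scenario %s: N=%d achieved placement corr %.4f (%d swaps)",
            self.name,
            g.number_of_nodes(),
            placement.achieved_corr,
            placement.iterations,
        )
        return init_population(
            g,
            placement.indicator,
            self.subpops(),
            initial_fraction_A=self.initial_fraction_A,
            init_mode=self.init_mode,
            params=DecisionParams(beta=self.beta),
            rng=np.random.default_rng(init_ss),
        )


def run_scenario(
    scenario: Scenario,
    seed: int | None = None,
    n_realizations: int | None = None,
) -> EnsembleResult:
    """Run the scenario's ensemble (overrides take precedence over the config)."""
    return run_ensemble(
        scenario.build_population,
        scenario.environment(),
        scenario.horizon_sweeps,
        n_realizations or scenario.n_realizations,
        seed=scenario.seed if seed is None else seed,
        record_every=scenario.record_every,
        freeze_sweeps=scenario.freeze_sweeps,
        snapshot_sweep=int(scenario.thresholds.get("burn_in", 0)),
    )


# ---------------------------------------------------------------------------
# composition helpers


def mixed_composition(
    fraction_anti: float,
    delta_o: float = 10.0,
    w_conf: float = 1.0,
    w_dissent: float = -1.0,
    pref_split: float = 0.5,
    dissenter_placed: bool = True,
) -> list[dict]:
    """Half-and-half preference split crossed with a dissenter fraction.

    Conformists (w = w_conf) make up 1 - f of the population and
    dissenters (w = w_dissent; anticonformists by default, w = 0 for
    nonconformists) the remaining f, each split ``pref_split`` /
    ``1 - pref_split`` between preferring A (+delta_o) and B
    (-delta_o).  Dissenters are bound to the placement indicator.
    """
    f = fraction_anti
    comp = [
        {"name": "conf_A", "delta_o": delta_o, "w": w_conf, "fraction": (1 - f) * pref_split},
        {
            "name": "conf_B",
            "delta_o": -delta_o,
            "w": w_conf,
            "fraction": (1 - f) * (1 - pref_split),
        },
    ]
    if f > 0:
        comp += [
            {
                "name": "dissent_A",
                "delta_o": delta_o,
                "w": w_dissent,
                "fraction": f * pref_split,
                "placed": dissenter_placed,
            },
            {
                "name": "dissent_B",
                "delta_o": -delta_o,
                "w": w_dissent,
                "fraction": f * (1 - pref_split),
                "placed": dissenter_placed,
            },
        ]
    return [c for c in comp if c["fraction"] > 0]


def shared_composition(
    fraction_anti: float, w_conf: float = 1.0, w_dissent: float = -1.0
) -> list[dict]:
    """Conformist/dissenter split for shared (dynamic) preferences."""
    comp = [
        {"name": "conformist", "delta_o": 0.0, "w": w_conf, "fraction": 1 - fraction_anti}
    ]
    if fraction_anti > 0:
        comp.append(
            {
                "name": "dissenter",
                "delta_o": 0.0,
                "w": w_dissent,
                "fraction": fraction_anti,
                "placed": True,
            }
        )
    return comp


def matched_meanfield(scenario: Scenario, k: float) -> MeanFieldModel:
    """Mean-field model with the scenario's composition and effective degree k."""
    subpops = tuple((c["fraction"], c["delta_o"], c["w"]) for c in scenario.composition)
    return MeanFieldModel(subpops=subpops, k=k, beta=scenario.beta)


# ---------------------------------------------------------------------------
# canned desk-scale scenarios


def fig2a(
    fraction_anti: float = 0.0,
    n: int = 500,
    m: int = 20,
    n_realizations: int = 20,
    seed: int = 0,
) -> Scenario:
    """Static heterogeneous preferences, random anticonformist placement.

    BA network with k_min = m, half the population preferring A
    (delta_o = +10) and half B (delta_o = -10), conformists w = +1,
    anticonformists w = -1, everyone starting on A: the conformity-trap
    scenario and its breakdown as f grows.
    """
    return Scenario(
        name="fig2a",
        network={"family": "ba", "n": n, "m": m},
        placement={"fraction_anti": fraction_anti, "target_corr": 0.0, "tolerance": 0.02},
        composition=mixed_composition(fraction_anti),
        schedule={"kind": "static"},
        horizon_sweeps=2000,
        record_every=5,
        n_realizations=n_realizations,
        seed=seed,
        initial_fraction_A=1.0,
    )


def fig2b(
    fraction_anti: float,
    target_corr: float | str = 0.0,
    n: int = 500,
    m: int = 20,
    n_realizations: int = 20,
    seed: int = 0,
) -> Scenario:
    """As fig2a with degree-correlated anticonformist placement."""
    s = fig2a(fraction_anti, n=n, m=m, n_realizations=n_realizations, seed=seed)
    s.name = "fig2b"
    s.placement["target_corr"] = target_corr
    return s


def fig3a(
    fraction_anti: float = 0.15,
    n: int = 500,
    m: int = 20,
    n_realizations: int = 20,
    seed: int = 0,
) -> Scenario:
    """Linearly drifting shared preference: delta_o(t) = 10 - 0.1 t.

    The population starts at consensus on A (the initially preferred
    option); the environment crosses zero at sweep 100 of a 400-sweep
    horizon.
    """
    return Scenario(
        name="fig3a",
        network={"family": "ba", "n": n, "m": m},
        placement={"fraction_anti": fraction_anti, "target_corr": 0.0, "tolerance": 0.02},
        composition=shared_composition(fraction_anti),
        schedule={"kind": "linear", "delta_o0": 10.0, "rate": 0.1},
        horizon_sweeps=400,
        record_every=1,
        n_realizations=n_realizations,
        seed=seed,
        initial_fraction_A=1.0,
        freeze_sweeps=0,
    )


def fig3b(
    target_corr: float | str = 0.0,
    fraction_anti: float = 0.15,
    n: int = 500,
    m: int = 20,
    n_realizations: int = 20,
    seed: int = 0,
) -> Scenario:
    """As fig3a with degree-correlated anticonformist placement."""
    s = fig3a(fraction_anti, n=n, m=m, n_realizations=n_realizations, seed=seed)
    s.name = "fig3b"
    s.placement["target_corr"] = target_corr
    return s


def fig4(
    target_corr: float | str = 0.0,
    fraction_anti: float = 0.2,
    n: int = 500,
    m: int = 20,
    n_realizations: int = 20,
    seed: int = 0,
) -> Scenario:
    """Sinusoidally fluctuating shared preference, period 200 sweeps."""
    return Scenario(
        name="fig4",
        network={"family": "ba", "n": n, "m": m},
        placement={"fraction_anti": fraction_anti, "target_corr": target_corr, "tolerance": 0.02},
        composition=shared_composition(fraction_anti),
        schedule={"kind": "sinusoidal", "amplitude": 10.0, "period": 200.0, "phase": 0.0},
        horizon_sweeps=700,
        record_every=1,
        n_realizations=n_realizations,
        seed=seed,
        initial_fraction_A=1.0,
        freeze_sweeps=0,
    )


CANNED = {"fig2a": fig2a, "fig2b": fig2b, "fig3a": fig3a, "fig3b": fig3b, "fig4": fig4}


# ---------------------------------------------------------------------------
# summaries and sweeps


def summarize(ensemble: EnsembleResult, scenario: Scenario) -> dict:
    """Per-scenario metric summary (medians and quartiles across realizations)."""
    sched = scenario.environment()
    thr = scenario.thresholds
    out: dict = {
        "scenario": scenario.name,
        "n_realizations": len(ensemble.trajectories),
        "final_frac_A": _qdict([t.frac_A[-1] for t in ensemble.trajectories]),
    }
    if not sched.shared:
        aligns = [alignment_trajectory(t).global_alignment for t in ensemble.trajectories]
        vols = [
            volatility(t, thr.get("burn_in", 100.0))
            for t in ensemble.trajectories
            if t.times[-1] > thr.get("burn_in", 100.0)
        ]
        out["equilibrium_alignment"] = _qdict(aligns)
        out["expression_achieved"] = bool(
            np.median(aligns) >= thr.get("expression", 0.9)
        )
        # sensitivity of the binary outcome to the expression threshold
        out["expression_achieved_by_threshold"] = {
            str(t): bool(np.median(aligns) >= t) for t in (0.8, 0.9, 0.95)
        }
        if vols:
            out["volatility"] = _qdict(vols)
        out["equilibrated"] = float(np.mean([t.equilibrium for t in ensemble.trajectories]))
    elif sched.kind == "linear":
        lags = [
            tipping_time(t, sched, thr.get("tipping", 0.5)).lag
            for t in ensemble.trajectories
        ]
        lags = [l for l in lags if l is not None]
        out["tipping_lag"] = _qdict(lags) if lags else None
        out["tipped_fraction"] = float(
            np.mean([tipping_time(t, sched).tipped for t in ensemble.trajectories])
        )
    elif sched.kind == "sinusoidal":
        for name in ensemble.trajectories[0].subpop_names:
            leads = [lead_time(t, sched, name) for t in ensemble.trajectories]
            leads = [x for x in leads if np.isfinite(x)]
            out[f"lead_time_{name}"] = _qdict(leads) if leads else None
            out[f"tracking_alignment_{name}"] = _qdict(
                [tracking_alignment(t, name) for t in ensemble.trajectories]
            )
        out["tracking_alignment_global"] = _qdict(
            [tracking_alignment(t) for t in ensemble.trajectories]
        )
    return out


def _qdict(values) -> dict:
    arr = np.asarray(list(values), dtype=float)
    return {
        "median": float(np.median(arr)),
        "q25": float(np.quantile(arr, 0.25)),
        "q75": float(np.quantile(arr, 0.75)),
        "n": int(arr.size),
    }


def ensemble_to_frame(ensemble: EnsembleResult) -> pd.DataFrame:
    """Tidy long-format trajectory table (one row per realization and record)."""
    frames = []
    for r, t in enumerate(ensemble.trajectories):
        d = {
            "realization": r,
            "sweep": t.times,
            "delta_o": t.delta_o_t,
            "frac_A_global": t.frac_A,
            "flips": t.cum_flips,
        }
        for s, name in enumerate(t.subpop_names):
            d[f"frac_A_{name}"] = t.subpop_frac_A[:, s]
        frames.append(pd.DataFrame(d))
    return pd.concat(frames, ignore_index=True)


def set_config_value(scenario: Scenario, path: str, value) -> Scenario:
    """Return a copy with the dotted-path scalar field replaced."""
    d = scenario.to_dict()
    parts = path.split(".")
    node = d
    for p in parts[:-1]:
        if isinstance(node, list):
            node = node[int(p)]
        else:
            node = node[p]
    leaf = parts[-1]
    current = node[int(leaf)] if isinstance(node, list) else node.get(leaf)
    if isinstance(current, (dict, list)):
        raise ValueError(f"axis {path!r} does not resolve to a scalar field")
    if isinstance(node, list):
        node[int(leaf)] = value
    else:
        node[leaf] = value
    return Scenario.from_dict(d)


def sweep(
    scenario_for_value,
    values,
    seed: int = 0,
) -> pd.DataFrame:
    """Run one ensemble per axis value; long-format summary rows.

    ``scenario_for_value(v)`` must return the Scenario for value ``v``;
    each value gets an independent seed substream derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for v, child in zip(values, ss.spawn(len(list(values)))):
        sc = scenario_for_value(v)
        ens = run_scenario(sc, seed=child)
        summ = summarize(ens, sc)
        row = {"value": v, "scenario": sc.name}
        for key, stat in summ.items():
            if isinstance(stat, dict) and "median" in stat:
                row[key] = stat["median"]
                row[f"{key}_q25"] = stat["q25"]
                row[f"{key}_q75"] = stat["q75"]
            elif isinstance(stat, (int, float, bool)):
                row[key] = stat
        rows.append(row)
    return pd.DataFrame(rows)


def fraction_sweep_alignment(
    fractions,
    n: int = 500,
    m: int = 20,
    target_corr: float | str = 0.0,
    n_realizations: int = 20,
    dissenter_w: float = -1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Median equilibrium alignment across a dissenter-fraction axis."""

    def make(f):
        s = fig2b(f, target_corr, n=n, m=m, n_realizations=n_realizations)
        s.composition = mixed_composition(f, w_dissent=dissenter_w)
        return s

    return sweep(make, list(fractions), seed=seed)


def empirical_critical_fraction(
    make_scenario,
    f_lo: float = 0.0,
    f_hi: float = 0.6,
    tol_f: float = 0.01,
    threshold: float = 0.9,
    seed: int = 0,
) -> float | None:
    """Bisect for the smallest dissenter fraction achieving expression.

    ``make_scenario(f)`` builds the scenario at fraction f; expression
    is achieved when the median equilibrium alignment across the
    ensemble reaches ``threshold``.  Returns None when even ``f_hi``
    fails.  Each probe reuses the same seed substream sequence so the
    bisection responds to f only.
    """
    ss = np.random.SeedSequence(seed)

    def achieved(f: float) -> bool:
        if f > 0 and round(f * make_scenario(f).network["n"]) == 0:
            return False
        sc = make_scenario(f)
        ens = run_scenario(sc, seed=np.random.SeedSequence(ss.entropy, spawn_key=(0,)))
        med = np.median(
            [alignment_trajectory(t).global_alignment for t in ens.trajectories]
        )
        return bool(med >= threshold)

    if achieved(f_lo):
        return f_lo
    if not achieved(f_hi):
        return None
    lo, hi = f_lo, f_hi
    while hi - lo > tol_f:
        mid = 0.5 * (lo + hi)
        if achieved(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def meanfield_critical_for(scenario: Scenario, k: float, tol_f: float = 1e-3):
    """Mean-field critical anticonformist fraction matched to a fig2-style scenario.

    The base (f = 0) composition is the conformist half/half preference
    split; anticonformists mirror the preference split with w = -1.
    """
    base = MeanFieldModel(
        subpops=((0.5, 10.0, 1.0), (0.5, -10.0, 1.0)), k=k, beta=scenario.beta
    )
    anti = [(0.5, 10.0, -1.0), (0.5, -10.0, -1.0)]
    return critical_fraction(base, anti, tol_f=tol_f)


def bifurcation_scan(
    base: MeanFieldModel,
    anti,
    fractions,
) -> pd.DataFrame:
    """Fixed points and stability across an anticonformist-fraction grid."""
    from dissentnet.meanfield import find_fixed_points

    rows = []
    for f in fractions:
        model = with_anticonformists(base, f, anti)
        for fp in find_fixed_points(model):
            rows.append(
                {"f": f, "X_star": fp.X_star, "stability": fp.stability, "residual": fp.residual}
            )
    return pd.DataFrame(rows)
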