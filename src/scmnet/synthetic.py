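"""Synthetic classroom studies with controllable transitivity and report noise.

The generator plants, per classroom-wave, a "true" affiliative network whose
global transitivity is steered to a target by hill-climbing edge swaps, then
emits one noisy SCM-style report per participating perceiver:

* each true tie involving the perceiver is reported with ``p_hit_own``;
* each other true tie with ``p_hit_other`` — or, when the transitivity
  coupling ``(a, b)`` is enabled, with ``logistic(a + b * transitivity)``,
  so perceivers in more transitive classrooms see more of the network;
* each non-tie is reported with ``p_false``.

The perceived edge set is encoded back into groups as maximal cliques, which
makes generator → file → clique-expansion lossless.  ``p_hit_own`` is kept
separate from the coupling so the consensus (intersection-rule) network —
which only depends on reports about one's own ties — is unaffected by the
perception coupling.

Everything is reproducible from the single config seed, including the files
written to disk (byte-identical reruns).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io import GroupReport, Roster, encode_as_groups, write_edge_list, write_reports, write_roster
from .metrics import transitivity_index
from .network import AffiliativeNetwork

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "TransitivityTargetError",
    "generate_true_network",
    "evolve_network",
    "simulate_report",
    "simulate_study",
    "simulate_model_table",
]


class TransitivityTargetError(RuntimeError):
    """Hill-climbing could not reach the transitivity target within tolerance."""

    def __init__(self, target: float, best: float, tol: float, max_iter: int):
        self.target = target
        self.best = best
        super().__init__(
            f"could not reach transitivity {target:.3f} +/- {tol:.3f} within "
            f"{max_iter} swap attempts; best achieved {best:.3f}"
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level generator settings.

    Defaults emulate observed elementary/middle-school classroom studies:
    classrooms of ~20 members followed over 3 waves, classroom transitivity
    spread over roughly 0.3-0.8 and mean perceiver accuracy roughly 0.2-0.6.
    ``target_transitivity`` may be a single value or a (low, high) range
    sampled per classroom-wave.  ``coupling`` is (a, b) on the log-odds of
    ``p_hit_other``; set it to None to decouple perception quality from
    classroom structure.
    """

    n_classrooms: int = 12
    class_size: int = 20
    n_waves: int = 3
    edge_density: float = 0.15
    target_transitivity: float | tuple[float, float] = (0.35, 0.75)
    transitivity_tolerance: float = 0.03
    p_hit_own: float = 0.95
    p_hit_other: float = 0.60
    p_false: float = 0.02
    coupling: tuple[float, float] | None = (-1.3, 3.2)
    rewire_fraction: float = 0.2
    p_participate: float = 0.85
    max_iter: int = 30000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_hit_own", "p_hit_other", "p_false", "edge_density", "p_participate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_classrooms", "class_size", "n_waves", "max_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.transitivity_tolerance <= 0:
            raise ValueError("transitivity_tolerance must be > 0")
        if not 0.0 <= self.rewire_fraction <= 1.0:
            raise ValueError("rewire_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulatedStudy:
    """Planted truth record of one simulated study.

    ``planted`` holds the full planted network per (classroom_id, wave_id);
    downstream consensus recovery compares against its restriction to that
    wave's participants (non-participants contribute no reports).
    """

    config: SimulationConfig
    rosters: tuple[Roster, ...]
    reports: dict[tuple[str, int], tuple[GroupReport, ...]]
    planted: dict[tuple[str, int], AffiliativeNetwork]
    planted_transitivity: dict[tuple[str, int], float]

    def planted_participant_network(self, classroom_id: str, wave_id: int) -> AffiliativeNetwork:
        roster = next(
            r for r in self.rosters if r.classroom_id == classroom_id and r.wave_id == wave_id
        )
        return self.planted[(classroom_id, wave_id)].subgraph(roster.participants)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _graph_transitivity(g: nx.Graph) -> float:
    t = nx.transitivity(g)  # 0.0 when no connected triple exists
    return t


def _random_graph(nodes: list[str], n_edges: int, rng: np.random.Generator) -> nx.Graph:
    n = len(nodes)
    all_pairs = [(nodes[i], nodes[j]) for i in range(n) for j in range(i + 1, n)]
    idx = rng.choice(len(all_pairs), size=n_edges, replace=False)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(all_pairs[i] for i in idx)
    return g


def _propose_raise(g: nx.Graph, rng: np.random.Generator):
    """Close a random open two-path; pay by removing a random other edge."""
    centers = [n for n, d in g.degree() if d >= 2]
    if not centers:
        return None
    j = centers[rng.integers(len(centers))]
    nbrs = list(g.neighbors(j))
    a, b = rng.choice(len(nbrs), size=2, replace=False)
    i, k = nbrs[a], nbrs[b]
    if g.has_edge(i, k):
        return None
    edges = list(g.edges())
    drop = edges[rng.integers(len(edges))]
    if set(drop) == {i, k}:
        return None
    return drop, (i, k)


def _propose_lower(g: nx.Graph, rng: np.random.Generator):
    """Break a random triangle edge; pay by adding a random non-edge."""
    edges = list(g.edges())
    tri_edges = [e for e in edges if set(nx.common_neighbors(g, *e))]
    if not tri_edges:
        drop = edges[rng.integers(len(edges))]
    else:
        drop = tri_edges[rng.integers(len(tri_edges))]
    nodes = list(g.nodes())
    for _ in range(20):
        u, v = rng.choice(len(nodes), size=2, replace=False)
        u, v = nodes[u], nodes[v]
        if not g.has_edge(u, v) and set((u, v)) != set(drop):
            return drop, (u, v)
    return None


def _hill_climb(
    g: nx.Graph, target: float, tol: float, rng: np.random.Generator, max_iter: int
) -> nx.Graph:
    current = _graph_transitivity(g)
    best_gap = abs(current - target)
    if best_gap <= tol:
        return g
    for _ in range(max_iter):
        proposal = _propose_raise(g, rng) if current < target else _propose_lower(g, rng)
        if proposal is None:
            continue
        drop, add = proposal
        g.remove_edge(*drop)
        g.add_edge(*add)
        new = _graph_transitivity(g)
        if abs(new - target) < abs(current - target):
            current = new
            best_gap = min(best_gap, abs(current - target))
            if best_gap <= tol:
                return g
        else:
            g.remove_edge(*add)
            g.add_edge(*drop)
    raise TransitivityTargetError(target, current, tol, max_iter)


def generate_true_network(
    n: int,
    density: float,
    target_t: float,
    tol: float = 0.03,
    seed=0,
    max_iter: int = 30000,
    nodes: list[str] | None = None,
) -> AffiliativeNetwork:
    """Random simple graph at fixed edge count, steered to a transitivity target.

    Starts from a uniform random graph with ``round(density * n(n-1)/2)``
    edges and hill-climbs by edge swaps (close a two-path to raise the index,
    break a triangle to lower it), accepting only moves that shrink the gap
    to ``target_t``.  Edge count is preserved throughout.  Raises
    TransitivityTargetError (reporting the best value achieved) if the
    target is unreachable within ``max_iter`` attempts.
    """
    rng = _as_rng(seed)
    if nodes is None:
        nodes = [f"m{i:02d}" for i in range(n)]
    if len(nodes) != n:
        raise ValueError("nodes must have length n")
    n_edges = round(density * n * (n - 1) / 2)
    if n_edges < 1:
        raise ValueError("density too low: zero edges requested")
    g = _random_graph(nodes, n_edges, rng)
    g = _hill_climb(g, target_t, tol, rng, max_iter)
    return AffiliativeNetwork.from_networkx(g)


def evolve_network(
    network: AffiliativeNetwork,
    rewire_fraction: float,
    target_t: float,
    tol: float = 0.03,
    seed=0,
    max_iter: int = 30000,
) -> AffiliativeNetwork:
    """Rewire a fraction of edges, then re-steer transitivity to a new target.

    Edge count is preserved.  With ``rewire_fraction`` 0 and the current
    transitivity already within ``tol`` of ``target_t`` the input is
    returned unchanged.
    """
    rng = _as_rng(seed)
    g = network.to_networkx()
    n_rewire = math.ceil(rewire_fraction * g.number_of_edges())
    if n_rewire:
        edges = list(g.edges())
        idx = rng.choice(len(edges), size=n_rewire, replace=False)
        g.remove_edges_from(edges[i] for i in idx)
        nodes = sorted(g.nodes())
        non_edges = [
            (a, b)
            for i, a in enumerate(nodes)
            for b in nodes[i + 1 :]
            if not g.has_edge(a, b)
        ]
        add_idx = rng.choice(len(non_edges), size=n_rewire, replace=False)
        g.add_edges_from(non_edges[i] for i in add_idx)
    g = _hill_climb(g, target_t, tol, rng, max_iter)
    return AffiliativeNetwork.from_networkx(g)


def simulate_report(
    true: AffiliativeNetwork,
    perceiver: str,
    config: SimulationConfig,
    classroom_transitivity: float,
    seed=0,
) -> GroupReport:
    """One perceiver's noisy SCM report about the planted true network."""
    if perceiver not in true.nodes:
        raise ValueError(f"perceiver {perceiver!r} is not in the network")
    rng = _as_rng(seed)
    if config.coupling is not None:
        a, b = config.coupling
        p_other = _logistic(a + b * classroom_transitivity)
    else:
        p_other = config.p_hit_other

    nodes = sorted(true.nodes)
    edges = set()
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if true.has_edge(u, v):
                p = config.p_hit_own if perceiver in (u, v) else p_other
            else:
                p = config.p_false
            if p > 0 and rng.random() < p:
                edges.add((u, v))
    perceived = AffiliativeNetwork(nodes=frozenset(nodes), edges=frozenset(edges))
    report = encode_as_groups(perceived)
    return dataclasses.replace(report, perceiver=perceiver)


def _wave_target(config: SimulationConfig, rng: np.random.Generator) -> float:
    t = config.target_transitivity
    if isinstance(t, (tuple, list)):
        low, high = t
        return float(rng.uniform(low, high))
    return float(t)


def simulate_study(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedStudy:
    """Simulate a full multi-classroom, multi-wave study.

    Per classroom: a wave-0 planted network steered to a sampled transitivity
    target, evolved wave to wave by rewiring and re-targeting; per wave, a
    participation draw and one noisy report per participant.  With
    ``out_dir`` set, writes ``roster.csv``, per-classroom-wave report JSONs,
    planted-truth edge lists and a ``truth.json`` record, all byte-stable
    for a fixed config.
    """
    rng = _as_rng(config.seed)
    rosters: list[Roster] = []
    reports: dict[tuple[str, int], tuple[GroupReport, ...]] = {}
    planted: dict[tuple[str, int], AffiliativeNetwork] = {}
    planted_t: dict[tuple[str, int], float] = {}

    for c in range(config.n_classrooms):
        cid = f"c{c:02d}"
        members = [f"{cid}s{i:02d}" for i in range(config.class_size)]
        network: AffiliativeNetwork | None = None
        for w in range(config.n_waves):
            target = _wave_target(config, rng)
            if network is None:
                network = generate_true_network(
                    config.class_size,
                    config.edge_density,
                    target,
                    tol=config.transitivity_tolerance,
                    seed=rng,
                    max_iter=config.max_iter,
                    nodes=members,
                )
            else:
                network = evolve_network(
                    network,
                    config.rewire_fraction,
                    target,
                    tol=config.transitivity_tolerance,
                    seed=rng,
                    max_iter=config.max_iter,
                )
            t_value = transitivity_index(network)
            participating = [m for m in members if rng.random() < config.p_participate]
            if len(participating) < 2:
                participating = members[:2]
            roster = Roster(
                classroom_id=cid,
                wave_id=w,
                members=frozenset(members),
                participants=frozenset(participating),
            )
            wave_reports = tuple(
                simulate_report(network, perceiver, config, t_value, seed=rng)
                for perceiver in sorted(participating)
            )
            rosters.append(roster)
            reports[(cid, w)] = wave_reports
            planted[(cid, w)] = network
            planted_t[(cid, w)] = t_value

    study = SimulatedStudy(
        config=config,
        rosters=tuple(rosters),
        reports=reports,
        planted=planted,
        planted_transitivity=planted_t,
    )
    if out_dir is not None:
        _write_study(study, Path(out_dir))
    return study


def _write_study(study: SimulatedStudy, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    write_roster(list(study.rosters), out_dir / "roster.csv")
    for (cid, wid), wave_reports in sorted(study.reports.items()):
        write_reports(list(wave_reports), cid, wid, out_dir / f"reports_{cid}_w{wid}.json")
    for (cid, wid), network in sorted(study.planted.items()):
        write_edge_list(network, truth_dir / f"planted_{cid}_w{wid}.tsv")
    record = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(study.config).items()
        },
        "planted_transitivity": {
            f"{cid}:{wid}": t for (cid, wid), t in sorted(study.planted_transitivity.items())
        },
    }
    (truth_dir / "truth.json").write_text(
        json.dumps(record, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def simulate_model_table(
    n_participants: int = 150,
    n_waves: int = 3,
    beta: tuple[float, float, float, float] = (0.1, 0.0, 0.5, 0.5),
    sigma2_intercept: float = 0.01,
    sigma2_residual: float = 0.01,
    classroom_size: int = 20,
    t0_range: tuple[float, float] = (0.3, 0.8),
    change_sd: float = 0.10,
    seed=0,
):
    """Simulate the participant-wave table directly from the linear model.

    Used for parameter-recovery and null-calibration experiments: classroom
    baseline transitivity is uniform on ``t0_range``, wave deviations are
    normal with sd ``change_sd`` (zero at wave 0) and shared within
    classroom, and accuracy follows the random-intercept model exactly.
    Returns a table in the layout ``assemble_long_table`` produces.
    """
    import pandas as pd

    rng = _as_rng(seed)
    b0, b1, b2, b3 = beta
    n_classrooms = math.ceil(n_participants / classroom_size)
    class_t0 = rng.uniform(*t0_range, size=n_classrooms)
    class_change = np.zeros((n_classrooms, n_waves))
    if n_waves > 1:
        class_change[:, 1:] = rng.normal(0.0, change_sd, size=(n_classrooms, n_waves - 1))
    u = rng.normal(0.0, math.sqrt(sigma2_intercept), size=n_participants)

    rows = []
    for i in range(n_participants):
        c = i % n_classrooms
        t0 = class_t0[c]
        for w in range(n_waves):
            change = class_change[c, w]
            eps = rng.normal(0.0, math.sqrt(sigma2_residual))
            rows.append(
                {
                    "participant": f"p{i:04d}",
                    "classroom_id": f"c{c:02d}",
                    "wave_id": w,
                    "time": w,
                    "accuracy": b0 + b1 * w + b2 * t0 + b3 * change + u[i] + eps,
                    "transitivity": t0 + change,
                    "transitivity_t0": t0,
                    "transitivity_change": change,
                }
            )
    return pd.DataFrame(rows)
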