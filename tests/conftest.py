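import itertools

import networkx as nx
import numpy as np
import pytest

from scmnet import AffiliativeNetwork, GroupReport, Roster


def random_network(n: int, p: float, rng: np.random.Generator) -> AffiliativeNetwork:
    """Erdos–Renyi simple graph over string-labelled nodes."""
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = [
        (a, b) for a, b in itertools.combinations(nodes, 2) if rng.random() < p
    ]
    return AffiliativeNetwork.from_edges(edges, nodes=nodes)


def brute_force_triads(network: AffiliativeNetwork) -> tuple[int, int]:
    """Classify every unordered triple by edge count: (triangles, two-paths)."""
    triangles = two_paths = 0
    for triple in itertools.combinations(sorted(network.nodes), 3):
        k = sum(network.has_edge(a, b) for a, b in itertools.combinations(triple, 2))
        if k == 3:
            triangles += 1
        elif k == 2:
            two_paths += 1
    return triangles, two_paths


@pytest.fixture
def roster_abc() -> Roster:
    return Roster(
        classroom_id="c1",
        wave_id=0,
        members=frozenset("ABCDEF"),
        participants=frozenset("ABCDE"),
    )


@pytest.fixture
def report_groups(roster_abc) -> GroupReport:
    return GroupReport(perceiver="A", groups=(frozenset("ABC"), frozenset("DE")), isolates=frozenset("F"))


def networkx_roundtrip(network: AffiliativeNetwork) -> nx.Graph:
    return network.to_networkx()
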