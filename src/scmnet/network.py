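"""Undirected simple-graph container for classroom affiliative ties.

An affiliative network is a simple undirected graph over a fixed set of
member identifiers.  Identifiers are opaque strings; edges are stored as
canonical (lexicographically sorted) pairs so that two networks over the
same ties compare equal regardless of construction order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

__all__ = ["AffiliativeNetwork", "canonical_edge"]


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in canonical sorted form.

    Raises ValueError for a self-loop, which has no meaning in an
    affiliative network.
    """
    if a == b:
        raise ValueError(f"self-loop on node {a!r} is not a valid tie")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class AffiliativeNetwork:
    """A simple undirected graph over classroom member identifiers.

    Parameters
    ----------
    nodes
        Member identifiers in the network (isolates included).
    edges
        Unordered ties; stored canonically, duplicates collapse.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        nodes = frozenset(str(n) for n in self.nodes)
        edges = frozenset(canonical_edge(str(a), str(b)) for a, b in self.edges)
        for a, b in edges:
            if a not in nodes or b not in nodes:
                raise ValueError(f"edge ({a!r}, {b!r}) has an endpoint outside the node set")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "AffiliativeNetwork":
        """Build a network from an edge iterable; `nodes` may add isolates."""
        edge_set = frozenset(canonical_edge(str(a), str(b)) for a, b in edges)
        node_set = frozenset(str(n) for n in nodes) | {n for e in edge_set for n in e}
        return cls(nodes=node_set, edges=edge_set)

    @classmethod
    def from_networkx(cls, graph: nx.Graph) -> "AffiliativeNetwork":
        return cls.from_edges(
            ((str(a), str(b)) for a, b in graph.edges()),
            nodes=(str(n) for n in graph.nodes()),
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_edge(a, b) in self.edges

    def degree(self, node: str) -> int:
        if node not in self.nodes:
            raise KeyError(f"node {node!r} not in network")
        return sum(node in e for e in self.edges)

    def isolates(self) -> frozenset[str]:
        """Nodes with no incident tie."""
        touched = {n for e in self.edges for n in e}
        return self.nodes - touched

    def subgraph(self, keep: Iterable[str]) -> "AffiliativeNetwork":
        """Restrict to `keep`: drop other nodes and any edge touching them."""
        keep_set = frozenset(str(n) for n in keep)
        return AffiliativeNetwork(
            nodes=self.nodes & keep_set,
            edges=frozenset(e for e in self.edges if e[0] in keep_set and e[1] in keep_set),
        )
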