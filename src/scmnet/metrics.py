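"""Perception-accuracy and transitivity indices.

Accuracy of one perceiver against the consensus ("true") network:

    precision = |depicted ∩ true| / |depicted|
    coverage  = |depicted ∩ true| / |true|
    accuracy  = precision × coverage

Accuracy is 1 exactly when the perceiver depicts all true ties and nothing
else; it falls when true ties are omitted (coverage) or spurious ties are
depicted (precision).  A perceiver who depicts nothing gets accuracy 0
(flagged): they identified no relationship at all, which is the index's
floor, not an error.

Classroom transitivity is the global clustering coefficient of the true
network: 3T / (3T + P) with T the number of triangles (transitive triads)
and P the number of open two-paths — the probability that a connected
triple of members is closed.  With no connected triples the index carries
no information and is recorded as missing (NaN), not 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .network import AffiliativeNetwork

__all__ = [
    "AccuracyRecord",
    "TransitivityRecord",
    "precision",
    "coverage",
    "accuracy_index",
    "score_perceiver",
    "transitive_triad_count",
    "two_path_count",
    "transitivity_index",
    "score_classroom",
    "UndefinedCoverageError",
]


class UndefinedCoverageError(ValueError):
    """Coverage has no denominator: the true network has zero edges."""


@dataclass(frozen=True)
class AccuracyRecord:
    """Per perceiver-wave accuracy components and index."""

    perceiver: str
    classroom_id: str
    wave_id: int
    n_depicted: int
    n_correct: int
    n_true: int
    precision: float
    coverage: float
    accuracy: float
    zero_depicted: bool = False  # flagged: perceiver identified nothing


@dataclass(frozen=True)
class TransitivityRecord:
    """Per classroom-wave triad counts and transitivity index (NaN if undefined)."""

    classroom_id: str
    wave_id: int
    n_transitive_triads: int
    n_two_paths: int
    transitivity: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.transitivity)


def _check_same_nodes(perceived: AffiliativeNetwork, true: AffiliativeNetwork) -> None:
    if perceived.nodes != true.nodes:
        raise ValueError(
            "perceived and true networks must share a node set "
            f"(symmetric difference: {sorted(perceived.nodes ^ true.nodes)})"
        )


def precision(perceived: AffiliativeNetwork, true: AffiliativeNetwork) -> float:
    """Fraction of depicted ties that are true; 0.0 when nothing is depicted.

    The 0/0 case is resolved to 0.0 by the zero-depicted convention so that
    a perceiver who identifies nothing scores the index's floor rather than
    being dropped.
    """
    _check_same_nodes(perceived, true)
    if not perceived.edges:
        return 0.0
    return len(perceived.edges & true.edges) / len(perceived.edges)


def coverage(perceived: AffiliativeNetwork, true: AffiliativeNetwork) -> float:
    """Fraction of true ties the perceiver depicted."""
    _check_same_nodes(perceived, true)
    if not true.edges:
        raise UndefinedCoverageError(
            "coverage undefined: the true network has no edges; "
            "exclude this classroom-wave from accuracy scoring"
        )
    return len(perceived.edges & true.edges) / len(true.edges)


def accuracy_index(perceived: AffiliativeNetwork, true: AffiliativeNetwork) -> float:
    """Precision × coverage on unrounded components."""
    return precision(perceived, true) * coverage(perceived, true)


def score_perceiver(
    perceiver: str,
    classroom_id: str,
    wave_id: int,
    perceived: AffiliativeNetwork,
    true: AffiliativeNetwork,
) -> AccuracyRecord:
    """Build the full AccuracyRecord for one perceiver-wave."""
    _check_same_nodes(perceived, true)
    if not true.edges:
        raise UndefinedCoverageError(
            f"classroom {classroom_id!r} wave {wave_id}: true network has no edges"
        )
    n_depicted = len(perceived.edges)
    n_correct = len(perceived.edges & true.edges)
    n_true = len(true.edges)
    prec = n_correct / n_depicted if n_depicted else 0.0
    cov = n_correct / n_true
    return AccuracyRecord(
        perceiver=perceiver,
        classroom_id=classroom_id,
        wave_id=wave_id,
        n_depicted=n_depicted,
        n_correct=n_correct,
        n_true=n_true,
        precision=prec,
        coverage=cov,
        accuracy=prec * cov,
        zero_depicted=n_depicted == 0,
    )


def transitive_triad_count(network: AffiliativeNetwork) -> int:
    """Number of unordered member triples with all three ties present (triangles)."""
    g = network.to_networkx()
    import networkx as nx

    return sum(nx.triangles(g).values()) // 3


def two_path_count(network: AffiliativeNetwork) -> int:
    """Number of unordered triples with exactly two ties (open two-paths).

    Counted as connected triples centred at each node, C(deg, 2) summed over
    nodes, minus the three closed triples each triangle contributes.
    """
    g = network.to_networkx()
    connected_triples = sum(d * (d - 1) // 2 for _, d in g.degree())
    return connected_triples - 3 * transitive_triad_count(network)


def transitivity_index(network: AffiliativeNetwork) -> float:
    """3T / (3T + P); NaN when the network has no connected triple."""
    t = transitive_triad_count(network)
    p = two_path_count(network)
    denom = 3 * t + p
    if denom == 0:
        return math.nan
    return 3 * t / denom


def score_classroom(
    classroom_id: str, wave_id: int, true: AffiliativeNetwork
) -> TransitivityRecord:
    """Build the TransitivityRecord of a classroom-wave's true network."""
    t = transitive_triad_count(true)
    p = two_path_count(true)
    denom = 3 * t + p
    return TransitivityRecord(
        classroom_id=classroom_id,
        wave_id=wave_id,
        n_transitive_triads=t,
        n_two_paths=p,
        transitivity=(3 * t / denom) if denom else math.nan,
    )
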