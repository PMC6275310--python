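"""Participation filtering and the intersection-rule consensus network.

The "true" affiliative network of a classroom is built by the locally
aggregate structures intersection rule: a tie {i, j} exists if and only if
both i's own report and j's own report depict it.  Third-party reports of a
dyad are irrelevant to its truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import GroupReport, Roster, expand_report
from .network import AffiliativeNetwork, canonical_edge

__all__ = [
    "ClassroomWaveData",
    "participation_rate",
    "filter_eligible",
    "intersection_true_network",
    "build_classroom_wave",
    "DEFAULT_PARTICIPATION_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_PARTICIPATION_THRESHOLD = 0.60


@dataclass(frozen=True)
class ClassroomWaveData:
    """One classroom-wave: roster, SCM reports, and perceived networks.

    ``perceived`` maps each reporting participant to the clique expansion of
    their report; all perceived networks share the node set
    ``roster.participants``.
    """

    roster: Roster
    reports: tuple[GroupReport, ...]
    perceived: dict[str, AffiliativeNetwork]

    def __post_init__(self) -> None:
        reporters = {r.perceiver for r in self.reports}
        if set(self.perceived) != reporters:
            raise ValueError("perceived must have exactly one entry per reporting participant")
        for who, net in self.perceived.items():
            if net.nodes != self.roster.participants:
                raise ValueError(
                    f"perceived network of {who!r} is not over the roster participants"
                )


def build_classroom_wave(roster: Roster, reports: list[GroupReport]) -> ClassroomWaveData:
    """Expand each report over the roster and bundle the classroom-wave."""
    perceived = {r.perceiver: expand_report(r, roster) for r in reports}
    return ClassroomWaveData(roster=roster, reports=tuple(reports), perceived=perceived)


def participation_rate(roster: Roster) -> float:
    """Fraction of classroom members who completed an SCM report."""
    if not roster.members:
        raise ValueError(
            f"classroom {roster.classroom_id!r} wave {roster.wave_id}: empty roster"
        )
    return len(roster.participants) / len(roster.members)


def filter_eligible(
    classroom_waves: list[ClassroomWaveData],
    threshold: float = DEFAULT_PARTICIPATION_THRESHOLD,
) -> list[ClassroomWaveData]:
    """Keep classroom-waves with participation rate strictly above `threshold`.

    The inequality is strict: a classroom at exactly the threshold is
    excluded.  Exclusions are logged with the offending rate.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    kept = []
    for cw in classroom_waves:
        rate = participation_rate(cw.roster)
        if rate > threshold:
            kept.append(cw)
        else:
            logger.info(
                "excluding classroom %s wave %d: participation rate %.3f <= %.2f",
                cw.roster.classroom_id,
                cw.roster.wave_id,
                rate,
                threshold,
            )
    return kept


def intersection_true_network(data: ClassroomWaveData) -> AffiliativeNetwork:
    """Consensus network over participants: a tie holds iff both endpoints report it.

    Every participant must have a perceived network; a participant without
    one cannot corroborate any of their dyads, so the input is rejected
    rather than silently treated as all-absent.
    """
    participants = data.roster.participants
    missing = participants - set(data.perceived)
    if missing:
        raise ValueError(
            f"classroom {data.roster.classroom_id!r} wave {data.roster.wave_id}: "
            f"participants without a perceived network: {sorted(missing)}"
        )
    edges = set()
    for i in participants:
        for edge in data.perceived[i].edges:
            a, b = edge
            j = b if a == i else a if b == i else None
            if j is None:
                continue  # third-party report: not evidence for the dyad
            if canonical_edge(i, j) in data.perceived[j].edges:
                edges.add(edge)
    return AffiliativeNetwork(nodes=participants, edges=frozenset(edges))
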