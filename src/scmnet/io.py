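"""Reading and writing rosters, Social Cognitive Map reports, and edge lists.

File formats
------------
Roster: UTF-8 CSV with header ``classroom_id,wave_id,member_id,participated``,
one row per classroom-wave-member, ``participated`` coded 0/1.

Report: JSON, a list of records, each with keys ``classroom_id``, ``wave_id``,
``perceiver``, ``groups`` (list of lists of member ids) and ``isolates``
(list of member ids).  One record per perceiver: the groups of classmates the
perceiver says hang around together, plus the classmates the perceiver says
belong to no group.

Edge list: two-column TSV with header ``node_a\tnode_b``, endpoints of each
edge in lexicographic order, lines sorted — byte-identical for equal networks.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx

from .network import AffiliativeNetwork

__all__ = [
    "Roster",
    "GroupReport",
    "read_roster",
    "write_roster",
    "read_reports",
    "write_reports",
    "expand_report",
    "encode_as_groups",
    "write_edge_list",
    "read_edge_list",
]

ROSTER_COLUMNS = ("classroom_id", "wave_id", "member_id", "participated")
EDGE_LIST_HEADER = "node_a\tnode_b"


@dataclass(frozen=True)
class Roster:
    """Membership of one classroom at one wave.

    ``participants`` is the subset of ``members`` who completed an SCM report
    at this wave; only their relational data enter any downstream computation.
    """

    classroom_id: str
    wave_id: int
    members: frozenset[str]
    participants: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(str(m) for m in self.members))
        object.__setattr__(self, "participants", frozenset(str(p) for p in self.participants))
        extra = self.participants - self.members
        if extra:
            raise ValueError(
                f"classroom {self.classroom_id!r} wave {self.wave_id}: "
                f"participants not in members: {sorted(extra)}"
            )


@dataclass(frozen=True)
class GroupReport:
    """One perceiver's Social Cognitive Map: listed groups plus isolates.

    Every listed group has at least two members; a classmate the perceiver
    places in no group is an isolate.  No member appears both in a group and
    as an isolate.
    """

    perceiver: str
    groups: tuple[frozenset[str], ...]
    isolates: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        groups = tuple(frozenset(str(m) for m in g) for g in self.groups)
        isolates = frozenset(str(m) for m in self.isolates)
        for g in groups:
            if len(g) < 2:
                raise ValueError(
                    f"perceiver {self.perceiver!r}: group {sorted(g)} has fewer than 2 "
                    "members; record a singleton as an isolate instead"
                )
        grouped = frozenset().union(*groups) if groups else frozenset()
        overlap = grouped & isolates
        if overlap:
            raise ValueError(
                f"perceiver {self.perceiver!r}: members both grouped and isolate: "
                f"{sorted(overlap)}"
            )
        object.__setattr__(self, "perceiver", str(self.perceiver))
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "isolates", isolates)

    def mentioned(self) -> frozenset[str]:
        out = frozenset(self.isolates)
        for g in self.groups:
            out |= g
        return out


class FormatError(ValueError):
    """A roster or report file violates its format contract."""


def read_roster(path: str | Path) -> list[Roster]:
    """Parse a roster CSV into one Roster per (classroom_id, wave_id).

    Identifiers are kept verbatim as strings.  A malformed row or a member
    listed twice within a classroom-wave raises FormatError naming the line.
    """
    path = Path(path)
    grouped: dict[tuple[str, int], dict[str, bool]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return []
        if tuple(h.strip() for h in header) != ROSTER_COLUMNS:
            raise FormatError(
                f"{path}: expected header {','.join(ROSTER_COLUMNS)}, got {','.join(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            classroom_id, wave_raw, member_id, part_raw = (f.strip() for f in row)
            try:
                wave_id = int(wave_raw)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: wave_id {wave_raw!r} is not an integer")
            if part_raw not in {"0", "1"}:
                raise FormatError(f"{path}:{lineno}: participated must be 0 or 1, got {part_raw!r}")
            if not member_id:
                raise FormatError(f"{path}:{lineno}: empty member_id")
            key = (classroom_id, wave_id)
            members = grouped.setdefault(key, {})
            if member_id in members:
                raise FormatError(
                    f"{path}:{lineno}: member {member_id!r} listed twice in "
                    f"classroom {classroom_id!r} wave {wave_id}"
                )
            members[member_id] = part_raw == "1"
    return [
        Roster(
            classroom_id=cid,
            wave_id=wid,
            members=frozenset(members),
            participants=frozenset(m for m, p in members.items() if p),
        )
        for (cid, wid), members in sorted(grouped.items())
    ]


def write_roster(rosters: list[Roster], path: str | Path) -> None:
    """Write rosters in the CSV dialect read_roster accepts (sorted, stable)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(ROSTER_COLUMNS)
        for roster in sorted(rosters, key=lambda r: (r.classroom_id, r.wave_id)):
            for member in sorted(roster.members):
                writer.writerow(
                    [
                        roster.classroom_id,
                        roster.wave_id,
                        member,
                        int(member in roster.participants),
                    ]
                )


def read_reports(path: str | Path, roster: Roster) -> list[GroupReport]:
    """Parse report JSON records for one classroom-wave, validated against `roster`.

    Every identifier must resolve against ``roster.members`` and every
    perceiver must be in ``roster.participants``.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        try:
            records = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(records, list):
        raise FormatError(f"{path}: expected a JSON list of report records")
    reports = []
    for record in records:
        cid = str(record.get("classroom_id", ""))
        wid = record.get("wave_id")
        if cid != roster.classroom_id or int(wid) != roster.wave_id:
            continue
        perceiver = str(record["perceiver"])
        if perceiver not in roster.participants:
            raise FormatError(
                f"{path}: perceiver {perceiver!r} is not a participant of "
                f"classroom {roster.classroom_id!r} wave {roster.wave_id}"
            )
        try:
            report = GroupReport(
                perceiver=perceiver,
                groups=tuple(frozenset(str(m) for m in g) for g in record.get("groups", [])),
                isolates=frozenset(str(m) for m in record.get("isolates", [])),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        unknown = report.mentioned() - roster.members
        if unknown:
            raise FormatError(
                f"{path}: perceiver {perceiver!r} names unknown member(s) "
                f"{sorted(unknown)} not on the roster"
            )
        reports.append(report)
    return reports


def write_reports(
    reports: list[GroupReport], classroom_id: str, wave_id: int, path: str | Path
) -> None:
    """Write reports as the JSON record list read_reports accepts (deterministic)."""
    records = [
        {
            "classroom_id": classroom_id,
            "wave_id": wave_id,
            "perceiver": r.perceiver,
            "groups": [sorted(g) for g in sorted(r.groups, key=sorted)],
            "isolates": sorted(r.isolates),
        }
        for r in sorted(reports, key=lambda r: r.perceiver)
    ]
    Path(path).write_text(json.dumps(records, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def expand_report(report: GroupReport, roster: Roster) -> AffiliativeNetwork:
    """Clique-expand a group report into the perceiver's perceived network.

    Each listed group implies ties among all pairs of its members.  Nodes are
    the roster's participants; pairs with a non-participant endpoint are
    dropped, and isolates contribute no edges.  Overlapping groups union at
    the edge level.
    """
    unknown = report.mentioned() - roster.members
    if unknown:
        raise ValueError(
            f"perceiver {report.perceiver!r} names members not on the roster: {sorted(unknown)}"
        )
    participants = roster.participants
    edges = {
        (a, b) if a < b else (b, a)
        for group in report.groups
        for a, b in combinations(sorted(group), 2)
        if a in participants and b in participants
    }
    return AffiliativeNetwork(nodes=participants, edges=frozenset(edges))


def encode_as_groups(network: AffiliativeNetwork) -> GroupReport:
    """Encode a network as an SCM-style report: maximal cliques + isolates.

    The maximal cliques (each of size >= 2) cover every edge, so expanding the
    result reproduces the network exactly (lossless round trip).  The
    perceiver slot is filled with a placeholder; callers relabel it.
    """
    g = network.to_networkx()
    cliques = tuple(
        frozenset(c) for c in sorted(
            (sorted(c) for c in nx.find_cliques(g) if len(c) >= 2)
        )
    )
    return GroupReport(perceiver="__encoded__", groups=cliques, isolates=network.isolates())


def write_edge_list(network: AffiliativeNetwork, path: str | Path) -> None:
    """Write a canonical TSV edge list; equal networks yield identical bytes."""
    lines = [EDGE_LIST_HEADER]
    lines += [f"{a}\t{b}" for a, b in sorted(network.edges)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_edge_list(path: str | Path, nodes: frozenset[str] | None = None) -> AffiliativeNetwork:
    """Read a TSV edge list written by write_edge_list."""
    text = Path(path).read_text(encoding="utf-8").splitlines()
    if not text or text[0] != EDGE_LIST_HEADER:
        raise FormatError(f"{path}: missing edge-list header {EDGE_LIST_HEADER!r}")
    edges = []
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        edges.append((parts[0], parts[1]))
    return AffiliativeNetwork.from_edges(edges, nodes=nodes or ())
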