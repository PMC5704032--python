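"""Equivalence matching of CNVs and SVs across samples.

Two interval events are "the same" when they satisfy a 50% *reciprocal*
overlap: the shared length must be at least half of each event's own
length, so a small event buried in a large one does not match.
Interchromosomal events match when origin and destination chromosomes
agree and both junction positions are less than 500 bp apart (strict).
Inversions must additionally share their direction.  Matching is only
ever attempted within one category, and CNVs must agree in copy
direction (amp vs del).

Because >=50% reciprocal overlap is not transitive, matched events are
merged into groups as connected components of the pairwise match graph
(the merged-group semantics of interval-merging CNV tools).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx

from .callsets import CnvCall, SvEvent
from .errors import ContractViolation

Event = CnvCall | SvEvent


@dataclass(frozen=True)
class OverlapResult:
    """Reciprocal overlap of two intervals: the overlap length as a
    fraction of each interval's own length."""

    fraction_a: float
    fraction_b: float
    matched: bool


def reciprocal_overlap(
    interval_a: tuple[str, int, int],
    interval_b: tuple[str, int, int],
    threshold: float = 0.5,
) -> OverlapResult:
    """Reciprocal-overlap test of two 0-based half-open intervals.

    ``matched`` requires BOTH fractions to reach ``threshold``;
    intervals on different chromosomes never overlap.
    """
    chrom_a, start_a, end_a = interval_a
    chrom_b, start_b, end_b = interval_b
    len_a = end_a - start_a
    len_b = end_b - start_b
    if len_a <= 0 or len_b <= 0:
        raise ValueError("zero- or negative-length interval")
    if chrom_a != chrom_b:
        return OverlapResult(0.0, 0.0, False)
    overlap = max(0, min(end_a, end_b) - max(start_a, start_b))
    fa = overlap / len_a
    fb = overlap / len_b
    return OverlapResult(fa, fb, min(fa, fb) >= threshold)


def match_interchromosomal(
    event_a: SvEvent, event_b: SvEvent, max_dist: int = 500
) -> bool:
    """Interchromosomal events are the same iff origin and destination
    chromosomes match and both junction distances are < ``max_dist``
    (strict)."""
    if event_a.category != "interchromosomal" or event_b.category != "interchromosomal":
        raise ContractViolation("both events must be interchromosomal")
    (ca1, pa1), (ca2, pa2) = event_a.junctions
    (cb1, pb1), (cb2, pb2) = event_b.junctions
    if (ca1, ca2) != (cb1, cb2):
        return False
    return abs(pa1 - pb1) < max_dist and abs(pa2 - pb2) < max_dist


def match_inversion(
    inv_a: SvEvent, inv_b: SvEvent, threshold: float = 0.5
) -> bool:
    """Inversions are shared iff they have the same direction and at
    least ``threshold`` reciprocal positional overlap (inclusive)."""
    if inv_a.category != "inversion" or inv_b.category != "inversion":
        raise ContractViolation("both events must be inversions")
    if inv_a.orientation != inv_b.orientation:
        return False
    return reciprocal_overlap(inv_a.interval, inv_b.interval, threshold).matched


def event_category(event: Event) -> str:
    """Matching category of an event; CNV copy direction is part of the
    category so an amplification never matches a deletion."""
    if isinstance(event, CnvCall):
        return f"cnv_{event.cnv_type}"
    return f"sv_{event.category}"


def events_match(
    event_a: Event,
    event_b: Event,
    threshold: float = 0.5,
    junction_max_dist: int = 500,
) -> bool:
    """Category-dispatched pairwise equivalence test.  Events of
    different categories never match."""
    if event_category(event_a) != event_category(event_b):
        return False
    if isinstance(event_a, SvEvent):
        if event_a.category == "interchromosomal":
            return match_interchromosomal(event_a, event_b, junction_max_dist)
        if event_a.category == "inversion":
            return match_inversion(event_a, event_b, threshold)
    return reciprocal_overlap(
        event_a.interval, event_b.interval, threshold
    ).matched


@dataclass
class MatchGroup:
    """A merged group: one connected component of the pairwise match
    graph, all members of one category."""

    category: str
    members: list[Event]

    @property
    def sample_ids(self) -> set[str]:
        return {e.sample_id for e in self.members}


def build_match_groups(
    events: Sequence[Event],
    threshold: float = 0.5,
    junction_max_dist: int = 500,
) -> list[MatchGroup]:
    """Group all samples' events of one category into merged groups.

    All events must belong to a single matching category; an event that
    matches nothing forms a singleton group.  Pairwise comparisons are
    restricted to same-chromosome candidates, then connected components
    of the match graph are taken (the relation is not transitive, so a
    chain A~B~C merges even when A and C do not match directly).
    """
    if not events:
        return []
    categories = {event_category(e) for e in events}
    if len(categories) > 1:
        raise ContractViolation(
            f"build_match_groups takes one category at a time, got {sorted(categories)}"
        )
    category = categories.pop()
    graph = nx.Graph()
    graph.add_nodes_from(range(len(events)))
    for i, j in combinations(range(len(events)), 2):
        if events_match(events[i], events[j], threshold, junction_max_dist):
            graph.add_edge(i, j)
    groups = []
    for component in nx.connected_components(graph):
        members = [events[i] for i in sorted(component)]
        groups.append(MatchGroup(category=category, members=members))
    groups.sort(key=lambda g: (g.members[0].chrom, g.members[0].start))
    return groups


def _has_match(
    event: Event,
    pool: Sequence[Event],
    threshold: float,
    junction_max_dist: int,
) -> bool:
    return any(
        events_match(event, other, threshold, junction_max_dist) for other in pool
    )


@dataclass(frozen=True)
class ClassifiedEvent:
    """A CNV/SV event with sharing and origin labels (same vocabulary as
    small variants)."""

    event: Event
    sharing: str
    origin: str


def classify_event_inheritance(
    twin_events: Sequence[Event],
    cotwin_events: Sequence[Event],
    father_events: Sequence[Event] | None,
    mother_events: Sequence[Event] | None,
    threshold: float = 0.5,
    junction_max_dist: int = 500,
) -> list[ClassifiedEvent]:
    """Label one twin's events shared/unshared against the co-twin and,
    when parents are given, inherited/de novo against the parents.

    An event is *shared* when it matches any co-twin event of the same
    category; an unshared event is *inherited* when it matches an event
    in at least one parent and *de_novo* otherwise.  With
    ``father_events`` and ``mother_events`` both ``None`` (twin-only
    mode) unshared events are labelled *provisional_de_novo*.
    """
    if (father_events is None) != (mother_events is None):
        raise ContractViolation("parents must be both given or both absent")
    parents_present = father_events is not None
    parent_pool = list(father_events or []) + list(mother_events or [])
    out = []
    for event in twin_events:
        shared = _has_match(event, cotwin_events, threshold, junction_max_dist)
        if shared:
            sharing, origin = "shared", "not_applicable"
        elif parents_present:
            inherited = _has_match(event, parent_pool, threshold, junction_max_dist)
            sharing, origin = "unshared", ("inherited" if inherited else "de_novo")
        else:
            sharing, origin = "unshared", "provisional_de_novo"
        out.append(ClassifiedEvent(event=event, sharing=sharing, origin=origin))
    return out


def event_summary(classified: Sequence[ClassifiedEvent]) -> dict:
    """Count matrix for one sample's events, mirroring the shared/
    unshared x inherited/de-novo report layout."""
    n_shared = sum(1 for c in classified if c.sharing == "shared")
    n_unshared = len(classified) - n_shared
    counts = {
        "total": len(classified),
        "shared": n_shared,
        "unshared": n_unshared,
    }
    for origin in ("inherited", "de_novo", "provisional_de_novo"):
        n = sum(1 for c in classified if c.origin == origin)
        counts[origin] = n
    return counts
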