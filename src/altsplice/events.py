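"""Alternative-splicing event detection on splicing graphs.

Each event is a local subgraph motif reported as a *mini-gene*: two splice
variants (ordered exon lists) that share their outermost flanking coordinates
and differ in the diagnostic introns between them.  Supported types:

====================  ======================================================
exon_skip             cassette exon included or skipped between two flanks
intron_retention      intron spliced out or retained inside one exon
alt_3prime            competing acceptor sites, overlapping target exons
alt_5prime            competing donor sites, overlapping source exons
mutex_exons           two non-overlapping exons that never co-occur
mult_exon_skip        a run of >= 2 consecutive exons skipped together
====================  ======================================================

Alternative transcript starts/ends are products of transcriptional rather
than splicing regulation and are deliberately not detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

from .model import GenomicInterval, SplicingGraph, implied_intron

log = logging.getLogger(__name__)

__all__ = [
    "ASEvent",
    "EVENT_TYPES",
    "detect_exon_skips",
    "detect_intron_retention_events",
    "detect_alt_splice_sites",
    "detect_mutex_exons",
    "detect_mult_exon_skips",
    "detect_events",
    "merge_events",
]

EVENT_TYPES = (
    "exon_skip",
    "intron_retention",
    "alt_3prime",
    "alt_5prime",
    "mutex_exons",
    "mult_exon_skip",
)

IntronSet = FrozenSet[Tuple[int, int]]


def _introns_of(exons: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    return [implied_intron(a, b) for a, b in zip(exons, exons[1:])]


@dataclass(frozen=True, slots=True)
class ASEvent:
    """A two-variant mini-gene describing one alternative-splicing event.

    ``variant1`` is the *inclusion* form by convention (cassette-containing,
    intron-retaining, longer-exon, or upstream-mutex variant); ``variant2``
    the exclusion form.  ``diagnostic_introns1/2`` are the intron coordinate
    pairs whose usage distinguishes the variants.
    """

    event_type: str
    gene_id: str
    chrom: str
    strand: str
    variant1: Tuple[GenomicInterval, ...]
    variant2: Tuple[GenomicInterval, ...]
    diagnostic_introns1: IntronSet
    diagnostic_introns2: IntronSet

    @property
    def introns1(self) -> List[GenomicInterval]:
        return _introns_of(self.variant1)

    @property
    def introns2(self) -> List[GenomicInterval]:
        return _introns_of(self.variant2)

    @property
    def diagnostic_introns(self) -> IntronSet:
        return self.diagnostic_introns1 | self.diagnostic_introns2

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.variant1[0].start, self.variant1[-1].end)

    def sort_key(self):
        return (self.event_type, sorted(self.diagnostic_introns),
                self.variant1, self.variant2)

    @property
    def event_id(self) -> str:
        first = min(self.diagnostic_introns)
        return f"{self.gene_id}.{self.event_type}.{first[0]}_{first[1]}"


def _shared_flanks(exons1: Sequence[GenomicInterval],
                   exons2: Sequence[GenomicInterval]
                   ) -> Tuple[Tuple[GenomicInterval, ...],
                              Tuple[GenomicInterval, ...]] | None:
    """Trim both variants' outer flanks to their intersection.

    The internal boundaries (those adjacent to introns) are fixed by the
    event; only the outermost start and end may differ between the exons the
    variants were built from.  Returns None when an intersection is empty.
    """
    v1, v2 = list(exons1), list(exons2)
    start = max(v1[0].start, v2[0].start)
    end = min(v1[-1].end, v2[-1].end)
    if start > v1[0].end or start > v2[0].end:
        return None
    if end < v1[-1].start or end < v2[-1].start:
        return None
    for v in (v1, v2):
        v[0] = GenomicInterval(start, v[0].end)
        v[-1] = GenomicInterval(v[-1].start, end)
    return tuple(v1), tuple(v2)


def _make_event(event_type: str, graph: SplicingGraph,
                inclusion: Sequence[GenomicInterval],
                exclusion: Sequence[GenomicInterval],
                diag1: Iterable[GenomicInterval],
                diag2: Iterable[GenomicInterval]) -> ASEvent | None:
    flanked = _shared_flanks(inclusion, exclusion)
    if flanked is None:
        return None
    v1, v2 = flanked
    if v1 == v2:
        return None
    return ASEvent(
        event_type=event_type,
        gene_id=graph.gene_id,
        chrom=graph.chrom,
        strand=graph.strand,
        variant1=v1,
        variant2=v2,
        diagnostic_introns1=frozenset((i.start, i.end) for i in diag1),
        diagnostic_introns2=frozenset((i.start, i.end) for i in diag2),
    )


def detect_exon_skips(graph: SplicingGraph) -> List[ASEvent]:
    """One event per triple e1 -> e2 -> e3 that also has the skip edge e1 -> e3."""
    events: List[ASEvent] = []
    for e1, e3 in sorted(graph.edges):
        for e2 in graph.out_nodes(e1):
            if e2 == e3 or not graph.has_edge(e2, e3):
                continue
            inc = [e1, e2, e3]
            exc = [e1, e3]
            ev = _make_event("exon_skip", graph, inc, exc,
                             _introns_of(inc), _introns_of(exc))
            if ev is not None:
                events.append(ev)
    return sorted(set(events), key=ASEvent.sort_key)


def detect_intron_retention_events(graph: SplicingGraph) -> List[ASEvent]:
    """One event per edge whose intron lies inside some (retention) node."""
    events: List[ASEvent] = []
    nodes = graph.nodes
    for v_s, v_t in sorted(graph.edges):
        intron = implied_intron(v_s, v_t)
        if not any(w.start <= v_s.end and w.end >= v_t.start for w in nodes):
            continue
        retained = [GenomicInterval(v_s.start, v_t.end)]
        spliced = [v_s, v_t]
        ev = _make_event("intron_retention", graph, retained, spliced,
                         [intron], [intron])
        if ev is not None:
            events.append(ev)
    return sorted(set(events), key=ASEvent.sort_key)


def detect_alt_splice_sites(graph: SplicingGraph,
                            strand: str | None = None) -> List[ASEvent]:
    """Events from edge pairs sharing one intron boundary, differing at the other.

    The two exons at the varying side must overlap (non-overlapping exons are
    the territory of the skip/mutex types).  Labelling is strand-aware: a
    varying intron *end* is the acceptor on '+' (alt 3') and the donor on '-'
    (alt 5'); a varying intron *start* the reverse.
    """
    strand = strand or graph.strand
    events: List[ASEvent] = []
    by_start: Dict[int, List[Tuple[GenomicInterval, GenomicInterval]]] = {}
    by_end: Dict[int, List[Tuple[GenomicInterval, GenomicInterval]]] = {}
    for u, v in sorted(graph.edges):
        intron = implied_intron(u, v)
        by_start.setdefault(intron.start, []).append((u, v))
        by_end.setdefault(intron.end, []).append((u, v))
    # varying acceptor (intron end differs, start shared)
    for start, pairs in sorted(by_start.items()):
        for (u1, v1), (u2, v2) in _pairs(pairs):
            if v1.start == v2.start or not v1.overlaps(v2):
                continue
            label = "alt_3prime" if strand == "+" else "alt_5prime"
            long_first = (u1, v1) if v1.start < v2.start else (u2, v2)
            short = (u2, v2) if long_first == (u1, v1) else (u1, v1)
            ev = _make_event(label, graph, list(long_first), list(short),
                             [implied_intron(*long_first)],
                             [implied_intron(*short)])
            if ev is not None:
                events.append(ev)
    # varying donor (intron start differs, end shared)
    for end, pairs in sorted(by_end.items()):
        for (u1, v1), (u2, v2) in _pairs(pairs):
            if u1.end == u2.end or not u1.overlaps(u2):
                continue
            label = "alt_5prime" if strand == "+" else "alt_3prime"
            long_first = (u1, v1) if u1.end > u2.end else (u2, v2)
            short = (u2, v2) if long_first == (u1, v1) else (u1, v1)
            ev = _make_event(label, graph, list(long_first), list(short),
                             [implied_intron(*long_first)],
                             [implied_intron(*short)])
            if ev is not None:
                events.append(ev)
    return sorted(set(events), key=ASEvent.sort_key)


def _pairs(items):
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            yield items[i], items[j]


def detect_mutex_exons(graph: SplicingGraph) -> List[ASEvent]:
    """Events from quadruples e1 -> {e2 | e3} -> e4 with e2, e3 exclusive.

    e2 and e3 must not overlap and must not be joined by a direct edge;
    longer connecting paths do not disqualify the motif (locality).
    """
    events: List[ASEvent] = []
    for e1 in graph.nodes:
        mids = graph.out_nodes(e1)
        for e2, e3 in _pairs(mids):
            if e2.overlaps(e3):
                continue
            lo, hi = sorted((e2, e3))
            if graph.has_edge(lo, hi):
                continue
            targets = set(graph.out_nodes(lo)) & set(graph.out_nodes(hi))
            for e4 in sorted(targets):
                inc = [e1, lo, e4]   # upstream exon = inclusion convention
                exc = [e1, hi, e4]
                ev = _make_event("mutex_exons", graph, inc, exc,
                                 _introns_of(inc), _introns_of(exc))
                if ev is not None:
                    events.append(ev)
    return sorted(set(events), key=ASEvent.sort_key)


def detect_mult_exon_skips(graph: SplicingGraph,
                           max_skipped: int = 5) -> List[ASEvent]:
    """Events where a chain of 2..max_skipped exons is skipped in one piece."""
    if max_skipped < 2:
        raise ValueError("max_skipped must be >= 2")
    events: List[ASEvent] = []
    for e_a, e_b in sorted(graph.edges):
        stack: List[List[GenomicInterval]] = [[m] for m in graph.out_nodes(e_a)
                                              if m != e_b and m.end < e_b.start]
        while stack:
            path = stack.pop()
            tail = path[-1]
            if len(path) >= 2 and graph.has_edge(tail, e_b):
                inc = [e_a, *path, e_b]
                exc = [e_a, e_b]
                ev = _make_event("mult_exon_skip", graph, inc, exc,
                                 _introns_of(inc), _introns_of(exc))
                if ev is not None:
                    events.append(ev)
            if len(path) < max_skipped:
                for nxt in graph.out_nodes(tail):
                    if nxt != e_b and nxt.end < e_b.start:
                        stack.append(path + [nxt])
    return sorted(set(events), key=ASEvent.sort_key)


def detect_events(graph: SplicingGraph,
                  event_types: Sequence[str] = EVENT_TYPES,
                  max_skipped: int = 5) -> List[ASEvent]:
    """Run the selected detectors and return the merged, sorted event list."""
    detectors = {
        "exon_skip": lambda g: detect_exon_skips(g),
        "intron_retention": lambda g: detect_intron_retention_events(g),
        "alt_3prime": lambda g: [e for e in detect_alt_splice_sites(g)
                                 if e.event_type == "alt_3prime"],
        "alt_5prime": lambda g: [e for e in detect_alt_splice_sites(g)
                                 if e.event_type == "alt_5prime"],
        "mutex_exons": lambda g: detect_mutex_exons(g),
        "mult_exon_skip": lambda g: detect_mult_exon_skips(g, max_skipped),
    }
    events: List[ASEvent] = []
    for etype in EVENT_TYPES:
        if etype in event_types:
            events.extend(detectors[etype](graph))
    return merge_events(events)


def merge_events(events: Iterable[ASEvent]) -> List[ASEvent]:
    """Collapse events identical up to outer flank extent.

    Events of the same type and gene with identical diagnostic intron sets
    differ only in how far their outermost exons extend; they merge into one
    event whose flanks are the intersection of all inputs' flanks.  An empty
    intersection keeps the events separate.
    """
    groups: Dict[tuple, List[ASEvent]] = {}
    for ev in events:
        key = (ev.gene_id, ev.event_type, ev.diagnostic_introns1,
               ev.diagnostic_introns2)
        groups.setdefault(key, []).append(ev)
    merged: List[ASEvent] = []
    for key, group in groups.items():
        group = sorted(set(group), key=ASEvent.sort_key)
        base = group[0]
        for other in group[1:]:
            v1 = _merge_variant(base.variant1, other.variant1)
            v2 = _merge_variant(base.variant2, other.variant2)
            if v1 is None or v2 is None:
                log.warning("%s: empty flank intersection, events kept apart",
                            base.gene_id)
                merged.append(other)
                continue
            base = ASEvent(base.event_type, base.gene_id, base.chrom,
                           base.strand, v1, v2,
                           base.diagnostic_introns1, base.diagnostic_introns2)
        merged.append(base)
    return sorted(set(merged), key=ASEvent.sort_key)


def _merge_variant(a: Tuple[GenomicInterval, ...],
                   b: Tuple[GenomicInterval, ...]
                   ) -> Tuple[GenomicInterval, ...] | None:
    if len(a) != len(b):
        return None
    out = list(a)
    start = max(a[0].start, b[0].start)
    end = min(a[-1].end, b[-1].end)
    if start > a[0].end or end < a[-1].start or start > end:
        return None
    out[0] = GenomicInterval(start, out[0].end)
    out[-1] = GenomicInterval(out[-1].start, end)
    return tuple(out)
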