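"""Gene, transcript and graph model.

Genes are modelled as collections of transcripts, each transcript an ordered
list of exon intervals.  Collapsing the transcripts of a gene yields the
*splicing graph*: a DAG whose nodes are distinct exons (identified by their
genomic coordinates) and whose directed edges are introns.  For read counting
the splicing graph is decomposed into the *segment graph*: maximal
non-overlapping exonic segments such that every exon is an exact concatenation
of consecutive segments, so no genomic position is ever quantified twice.

All coordinates are 1-based and inclusive on both ends.  Conversion from the
0-based half-open convention of BAM happens once, at the alignment I/O
boundary (:mod:`altsplice.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

__all__ = [
    "GenomicInterval",
    "Transcript",
    "Gene",
    "SplicingGraph",
    "SegmentGraph",
    "MalformedAnnotationError",
    "build_splicing_graph",
    "classify_terminals",
    "build_segment_graph",
]

ANNOTATED = "annotated"
NOVEL = "novel"


class MalformedAnnotationError(ValueError):
    """Raised when an annotation violates the gene/transcript/exon contract."""


@dataclass(frozen=True, order=True, slots=True)
class GenomicInterval:
    """A 1-based, both-ends-inclusive genomic interval.

    Ordering is lexicographic by ``(start, end)``, which is the node order
    used throughout the graph algorithms.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        s, e = max(self.start, other.start), min(self.end, other.end)
        return GenomicInterval(s, e) if s <= e else None


# Intron implied between two consecutive exons: first and last intronic base.
def implied_intron(left: GenomicInterval, right: GenomicInterval) -> GenomicInterval:
    return GenomicInterval(left.end + 1, right.start - 1)


@dataclass(slots=True)
class Transcript:
    """An ordered chain of non-overlapping exons."""

    id: str
    exons: List[GenomicInterval]

    def validate(self) -> None:
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end + 1:
                raise MalformedAnnotationError(
                    f"transcript {self.id!r}: exons {a} and {b} overlap, are "
                    "unsorted, or leave no intron between them"
                )

    @property
    def introns(self) -> List[GenomicInterval]:
        return [implied_intron(a, b) for a, b in zip(self.exons, self.exons[1:])]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.exons[0].start, self.exons[-1].end)


@dataclass(slots=True)
class Gene:
    id: str
    chrom: str
    strand: str
    transcripts: List[Transcript] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return GenomicInterval(start, end)


Edge = Tuple[GenomicInterval, GenomicInterval]


class SplicingGraph:
    """Per-gene DAG: exon nodes, intron edges, with annotated/novel origins.

    Node identity is the coordinate pair; edges always point from lower to
    higher coordinates, so the graph is acyclic by construction.
    """

    def __init__(self, gene_id: str = "", chrom: str = "", strand: str = "+"):
        self.gene_id = gene_id
        self.chrom = chrom
        self.strand = strand
        self.node_origin: Dict[GenomicInterval, str] = {}
        self.edge_origin: Dict[Edge, str] = {}

    # -- accessors -------------------------------------------------------
    @property
    def nodes(self) -> List[GenomicInterval]:
        return sorted(self.node_origin)

    @property
    def edges(self) -> Set[Edge]:
        return set(self.edge_origin)

    def has_node(self, v: GenomicInterval) -> bool:
        return v in self.node_origin

    def has_edge(self, u: GenomicInterval, v: GenomicInterval) -> bool:
        return (u, v) in self.edge_origin

    def in_nodes(self, v: GenomicInterval) -> List[GenomicInterval]:
        return sorted(u for (u, w) in self.edge_origin if w == v)

    def out_nodes(self, v: GenomicInterval) -> List[GenomicInterval]:
        return sorted(w for (u, w) in self.edge_origin if u == v)

    def intron_of(self, edge: Edge) -> GenomicInterval:
        return implied_intron(*edge)

    @property
    def introns(self) -> Dict[GenomicInterval, Edge]:
        """Map intron interval -> one edge realising it (sorted tie-break)."""
        out: Dict[GenomicInterval, Edge] = {}
        for edge in sorted(self.edge_origin):
            out.setdefault(self.intron_of(edge), edge)
        return out

    # -- mutation --------------------------------------------------------
    def add_node(self, v: GenomicInterval, origin: str = ANNOTATED) -> bool:
        if v in self.node_origin:
            return False
        self.node_origin[v] = origin
        return True

    def add_edge(self, u: GenomicInterval, v: GenomicInterval,
                 origin: str = ANNOTATED) -> bool:
        if u.end + 1 >= v.start:
            raise ValueError(f"edge {u}->{v} leaves no intron of length >= 1")
        if u not in self.node_origin or v not in self.node_origin:
            raise KeyError(f"edge {u}->{v} references unknown node")
        if (u, v) in self.edge_origin:
            return False
        self.edge_origin[(u, v)] = origin
        return True

    def remove_edge(self, u: GenomicInterval, v: GenomicInterval) -> None:
        self.edge_origin.pop((u, v), None)

    def remove_node(self, v: GenomicInterval) -> None:
        self.node_origin.pop(v, None)
        for edge in [e for e in self.edge_origin if v in e]:
            del self.edge_origin[edge]

    def copy(self) -> "SplicingGraph":
        g = SplicingGraph(self.gene_id, self.chrom, self.strand)
        g.node_origin = dict(self.node_origin)
        g.edge_origin = dict(self.edge_origin)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SplicingGraph):
            return NotImplemented
        return (self.node_origin.keys() == other.node_origin.keys()
                and self.edge_origin.keys() == other.edge_origin.keys())

    def __repr__(self) -> str:
        return (f"SplicingGraph({self.gene_id!r}, nodes={len(self.node_origin)}, "
                f"edges={len(self.edge_origin)})")


@dataclass(slots=True)
class SegmentGraph:
    """Non-overlapping exonic segments plus intron connectivity.

    ``composition`` maps every splicing-graph node to the ordered run of
    segment indices whose concatenation reproduces the node exactly.
    ``seg_edges`` holds index pairs (a, b): segment *a* is the last segment of
    some node u, segment *b* the first segment of some node v, and (u, v) is
    an edge of the splicing graph.
    """

    segments: List[GenomicInterval]
    seg_edges: Set[Tuple[int, int]]
    composition: Dict[GenomicInterval, List[int]]

    def segments_of(self, node: GenomicInterval) -> List[GenomicInterval]:
        return [self.segments[i] for i in self.composition[node]]


def build_splicing_graph(gene: Gene) -> SplicingGraph:
    """Collapse a gene's transcripts into its splicing graph.

    Exons shared between transcripts become a single node; consecutive exon
    pairs within each transcript become directed intron edges.  Everything is
    flagged ``annotated``.
    """
    if not gene.transcripts or any(not t.exons for t in gene.transcripts):
        raise MalformedAnnotationError(
            f"gene {gene.id!r} needs >= 1 transcript with >= 1 exon")
    graph = SplicingGraph(gene.id, gene.chrom, gene.strand)
    for tx in gene.transcripts:
        tx.validate()
        for exon in tx.exons:
            graph.add_node(exon, ANNOTATED)
        for a, b in zip(tx.exons, tx.exons[1:]):
            graph.add_edge(a, b, ANNOTATED)
    return graph


def classify_terminals(graph: SplicingGraph) -> Dict[GenomicInterval, str]:
    """Classify nodes by degree: start/end terminal, internal or isolated."""
    indeg = {v: 0 for v in graph.node_origin}
    outdeg = {v: 0 for v in graph.node_origin}
    for u, v in graph.edge_origin:
        outdeg[u] += 1
        indeg[v] += 1
    out: Dict[GenomicInterval, str] = {}
    for v in graph.node_origin:
        if indeg[v] == 0 and outdeg[v] == 0:
            out[v] = "isolated"
        elif indeg[v] == 0:
            out[v] = "start_terminal"
        elif outdeg[v] == 0:
            out[v] = "end_terminal"
        else:
            out[v] = "internal"
    return out


def build_segment_graph(graph: SplicingGraph) -> SegmentGraph:
    """Decompose a splicing graph into its segment graph.

    Breakpoints are every node start and every node end + 1; segments are the
    exon-covered stretches between consecutive breakpoints.  This realises the
    cumulative start/end-array construction on inclusive coordinates without
    double-booking boundary bases.
    """
    nodes = graph.nodes
    if not nodes:
        raise ValueError("cannot build a segment graph from an empty graph")
    breaks = sorted({v.start for v in nodes} | {v.end + 1 for v in nodes})
    # exon-covered <=> number of starts seen so far exceeds number of closed ends
    starts = sorted(v.start for v in nodes)
    ends = sorted(v.end + 1 for v in nodes)
    segments: List[GenomicInterval] = []
    import bisect
    for left, right in zip(breaks, breaks[1:]):
        n_open = bisect.bisect_right(starts, left)
        n_closed = bisect.bisect_right(ends, left)
        if n_open > n_closed:
            segments.append(GenomicInterval(left, right - 1))
    seg_start = {s.start: i for i, s in enumerate(segments)}
    composition: Dict[GenomicInterval, List[int]] = {}
    for v in nodes:
        run: List[int] = []
        i = seg_start[v.start]
        while i < len(segments) and segments[i].end <= v.end:
            run.append(i)
            i += 1
        composition[v] = run
    seg_edges = {
        (composition[u][-1], composition[v][0]) for (u, v) in graph.edge_origin
    }
    return SegmentGraph(segments, seg_edges, composition)
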