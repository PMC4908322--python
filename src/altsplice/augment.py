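"""RNA-Seq driven augmentation of annotation splicing graphs.

The annotation-derived graph G is enriched into an augmented graph Ghat using
intron junctions and exonic read coverage observed in one or more alignment
samples.  Augmentation is a four-step procedure:

1. build the initial graph from the annotation (:func:`altsplice.model.build_splicing_graph`)
2. add novel cassette exons supported by pairs of junctions
3. add novel intron retentions supported by intronic coverage
4. insert novel intron edges, iterating until no further edge can be added

Whenever a newly added node shares a boundary with an existing node, the
existing node's edges at that boundary are inherited by the new node.
Augmentation is monotone: annotated nodes and edges are never removed.  An
optional cross-sample pruning step afterwards removes edges that too few
samples support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import (
    ANNOTATED,
    NOVEL,
    Edge,
    Gene,
    GenomicInterval,
    SplicingGraph,
    implied_intron,
)

log = logging.getLogger(__name__)

__all__ = [
    "IntronJunction",
    "JunctionFilter",
    "RetentionCriteria",
    "CoverageTrack",
    "CONFIDENCE_PRESETS",
    "extract_junctions",
    "add_cassette_exons",
    "add_intron_retentions",
    "insert_intron_edges",
    "augment_graph",
    "prune_graph",
]


@dataclass(frozen=True, slots=True)
class IntronJunction:
    """One distinct spliced-alignment gap: first/last intronic base, 1-based."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    read_count: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"junction end {self.end} < start {self.start}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, slots=True)
class JunctionFilter:
    """Per-read and per-junction confidence thresholds for splice junctions."""

    min_anchor_len: int = 3
    max_mismatches: float = 3
    min_junction_reads: int = 1
    min_intron_len: int = 30
    max_intron_len: int = 350_000
    require_primary_unique: bool = True

    def __post_init__(self) -> None:
        if self.min_intron_len > self.max_intron_len:
            raise ValueError("min_intron_len > max_intron_len")
        if min(self.min_anchor_len, self.min_junction_reads,
               self.min_intron_len) < 0 or self.max_mismatches < 0:
            raise ValueError("junction-filter thresholds must be >= 0")


#: Tiered stringency presets 0 (permissive) .. 3 (strict):
#: (min_anchor_len, max_mismatches, min_junction_reads).
CONFIDENCE_PRESETS: Dict[int, JunctionFilter] = {
    0: JunctionFilter(1, float("inf"), 1),
    1: JunctionFilter(3, 3, 1),
    2: JunctionFilter(5, 2, 2),
    3: JunctionFilter(8, 1, 2),
}


@dataclass(frozen=True, slots=True)
class RetentionCriteria:
    """Evidence thresholds for calling an intron retained.

    An intron is retained when a fraction >= ``min_covered_fraction`` of its
    positions have coverage >= ``position_cov_threshold``, its mean coverage
    is >= ``min_intron_mean_cov``, and the smaller flanking-exon mean exceeds
    the intron mean by at most a factor ``max_exon_intron_ratio``.
    """

    min_covered_fraction: float = 0.9
    position_cov_threshold: int = 1
    min_intron_mean_cov: float = 5.0
    max_exon_intron_ratio: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_covered_fraction <= 1.0:
            raise ValueError("min_covered_fraction must be in [0, 1]")


class CoverageTrack:
    """Per-position read coverage over a gene span (1-based inclusive)."""

    def __init__(self, span: GenomicInterval, depth: Optional[np.ndarray] = None):
        self.span = span
        if depth is None:
            depth = np.zeros(span.length, dtype=np.int64)
        if len(depth) != span.length:
            raise ValueError("coverage length must equal span length")
        self.depth = np.asarray(depth)

    def add_block(self, start: int, end: int, count: int = 1) -> None:
        """Add coverage for the 1-based inclusive block [start, end]."""
        lo = max(start, self.span.start) - self.span.start
        hi = min(end, self.span.end) - self.span.start + 1
        if lo < hi:
            self.depth[lo:hi] += count

    def slice(self, interval: GenomicInterval) -> np.ndarray:
        lo = max(interval.start, self.span.start) - self.span.start
        hi = min(interval.end, self.span.end) - self.span.start + 1
        return self.depth[lo:max(lo, hi)]

    def mean(self, interval: GenomicInterval) -> float:
        values = self.slice(interval)
        return float(values.mean()) if values.size else 0.0

    def covered_fraction(self, interval: GenomicInterval, threshold: int) -> float:
        values = self.slice(interval)
        if values.size == 0:
            return 0.0
        return float((values >= threshold).mean())


# ---------------------------------------------------------------------------
# junction extraction
# ---------------------------------------------------------------------------

def _read_gaps(read) -> List[Tuple[int, int, int, int]]:
    """(gap_start_1b, gap_end_1b, left_anchor, right_anchor) per N op."""
    import pysam  # local import keeps pysam optional for pure-graph use

    ref = read.reference_start  # 0-based
    gaps: List[Tuple[int, int, int, int]] = []
    anchors: List[int] = [0]  # aligned ref-lengths between gaps
    bounds: List[Tuple[int, int]] = []
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            anchors[-1] += length
            ref += length
        elif op == 2:  # D consumes reference but is not an anchor break
            ref += length
        elif op == 3:  # N
            bounds.append((ref + 1, ref + length))  # 1-based inclusive
            anchors.append(0)
            ref += length
        # I, S, H, P consume no reference
    for i, (gs, ge) in enumerate(bounds):
        gaps.append((gs, ge, anchors[i], anchors[i + 1]))
    return gaps


def _read_passes(read, flt: JunctionFilter) -> bool:
    if read.is_unmapped:
        return False
    if flt.require_primary_unique:
        if read.is_secondary or read.is_supplementary:
            return False
        if read.mapping_quality == 0:
            return False
    if flt.max_mismatches != float("inf"):
        try:
            nm = read.get_tag("NM")
        except KeyError:
            nm = 0
        if nm > flt.max_mismatches:
            return False
    return True


def extract_junctions(alignments, region: "GeneRegion | tuple",
                      flt: JunctionFilter) -> List[IntronJunction]:
    """Collect filtered intron junctions overlapping a gene region.

    ``alignments`` is an open :class:`pysam.AlignmentFile` (indexed,
    coordinate-sorted); ``region`` is ``(chrom, span)`` with a 1-based
    inclusive span.  Each distinct gap coordinate pair becomes one
    :class:`IntronJunction` whose ``read_count`` is the number of supporting
    reads that pass the per-read filters; junctions below
    ``min_junction_reads`` or outside the intron-length bounds are dropped.
    """
    chrom, span = region
    counts: Dict[Tuple[int, int], int] = {}
    try:
        it = alignments.fetch(chrom, span.start - 1, span.end)
    except ValueError as exc:
        raise ValueError(
            f"alignment file must be coordinate-sorted and indexed: {exc}"
        ) from exc
    for read in it:
        if not _read_passes(read, flt):
            continue
        for gs, ge, left, right in _read_gaps(read):
            if left < flt.min_anchor_len or right < flt.min_anchor_len:
                continue
            counts[(gs, ge)] = counts.get((gs, ge), 0) + 1
    out = []
    for (gs, ge), n in sorted(counts.items()):
        length = ge - gs + 1
        if n < flt.min_junction_reads:
            continue
        if not flt.min_intron_len <= length <= flt.max_intron_len:
            continue
        out.append(IntronJunction(chrom, gs, ge, ".", n))
    return out


def coverage_from_alignments(alignments, chrom: str, span: GenomicInterval,
                             flt: JunctionFilter) -> CoverageTrack:
    """Per-position aligned-base coverage over ``span`` (gaps contribute 0)."""
    track = CoverageTrack(span)
    for read in alignments.fetch(chrom, span.start - 1, span.end):
        if not _read_passes(read, flt):
            continue
        for b0, b1 in read.get_blocks():  # 0-based half-open aligned blocks
            track.add_block(b0 + 1, b1)
    return track


# ---------------------------------------------------------------------------
# graph editing steps
# ---------------------------------------------------------------------------

def _inherit_boundary_edges(graph: SplicingGraph, new_node: GenomicInterval) -> None:
    """New node sharing a boundary with an existing node inherits its edges.

    Sharing a start means inheriting that node's incoming edges; sharing an
    end means inheriting its outgoing edges (the shared splice site implies
    the same upstream/downstream connectivity).
    """
    for other in list(graph.node_origin):
        if other == new_node:
            continue
        if other.start == new_node.start:
            for u in graph.in_nodes(other):
                if u.end + 1 < new_node.start:
                    graph.add_edge(u, new_node, NOVEL)
        if other.end == new_node.end:
            for w in graph.out_nodes(other):
                if new_node.end + 1 < w.start:
                    graph.add_edge(new_node, w, NOVEL)


def add_cassette_exons(graph: SplicingGraph,
                       junctions: Sequence[IntronJunction],
                       coverage: Optional[CoverageTrack] = None,
                       min_covered_fraction: float = 0.9,
                       max_candidate_pairs: int = 10_000) -> SplicingGraph:
    """Add novel cassette exons implied by non-overlapping junction pairs.

    For junction pair (gi1, gj1), (gi2, gj2) with gj1 < gi2 the candidate
    cassette is (gj1+1, gi2-1).  It is added when (a) some node ends at
    gi1-1 and a later node starts at gj2+1 ("intron ends" condition) and (b)
    no node with exactly the candidate coordinates exists ("new exon"
    condition).  When a coverage track is supplied the candidate region must
    additionally be read-covered over >= ``min_covered_fraction`` of its
    positions — the confidence check that keeps junction pairs belonging to
    two different alternative paths from fabricating intron-spanning exons.
    """
    graph = graph.copy()
    ends = {v.end for v in graph.node_origin}
    juncs = sorted({(j.start, j.end) for j in junctions})
    n_pairs = 0
    for (gi1, gj1), (gi2, gj2) in combinations(juncs, 2):
        if gj1 + 1 >= gi2:  # need >= 1 exonic base between the introns
            continue
        n_pairs += 1
        if n_pairs > max_candidate_pairs:
            log.warning("%s: cassette candidate-pair cap reached", graph.gene_id)
            break
        if gi1 - 1 not in ends:
            continue
        left_nodes = [v for v in graph.node_origin if v.end == gi1 - 1]
        right_nodes = [v for v in graph.node_origin
                       if v.start == gj2 + 1 and any(u < v for u in left_nodes)]
        if not right_nodes:
            continue
        candidate = GenomicInterval(gj1 + 1, gi2 - 1)
        if graph.has_node(candidate):
            continue
        if coverage is not None and (
                coverage.covered_fraction(candidate, 1) < min_covered_fraction):
            continue
        graph.add_node(candidate, NOVEL)
        for vi in left_nodes:
            graph.add_edge(vi, candidate, NOVEL)
        for vj in right_nodes:
            graph.add_edge(candidate, vj, NOVEL)
        _inherit_boundary_edges(graph, candidate)
        ends.add(candidate.end)
    return graph


def add_intron_retentions(graph: SplicingGraph, coverage: CoverageTrack,
                          criteria: RetentionCriteria) -> SplicingGraph:
    """Add a retention node for every edge whose intron shows exonic-like coverage.

    The new node spans source start to target end and inherits all incoming
    edges of the source and all outgoing edges of the target.
    """
    graph = graph.copy()
    for edge in sorted(graph.edges):
        v_s, v_t = edge
        intron = implied_intron(v_s, v_t)
        if coverage.covered_fraction(
                intron, criteria.position_cov_threshold) < criteria.min_covered_fraction:
            continue
        intron_mean = coverage.mean(intron)
        if intron_mean < criteria.min_intron_mean_cov:
            continue
        flank_mean = min(coverage.mean(v_s), coverage.mean(v_t))
        if flank_mean > criteria.max_exon_intron_ratio * intron_mean:
            continue
        new_node = GenomicInterval(v_s.start, v_t.end)
        if graph.has_node(new_node):
            continue
        graph.add_node(new_node, NOVEL)
        for x in graph.in_nodes(v_s):
            graph.add_edge(x, new_node, NOVEL)
        for x in graph.out_nodes(v_t):
            graph.add_edge(new_node, x, NOVEL)
    return graph


def insert_intron_edges(graph: SplicingGraph,
                        junctions: Sequence[IntronJunction],
                        allow_unanchored: bool = False
                        ) -> Tuple[SplicingGraph, int]:
    """Insert supported intron edges, adding boundary-matched novel nodes.

    For each junction (gi, gj) four cases arise from whether gi-1 matches an
    existing node end and gj+1 an existing node start: both match -> add the
    missing edge; start only -> clip an exon overlapping gj+1 into a novel
    node (gj+1, w.end) inheriting w's outgoing edges; end only -> the mirror
    clip on the upstream side; neither -> skipped unless ``allow_unanchored``
    creates a two-sided clipped node when overlapping exons exist on both
    sides.  Returns the edited graph and the number of added nodes + edges.
    """
    graph = graph.copy()
    added = 0
    for j in sorted({(x.start, x.end) for x in junctions}):
        gi, gj = j
        left = sorted(v for v in graph.node_origin if v.end == gi - 1)
        right = sorted(v for v in graph.node_origin if v.start == gj + 1)
        if left and right:  # case (iv)
            for u in left:
                for v in right:
                    if u < v and not graph.has_edge(u, v):
                        graph.add_edge(u, v, NOVEL)
                        added += 1
        elif left and not right:  # case (ii)
            overlaps = [w for w in sorted(graph.node_origin)
                        if w.start <= gj + 1 <= w.end]
            for w in overlaps:
                vn = GenomicInterval(gj + 1, w.end)
                if not graph.has_node(vn):
                    graph.add_node(vn, NOVEL)
                    added += 1
                    for x in graph.out_nodes(w):
                        if graph.add_edge(vn, x, NOVEL):
                            added += 1
                for u in left:
                    if u < vn and not graph.has_edge(u, vn):
                        graph.add_edge(u, vn, NOVEL)
                        added += 1
        elif right and not left:  # case (iii)
            overlaps = [w for w in sorted(graph.node_origin)
                        if w.start <= gi - 1 <= w.end]
            for w in overlaps:
                vn = GenomicInterval(w.start, gi - 1)
                if not graph.has_node(vn):
                    graph.add_node(vn, NOVEL)
                    added += 1
                    for x in graph.in_nodes(w):
                        if graph.add_edge(x, vn, NOVEL):
                            added += 1
                for v in right:
                    if vn < v and not graph.has_edge(vn, v):
                        graph.add_edge(vn, v, NOVEL)
                        added += 1
        elif allow_unanchored:  # case (i), speculative
            ups = [w for w in sorted(graph.node_origin)
                   if w.start <= gi - 1 <= w.end]
            downs = [w for w in sorted(graph.node_origin)
                     if w.start <= gj + 1 <= w.end]
            for wu in ups:
                vu = GenomicInterval(wu.start, gi - 1)
                if not graph.has_node(vu):
                    graph.add_node(vu, NOVEL)
                    added += 1
                    for x in graph.in_nodes(wu):
                        if graph.add_edge(x, vu, NOVEL):
                            added += 1
                for wd in downs:
                    vd = GenomicInterval(gj + 1, wd.end)
                    if not graph.has_node(vd):
                        graph.add_node(vd, NOVEL)
                        added += 1
                        for x in graph.out_nodes(wd):
                            if graph.add_edge(vd, x, NOVEL):
                                added += 1
                    if vu < vd and not graph.has_edge(vu, vd):
                        graph.add_edge(vu, vd, NOVEL)
                        added += 1
    return graph, added


@dataclass(slots=True)
class SampleEvidence:
    """Junctions and exonic coverage of one alignment sample over one gene."""

    junctions: List[IntronJunction]
    coverage: CoverageTrack


def merge_junctions(per_sample: Sequence[Sequence[IntronJunction]]
                    ) -> List[IntronJunction]:
    """Union junction lists across samples, summing read counts."""
    counts: Dict[Tuple[str, int, int], int] = {}
    for sample in per_sample:
        for j in sample:
            key = (j.chrom, j.start, j.end)
            counts[key] = counts.get(key, 0) + j.read_count
    return [IntronJunction(c, s, e, ".", n)
            for (c, s, e), n in sorted(counts.items())]


def augment_graph(graph: SplicingGraph,
                  evidence: Sequence[SampleEvidence],
                  flt: JunctionFilter = CONFIDENCE_PRESETS[1],
                  retention: RetentionCriteria = RetentionCriteria(),
                  max_iterations: int = 5,
                  allow_unanchored: bool = False) -> SplicingGraph:
    """Run the full augmentation: cassettes, retentions, then edge insertion
    to fixpoint (or ``max_iterations``).  Evidence from multiple samples is
    merged before editing; the result is a supergraph of the input.
    """
    junctions = merge_junctions([ev.junctions for ev in evidence])
    junctions = [j for j in junctions
                 if flt.min_intron_len <= j.length <= flt.max_intron_len
                 and j.read_count >= flt.min_junction_reads]
    if evidence:
        span = evidence[0].coverage.span
        total = CoverageTrack(span)
        for ev in evidence:
            total.depth += ev.coverage.slice(span)
        mean_cov = CoverageTrack(span, total.depth / max(1, len(evidence)))
    else:
        mean_cov = None
    g = add_cassette_exons(graph, junctions, coverage=mean_cov,
                           min_covered_fraction=retention.min_covered_fraction)
    if mean_cov is not None:
        g = add_intron_retentions(g, mean_cov, retention)
    for it in range(max_iterations):
        g, added = insert_intron_edges(g, junctions, allow_unanchored)
        if added == 0:
            break
    else:
        g2, added = insert_intron_edges(g, junctions, allow_unanchored)
        if added:
            log.warning("%s: edge insertion did not reach fixpoint in %d "
                        "iterations", graph.gene_id, max_iterations)
        g = g2
    return g


def edge_sample_support(graph: SplicingGraph,
                        per_sample: Sequence[Sequence[IntronJunction]],
                        min_junction_reads: int = 1) -> Dict[Edge, int]:
    """Number of samples whose junctions support each edge's intron."""
    support = {edge: 0 for edge in graph.edges}
    for sample in per_sample:
        observed = {(j.start, j.end) for j in sample
                    if j.read_count >= min_junction_reads}
        for edge in support:
            intron = graph.intron_of(edge)
            if (intron.start, intron.end) in observed:
                support[edge] += 1
    return support


def prune_graph(graph: SplicingGraph, edge_support: Mapping[Edge, int],
                min_samples: int) -> SplicingGraph:
    """Drop edges below the sample-support threshold, then novel orphans.

    Only nodes *made* orphan by the edge removal are candidates: a novel node
    that never had an edge (a retention node in a two-exon gene, say) stays.
    Annotated nodes orphaned by pruning are always retained.
    ``min_samples = 0`` is the identity.
    """
    graph = graph.copy()
    if min_samples <= 0:
        return graph
    before = {v for edge in graph.edge_origin for v in edge}
    for edge in sorted(graph.edges):
        if edge_support.get(edge, 0) < min_samples:
            graph.remove_edge(*edge)
    connected = {v for edge in graph.edge_origin for v in edge}
    for v in list(graph.node_origin):
        if v in before and v not in connected and graph.node_origin[v] == NOVEL:
            graph.remove_node(v)
    return graph
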