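"""Read counting on the segment graph and event-level PSI quantification.

Counting happens once per sample on the segment graph, whose segments
partition exonic space, so no genomic position is piled up twice; exon and
event quantities are then derived by length-weighted combination.  For every
event and sample we report the mean coverage of each variant exon, the
spliced-alignment counts of the diagnostic introns, the percent-spliced-in
(PSI) value, and a confirmation flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .augment import (
    CoverageTrack,
    JunctionFilter,
    coverage_from_alignments,
    extract_junctions,
)
from .events import ASEvent
from .model import GenomicInterval, SegmentGraph, SplicingGraph

__all__ = [
    "SegmentCounts",
    "JunctionCounts",
    "EventQuantification",
    "segment_coverage",
    "junction_counts",
    "quantify_event",
    "compute_psi",
    "confirm_event",
    "quantify_sample",
]


@dataclass(slots=True)
class SegmentCounts:
    """Per-segment mean read coverage (fractional) and segment lengths."""

    means: np.ndarray
    lengths: np.ndarray
    segments: List[GenomicInterval]

    def interval_mean(self, interval: GenomicInterval) -> float:
        """Length-weighted mean coverage of any interval.

        Positions outside every segment (i.e. purely intronic ones) count as
        zero coverage, so the value equals the position-wise pileup mean.
        """
        total = 0.0
        for seg, mean in zip(self.segments, self.means):
            ov = seg.intersect(interval)
            if ov is not None:
                total += mean * ov.length
        return total / interval.length

    def node_mean(self, seg_graph: SegmentGraph, node: GenomicInterval) -> float:
        idx = seg_graph.composition[node]
        w = self.lengths[idx]
        return float(np.average(self.means[idx], weights=w))


JunctionCounts = Dict[Tuple[int, int], int]
"""Intron (start, end) -> number of supporting spliced alignments."""


def segment_coverage(alignments, seg_graph: SegmentGraph, chrom: str,
                     span: GenomicInterval,
                     flt: JunctionFilter = JunctionFilter()) -> SegmentCounts:
    """Mean aligned-base coverage per segment from an indexed alignment file."""
    track = coverage_from_alignments(alignments, chrom, span, flt)
    means = np.array([track.mean(s) for s in seg_graph.segments])
    lengths = np.array([s.length for s in seg_graph.segments])
    return SegmentCounts(means, lengths, list(seg_graph.segments))


def junction_counts(alignments, graph: SplicingGraph,
                    flt: JunctionFilter = JunctionFilter()) -> JunctionCounts:
    """Spliced-alignment counts for every intron realised by a graph edge."""
    span = GenomicInterval(min(v.start for v in graph.node_origin),
                           max(v.end for v in graph.node_origin))
    permissive = JunctionFilter(
        flt.min_anchor_len, flt.max_mismatches, 0,
        1, 10_000_000, flt.require_primary_unique)
    observed = {(j.start, j.end): j.read_count
                for j in extract_junctions(alignments, (graph.chrom, span),
                                           permissive)}
    counts: JunctionCounts = {}
    for intron in graph.introns:
        counts[(intron.start, intron.end)] = observed.get(
            (intron.start, intron.end), 0)
    return counts


@dataclass(slots=True)
class EventQuantification:
    """Per-sample quantification of one event."""

    event: ASEvent
    exon_means1: List[List[float]] = field(default_factory=list)  # per sample
    exon_means2: List[List[float]] = field(default_factory=list)
    inclusion_counts: List[List[float]] = field(default_factory=list)
    exclusion_counts: List[List[float]] = field(default_factory=list)
    psi: List[Optional[float]] = field(default_factory=list)
    confirmed: List[bool] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.psi)

    @property
    def event_confirmed(self) -> bool:
        return any(self.confirmed)

    def mean_psi(self, samples: Sequence[int] | None = None) -> Optional[float]:
        idx = range(self.n_samples) if samples is None else samples
        vals = [self.psi[i] for i in idx if self.psi[i] is not None]
        return float(np.mean(vals)) if vals else None


def _diagnostic_features(event: ASEvent, seg: SegmentCounts,
                         junc: JunctionCounts
                         ) -> Tuple[List[float], List[float]]:
    """Inclusion and exclusion diagnostic feature values for one sample.

    Junction-based features are spliced-alignment counts; the retained
    variant of an intron-retention event instead uses the mean intron
    coverage as a per-position pseudo-count comparable to junction depth.
    """
    if event.event_type == "intron_retention":
        (istart, iend), = event.diagnostic_introns2
        intron = GenomicInterval(istart, iend)
        inclusion = [seg.interval_mean(intron)]
        exclusion = [float(junc.get((istart, iend), 0))]
        return inclusion, exclusion
    inclusion = [float(junc.get(i, 0)) for i in sorted(event.diagnostic_introns1)]
    exclusion = [float(junc.get(i, 0)) for i in sorted(event.diagnostic_introns2)]
    return inclusion, exclusion


def compute_psi(event_type: str, inclusion_counts: Sequence[float],
                exclusion_counts: Sequence[float],
                min_total: float = 10.0) -> Optional[float]:
    """PSI = mean(inclusion) / (mean(inclusion) + mean(exclusion)).

    Returns None (undefined) when the summed evidence falls below
    ``min_total``.  Inclusion is the variant listed first in the event: the
    cassette-containing, retained, longer-exon or upstream-mutex form.
    """
    if any(c < 0 for c in inclusion_counts) or any(c < 0 for c in exclusion_counts):
        raise ValueError("diagnostic counts must be non-negative")
    inc = float(np.mean(inclusion_counts)) if inclusion_counts else 0.0
    exc = float(np.mean(exclusion_counts)) if exclusion_counts else 0.0
    if inc + exc < min_total or inc + exc == 0:
        return None
    return inc / (inc + exc)


def confirm_event(quant: EventQuantification, min_diag_count: float = 3.0,
                  min_exon_cov: float = 0.0) -> bool:
    """Re-evaluate per-sample confirmation flags; return event-level flag.

    A sample confirms an event when every diagnostic feature of *each*
    variant reaches ``min_diag_count`` (both alternatives observed) and each
    variant's exons reach ``min_exon_cov`` mean coverage.  The event is
    confirmed when at least one sample confirms it.
    """
    flags = []
    for s in range(quant.n_samples):
        ok = (all(c >= min_diag_count for c in quant.inclusion_counts[s])
              and all(c >= min_diag_count for c in quant.exclusion_counts[s]))
        if ok and min_exon_cov > 0:
            ok = (all(m >= min_exon_cov for m in quant.exon_means1[s])
                  and all(m >= min_exon_cov for m in quant.exon_means2[s]))
        flags.append(ok)
    quant.confirmed = flags
    return any(flags)


def quantify_event(event: ASEvent, seg_by_sample: Sequence[SegmentCounts],
                   junc_by_sample: Sequence[JunctionCounts],
                   min_total: float = 10.0,
                   min_diag_count: float = 3.0) -> EventQuantification:
    """Populate per-sample coverages, diagnostic counts, PSI and confirmation."""
    quant = EventQuantification(event)
    for seg, junc in zip(seg_by_sample, junc_by_sample):
        quant.exon_means1.append([seg.interval_mean(e) for e in event.variant1])
        quant.exon_means2.append([seg.interval_mean(e) for e in event.variant2])
        inc, exc = _diagnostic_features(event, seg, junc)
        quant.inclusion_counts.append(inc)
        quant.exclusion_counts.append(exc)
        quant.psi.append(compute_psi(event.event_type, inc, exc, min_total))
    quant.confirmed = [False] * quant.n_samples
    confirm_event(quant, min_diag_count)
    return quant


def quantify_sample(alignments, graph: SplicingGraph, seg_graph: SegmentGraph,
                    flt: JunctionFilter = JunctionFilter()
                    ) -> Tuple[SegmentCounts, JunctionCounts]:
    """Count one sample over one gene: segment coverages + junction counts."""
    span = GenomicInterval(min(v.start for v in graph.node_origin),
                           max(v.end for v in graph.node_origin))
    seg = segment_coverage(alignments, seg_graph, graph.chrom, span, flt)
    junc = junction_counts(alignments, graph, flt)
    return seg, junc
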