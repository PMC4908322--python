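"""End-to-end orchestration: annotation + alignments -> events -> PSI -> test.

This is the programmatic equivalent of the command-line pipeline: build the
annotation splicing graphs, augment them per gene with junction and coverage
evidence from all samples, optionally prune by cross-sample support, detect
and merge events, and quantify every event in every sample.  Each gene is
processed independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .augment import (
    CONFIDENCE_PRESETS,
    JunctionFilter,
    RetentionCriteria,
    SampleEvidence,
    augment_graph,
    coverage_from_alignments,
    edge_sample_support,
    extract_junctions,
    prune_graph,
)
from .events import EVENT_TYPES, ASEvent, detect_events
from .io import open_alignments
from .model import Gene, SplicingGraph, build_segment_graph, build_splicing_graph
from .quantify import EventQuantification, quantify_event, quantify_sample

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "build_graphs", "run_pipeline"]


@dataclass(slots=True)
class PipelineConfig:
    """Run-wide options; ``confidence_level`` selects junction-filter presets."""

    confidence_level: int = 1
    event_types: Tuple[str, ...] = EVENT_TYPES
    retention: RetentionCriteria = field(default_factory=RetentionCriteria)
    junction_filter: Optional[JunctionFilter] = None  # overrides preset
    min_prune_samples: Optional[int] = None  # None: 2 if >= 3 samples else 0
    max_skipped: int = 5
    psi_min_total: float = 10.0
    min_diag_count: float = 3.0
    seed: int = 0

    def filter(self) -> JunctionFilter:
        if self.junction_filter is not None:
            return self.junction_filter
        if self.confidence_level not in CONFIDENCE_PRESETS:
            raise ValueError(f"confidence_level must be one of "
                             f"{sorted(CONFIDENCE_PRESETS)}")
        return CONFIDENCE_PRESETS[self.confidence_level]


@dataclass(slots=True)
class PipelineResult:
    graphs: List[SplicingGraph]
    events: List[ASEvent]
    quantifications: List[EventQuantification]
    sample_names: List[str]


def build_graphs(genes: Sequence[Gene], bam_paths: Sequence[str],
                 config: PipelineConfig = PipelineConfig()
                 ) -> List[SplicingGraph]:
    """Annotation graphs augmented (and pruned) with per-sample evidence."""
    flt = config.filter()
    if config.min_prune_samples is None:
        min_samples = 2 if len(bam_paths) >= 3 else 0
    else:
        min_samples = config.min_prune_samples
    handles = [open_alignments(p) for p in bam_paths]
    graphs: List[SplicingGraph] = []
    try:
        for gene in genes:
            graph = build_splicing_graph(gene)
            span = gene.span
            evidence = []
            per_sample_junctions = []
            for af in handles:
                junctions = extract_junctions(af, (gene.chrom, span), flt)
                coverage = coverage_from_alignments(af, gene.chrom, span, flt)
                evidence.append(SampleEvidence(junctions, coverage))
                per_sample_junctions.append(junctions)
            augmented = augment_graph(graph, evidence, flt, config.retention)
            if min_samples > 0:
                support = edge_sample_support(
                    augmented, per_sample_junctions, flt.min_junction_reads)
                augmented = prune_graph(augmented, support, min_samples)
            graphs.append(augmented)
    finally:
        for af in handles:
            af.close()
    return graphs


def run_pipeline(genes: Sequence[Gene], bam_paths: Sequence[str],
                 config: PipelineConfig = PipelineConfig()
                 ) -> PipelineResult:
    """Full run: augment, detect, merge and quantify over all samples."""
    flt = config.filter()
    graphs = build_graphs(genes, bam_paths, config)
    all_events: List[ASEvent] = []
    quants: List[EventQuantification] = []
    handles = [open_alignments(p) for p in bam_paths]
    try:
        for graph in graphs:
            if not graph.node_origin:
                continue
            events = detect_events(graph, config.event_types,
                                   config.max_skipped)
            if not events:
                continue
            seg_graph = build_segment_graph(graph)
            seg_by_sample, junc_by_sample = [], []
            for af in handles:
                seg, junc = quantify_sample(af, graph, seg_graph, flt)
                seg_by_sample.append(seg)
                junc_by_sample.append(junc)
            for ev in events:
                quants.append(quantify_event(
                    ev, seg_by_sample, junc_by_sample,
                    config.psi_min_total, config.min_diag_count))
            all_events.extend(events)
    finally:
        for af in handles:
            af.close()
    names = [str(p) for p in bam_paths]
    return PipelineResult(graphs, all_events, quants, names)
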