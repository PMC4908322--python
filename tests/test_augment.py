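"""Graph augmentation: junction extraction, the three edit steps, pruning."""

import random

import numpy as np
import pytest

from altsplice.augment import (
    CONFIDENCE_PRESETS,
    CoverageTrack,
    IntronJunction,
    JunctionFilter,
    RetentionCriteria,
    SampleEvidence,
    add_cassette_exons,
    add_intron_retentions,
    augment_graph,
    edge_sample_support,
    extract_junctions,
    insert_intron_edges,
    merge_junctions,
    prune_graph,
)
from altsplice.io import open_alignments
from altsplice.model import GenomicInterval, SplicingGraph

from conftest import CHROM, make_bam


def iv(s, e):
    return GenomicInterval(s, e)


def graph_of(nodes, edges=(), origins=None):
    g = SplicingGraph("g", CHROM, "+")
    for n in nodes:
        g.add_node(iv(*n), (origins or {}).get(n, "annotated"))
    for u, v in edges:
        g.add_edge(iv(*u), iv(*v))
    return g


def junc(start, end, count=10):
    return IntronJunction(CHROM, start, end, ".", count)


PERMISSIVE = JunctionFilter(min_anchor_len=1, max_mismatches=float("inf"),
                            min_junction_reads=1, min_intron_len=10)


class TestExtractJunctions:
    def test_cigar_gap_coordinates_and_count(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", [(1, "50M100N50M", 50, 0)])
        with open_alignments(bam) as af:
            juncs = extract_junctions(af, (CHROM, iv(1, 500)), PERMISSIVE)
        assert [(j.start, j.end, j.read_count) for j in juncs] == [(51, 150, 1)]
        # excluded when two supporting reads are required
        flt = JunctionFilter(1, float("inf"), 2, 10)
        with open_alignments(bam) as af:
            assert extract_junctions(af, (CHROM, iv(1, 500)), flt) == []

    def test_min_reads_threshold_boundary(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam",
                       [(1, "50M100N50M", 50, 0)] * 2)
        flt = JunctionFilter(1, float("inf"), 2, 10)
        with open_alignments(bam) as af:
            juncs = extract_junctions(af, (CHROM, iv(1, 500)), flt)
        assert [(j.start, j.end, j.read_count) for j in juncs] == [(51, 150, 2)]

    def test_short_gap_excluded_by_intron_length(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", [(1, "50M10N50M", 50, 0)])
        flt = JunctionFilter(1, float("inf"), 1, 30)
        with open_alignments(bam) as af:
            assert extract_junctions(af, (CHROM, iv(1, 500)), flt) == []

    def test_anchor_and_mismatch_and_mapq_filters(self, tmp_path):
        reads = [
            (1, "3M100N50M", 50, 0),    # left anchor 3
            (1, "50M100N50M", 50, 5),   # 5 mismatches
            (1, "50M100N50M", 0, 0),    # multimapper (MAPQ 0)
            (1, "50M100N50M", 50, 0, 256),  # secondary
        ]
        bam = make_bam(tmp_path / "a.bam", reads)
        flt = JunctionFilter(8, 2, 1, 10)
        with open_alignments(bam) as af:
            assert extract_junctions(af, (CHROM, iv(1, 500)), flt) == []

    def test_multiple_gaps_per_read(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", [(1, "20M80N20M80N20M", 50, 0)])
        with open_alignments(bam) as af:
            juncs = extract_junctions(af, (CHROM, iv(1, 500)), PERMISSIVE)
        assert [(j.start, j.end) for j in juncs] == [(21, 100), (121, 200)]


class TestAddCassetteExons:
    def test_cassette_inserted_between_anchored_introns(self):
        g = graph_of([(1, 100), (501, 600)])
        out = add_cassette_exons(g, [junc(101, 200), junc(301, 500)])
        assert out.has_node(iv(201, 300))
        assert out.node_origin[iv(201, 300)] == "novel"
        assert out.has_edge(iv(1, 100), iv(201, 300))
        assert out.has_edge(iv(201, 300), iv(501, 600))

    def test_existing_cassette_is_not_duplicated(self):
        g = graph_of([(1, 100), (201, 300), (501, 600)])
        out = add_cassette_exons(g, [junc(101, 200), junc(301, 500)])
        assert out == g

    def test_unanchored_intron_end_is_noop(self):
        g = graph_of([(1, 90), (501, 600)])  # nothing ends at 100
        out = add_cassette_exons(g, [junc(101, 200), junc(301, 500)])
        assert out == g

    def test_coverage_check_rejects_intron_spanning_candidate(self):
        g = graph_of([(1, 100), (501, 600)])
        track = CoverageTrack(iv(1, 600))
        track.add_block(201, 240, 20)   # only part of the candidate covered
        out = add_cassette_exons(g, [junc(101, 200), junc(301, 500)],
                                 coverage=track)
        assert out == g
        track.add_block(241, 300, 20)
        out = add_cassette_exons(g, [junc(101, 200), junc(301, 500)],
                                 coverage=track)
        assert out.has_node(iv(201, 300))


class TestAddIntronRetentions:
    def test_covered_intron_becomes_retention_node(self):
        g = graph_of([(1, 100), (201, 300)], [((1, 100), (201, 300))])
        track = CoverageTrack(iv(1, 300))
        track.add_block(1, 100, 25)
        track.add_block(201, 300, 25)
        track.add_block(101, 200, 20)
        out = add_intron_retentions(g, track, RetentionCriteria())
        assert out.has_node(iv(1, 300))
        assert out.node_origin[iv(1, 300)] == "novel"

    def test_uncovered_intron_is_noop(self):
        g = graph_of([(1, 100), (201, 300)], [((1, 100), (201, 300))])
        track = CoverageTrack(iv(1, 300))
        track.add_block(1, 100, 25)
        track.add_block(201, 300, 25)
        assert add_intron_retentions(g, track, RetentionCriteria()) == g

    def test_exon_intron_ratio_bound(self):
        g = graph_of([(1, 100), (201, 300)], [((1, 100), (201, 300))])
        track = CoverageTrack(iv(1, 300))
        track.add_block(1, 300, 1)
        track.add_block(1, 100, 99)   # exons at 100, intron at 1
        track.add_block(201, 300, 99)
        crit = RetentionCriteria(min_intron_mean_cov=1)
        assert add_intron_retentions(g, track, crit) == g

    def test_retention_node_inherits_chain_edges(self):
        g = graph_of([(1, 50), (101, 200), (301, 400)],
                     [((1, 50), (101, 200)), ((101, 200), (301, 400))])
        track = CoverageTrack(iv(1, 400))
        track.add_block(101, 400, 20)   # intron 201-300 covered, 51-100 not
        out = add_intron_retentions(g, track, RetentionCriteria())
        assert out.has_node(iv(101, 400))
        assert out.has_edge(iv(1, 50), iv(101, 400))
        assert not out.has_node(iv(1, 200))


class TestInsertIntronEdges:
    def test_case_iv_connects_existing_boundaries(self):
        g = graph_of([(1, 100), (201, 300)])
        out, added = insert_intron_edges(g, [junc(101, 200)])
        assert added == 1
        assert out.has_edge(iv(1, 100), iv(201, 300))

    def test_case_ii_clips_overlapping_exon(self):
        g = graph_of([(1, 100), (151, 300)])
        out, added = insert_intron_edges(g, [junc(101, 200)])
        assert out.has_node(iv(201, 300))
        assert out.has_edge(iv(1, 100), iv(201, 300))

    def test_case_ii_novel_node_inherits_outgoing_edges(self):
        g = graph_of([(1, 100), (151, 300), (401, 500)],
                     [((151, 300), (401, 500))])
        out, _ = insert_intron_edges(g, [junc(101, 200)])
        assert out.has_edge(iv(201, 300), iv(401, 500))

    def test_case_iii_clips_upstream_exon(self):
        g = graph_of([(1, 150), (301, 400)])
        out, added = insert_intron_edges(g, [junc(101, 300)])
        assert out.has_node(iv(1, 100))
        assert out.has_edge(iv(1, 100), iv(301, 400))

    def test_case_i_skipped_by_default(self):
        g = graph_of([(1, 90), (311, 400)])
        out, added = insert_intron_edges(g, [junc(101, 300)])
        assert added == 0
        assert out == g

    def test_insertion_commutes_with_junction_order(self):
        rng = random.Random(23)
        g = graph_of([(1, 100), (201, 300), (401, 500), (601, 700)])
        juncs = [junc(101, 200), junc(301, 400), junc(501, 600),
                 junc(101, 400), junc(301, 600)]
        baseline, _ = insert_intron_edges(g, juncs)
        for _ in range(10):
            rng.shuffle(juncs)
            permuted, _ = insert_intron_edges(g, juncs)
            assert permuted == baseline


class TestAugmentGraph:
    def evidence(self, junctions, span=(1, 700), blocks=()):
        track = CoverageTrack(iv(*span))
        for s, e, d in blocks:
            track.add_block(s, e, d)
        return SampleEvidence(list(junctions), track)

    def test_no_evidence_is_fixpoint(self):
        g = graph_of([(1, 100), (201, 300)], [((1, 100), (201, 300))])
        assert augment_graph(g, [self.evidence([], span=(1, 300))]) == g

    def test_monotone_and_idempotent(self):
        g = graph_of([(1, 100), (501, 600)], [((1, 100), (501, 600))])
        ev = [self.evidence(
            [junc(101, 200), junc(301, 500), junc(101, 500)],
            blocks=[(1, 100, 30), (201, 300, 15), (501, 600, 30)])]
        once = augment_graph(g, ev)
        for v in g.node_origin:
            assert once.has_node(v)
        for u, v in g.edges:
            assert once.has_edge(u, v)
        assert augment_graph(once, ev) == once

    def test_cassette_path_and_skip_edge_recovered(self):
        g = graph_of([(1, 100), (501, 600)], [((1, 100), (501, 600))])
        ev = [self.evidence(
            [junc(101, 200), junc(301, 500)],
            blocks=[(1, 100, 30), (201, 300, 15), (501, 600, 30)])]
        out = augment_graph(g, ev)
        assert out.has_node(iv(201, 300))
        assert out.has_edge(iv(1, 100), iv(201, 300))
        assert out.has_edge(iv(201, 300), iv(501, 600))
        assert out.has_edge(iv(1, 100), iv(501, 600))


class TestPruneGraph:
    def base(self):
        g = graph_of([(1, 100), (201, 300), (401, 500)],
                     [((1, 100), (201, 300))])
        g.add_node(iv(601, 700), "novel")
        g.add_edge(iv(201, 300), iv(401, 500), "novel")
        g.add_edge(iv(401, 500), iv(601, 700), "novel")
        return g

    def test_minsamples_zero_is_identity(self):
        g = self.base()
        support = {e: 0 for e in g.edges}
        assert prune_graph(g, support, 0) == g

    def test_unsupported_novel_edge_removed(self):
        g = self.base()
        support = {e: 3 for e in g.edges}
        support[(iv(401, 500), iv(601, 700))] = 1
        out = prune_graph(g, support, 2)
        assert not out.has_edge(iv(401, 500), iv(601, 700))

    def test_novel_orphan_removed_annotated_orphan_kept(self):
        g = self.base()
        support = {e: 0 for e in g.edges}
        out = prune_graph(g, support, 2)
        assert not out.has_node(iv(601, 700))     # novel orphan
        assert out.has_node(iv(201, 300))         # annotated orphan retained
        assert out.has_node(iv(1, 100))
        assert out.edges == set()

    def test_sample_support_counts_junction_occurrences(self):
        g = graph_of([(1, 100), (201, 300)], [((1, 100), (201, 300))])
        samples = [[junc(101, 200, 5)], [], [junc(101, 200, 1)]]
        support = edge_sample_support(g, samples, min_junction_reads=2)
        assert support[(iv(1, 100), iv(201, 300))] == 1


def test_merge_junctions_sums_counts_across_samples():
    merged = merge_junctions([[junc(101, 200, 2)],
                              [junc(101, 200, 3), junc(301, 400, 1)]])
    assert [(j.start, j.end, j.read_count) for j in merged] == \
        [(101, 200, 5), (301, 400, 1)]


def test_confidence_presets_are_ordered_by_stringency():
    anchors = [CONFIDENCE_PRESETS[i].min_anchor_len for i in range(4)]
    assert anchors == sorted(anchors)
    assert CONFIDENCE_PRESETS[0].min_junction_reads <= \
        CONFIDENCE_PRESETS[3].min_junction_reads
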