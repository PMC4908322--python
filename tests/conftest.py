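"""Shared fixtures: tiny BAM writer, random graph generators, e2e dataset."""

from __future__ import annotations

import random
from pathlib import Path

import numpy as np
import pytest

from altsplice.model import Gene, GenomicInterval, SplicingGraph, Transcript

CHROM = "c1"
CHROM_LEN = 1_000_000


def make_bam(path, reads, chrom: str = CHROM, chrom_len: int = CHROM_LEN) -> str:
    """Write a sorted, indexed BAM from (pos1, cigar, mapq, nm) tuples.

    ``pos1`` is 1-based; optional 5th element is the FLAG (default 0).
    """
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": chrom_len}]}
    reads = sorted(reads, key=lambda r: r[0])
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, read in enumerate(reads):
            pos1, cigar, mapq, nm = read[:4]
            flag = read[4] if len(read) > 4 else 0
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos1 - 1
            a.mapping_quality = mapq
            a.cigarstring = cigar
            qlen = _query_len(cigar)
            a.query_sequence = "A" * qlen
            a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            a.set_tag("NM", nm)
            bam.write(a)
    pysam.index(path)
    return path


def _query_len(cigar: str) -> int:
    total, num = 0, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MIS=X":
                total += int(num)
            num = ""
    return max(total, 1)


def random_gene(rng: random.Random, max_exons: int = 20) -> Gene:
    """A random gene with 1-4 transcripts sharing an exon pool."""
    n_exons = rng.randint(1, max_exons)
    exons = []
    pos = rng.randint(1, 50)
    for _ in range(n_exons):
        length = rng.randint(20, 200)
        exons.append(GenomicInterval(pos, pos + length - 1))
        pos += length + rng.randint(2, 150)
    txs = []
    for t in range(rng.randint(1, 4)):
        chosen = sorted(rng.sample(exons, rng.randint(1, n_exons)))
        txs.append(Transcript(f"t{t}", chosen))
    return Gene("g", "c1", rng.choice("+-"), txs)


def random_overlapping_graph(rng: random.Random, max_nodes: int = 12,
                             edge_prob: float = 0.4) -> SplicingGraph:
    """Random splicing graph whose nodes may overlap (alt-site structure)."""
    n = rng.randint(2, max_nodes)
    nodes = set()
    while len(nodes) < n:
        start = rng.randint(1, 400)
        end = start + rng.randint(10, 120)
        nodes.add(GenomicInterval(start, end))
    graph = SplicingGraph("g", "c1", rng.choice("+-"))
    for v in sorted(nodes):
        graph.add_node(v)
    for u in sorted(nodes):
        for v in sorted(nodes):
            if u.end + 1 < v.start and rng.random() < edge_prob:
                graph.add_edge(u, v)
    return graph


@pytest.fixture(scope="session")
def e2e_dataset(tmp_path_factory):
    """Reduced annotation + 3 simulated 50x replicate BAMs + ground truth."""
    from altsplice import synthetic as syn

    outdir = tmp_path_factory.mktemp("e2e")
    mix = {t: 18 for t in syn.EVENT_TYPES}
    genes, truth = syn.generate_gene_models(mix, seed=1)
    reduced = syn.reduce_annotation(genes)
    bams = []
    for s in range(3):
        recs = syn.simulate_alignments(genes, truth.abundances, depth=50,
                                       read_len=75, seed=100 + s)
        bams.append(syn.write_alignments_bam(recs, genes,
                                             outdir / f"sample{s}.bam"))
    return {"genes": genes, "reduced": reduced, "truth": truth, "bams": bams,
            "dir": outdir}


@pytest.fixture(scope="session")
def e2e_result(e2e_dataset):
    from altsplice.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(e2e_dataset["reduced"], e2e_dataset["bams"],
                        PipelineConfig())
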