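"""Readers and writers for the standard formats.

Annotation comes in as GFF3 or GTF (gene -> transcript -> exon hierarchy,
parsed through gffutils), alignments as coordinate-sorted indexed BAM/SAM
through pysam.  Events go out as GFF3 mini-genes (one gene feature with two
mRNA children, ``variant1`` = inclusion and ``variant2`` = exclusion);
quantifications and test results as TSV tables.  Graphs serialise to a
JSON-lines format for persistence between pipeline stages.

Every coordinate in every file handled here is 1-based inclusive (GFF3
convention); the single 0-based half-open conversion for BAM happens in
:func:`read_alignments` / the pysam fetch calls.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from .events import ASEvent
from .model import (
    ANNOTATED,
    Gene,
    GenomicInterval,
    SplicingGraph,
    Transcript,
)

log = logging.getLogger(__name__)

__all__ = [
    "AnnotationFormatError",
    "parse_annotation",
    "read_alignments",
    "open_alignments",
    "write_events_gff3",
    "write_genes_gff3",
    "events_from_gff3",
    "write_quantification_tsv",
    "write_test_results_tsv",
    "graph_to_json",
    "graph_from_json",
    "write_graphs",
    "read_graphs",
]


class AnnotationFormatError(ValueError):
    """Raised for annotation files violating the expected hierarchy."""


_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def parse_annotation(path: str | Path, dialect: str | None = None) -> List[Gene]:
    """Parse a GFF3 or GTF annotation into the gene model.

    ``dialect`` may be ``"gff3"`` or ``"gtf"``; by default it is inferred
    from the file suffix.  Transcripts are identified by their ``Parent``
    attribute (GFF3) or ``transcript_id`` (GTF); exons are attached to their
    parent transcript and sorted by coordinate.
    """
    import gffutils

    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = "gtf" if suffix == ".gtf" else "gff3"
    if dialect not in ("gff3", "gtf"):
        raise AnnotationFormatError(f"unknown annotation dialect {dialect!r}")
    db = gffutils.create_db(
        str(path), ":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: List[Gene] = []
    seen_tx: set = set()
    for grec in db.features_of_type("gene", order_by=("seqid", "start")):
        gene = Gene(id=grec.id, chrom=grec.seqid, strand=grec.strand or "+")
        for trec in db.children(grec, level=1, order_by="start"):
            if trec.featuretype not in _TRANSCRIPT_TYPES:
                continue
            exons = sorted(
                GenomicInterval(e.start, e.end)
                for e in db.children(trec, featuretype="exon", order_by="start")
            )
            if not exons:
                continue
            tx = Transcript(id=trec.id, exons=exons)
            tx.validate()
            key = (gene.id, tuple(exons))
            if key in seen_tx:       # duplicate transcripts add nothing
                continue
            seen_tx.add(key)
            gene.transcripts.append(tx)
        if gene.transcripts:
            genes.append(gene)
    _check_orphans(db)
    if not genes:
        raise AnnotationFormatError(f"{path}: no gene with transcripts found")
    return genes


def _check_orphans(db) -> None:
    for exon in db.features_of_type("exon"):
        parents = list(db.parents(exon, level=1))
        if not parents:
            raise AnnotationFormatError(
                f"exon at {exon.seqid}:{exon.start}-{exon.end} "
                f"(line-level id {exon.id!r}) has no resolvable parent")


def open_alignments(path: str | Path):
    """Open an indexed, coordinate-sorted BAM (or SAM for linear scans)."""
    import pysam

    path = Path(path)
    mode = "r" if path.suffix == ".sam" else "rb"
    af = pysam.AlignmentFile(str(path), mode)
    if mode == "rb" and not af.has_index():
        raise ValueError(
            f"{path} has no index; run `samtools index {path}` first")
    return af


def read_alignments(path: str | Path, region: Tuple[str, GenomicInterval]
                    ) -> Iterator[dict]:
    """Yield alignment records overlapping a region as plain dicts.

    Reported positions are converted to 1-based inclusive here, exactly
    once.  Each record carries position, CIGAR string, mapping quality,
    flags and the NM mismatch count (0 when the tag is absent).
    """
    chrom, span = region
    with open_alignments(path) as af:
        for read in af.fetch(chrom, span.start - 1, span.end):
            try:
                nm = read.get_tag("NM")
            except KeyError:
                nm = 0
            yield {
                "name": read.query_name,
                "chrom": chrom,
                "start": read.reference_start + 1,
                "end": read.reference_end,
                "cigar": read.cigarstring,
                "mapq": read.mapping_quality,
                "flag": read.flag,
                "mismatches": nm,
            }


# ---------------------------------------------------------------------------
# GFF3 output
# ---------------------------------------------------------------------------

def _gff3_line(chrom, source, ftype, start, end, strand, attrs) -> str:
    attr_str = ";".join(f"{k}={v}" for k, v in attrs)
    return f"{chrom}\t{source}\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attr_str}"


def write_events_gff3(events: Sequence[ASEvent], path: str | Path) -> None:
    """Write events as mini-genes: gene + two mRNA children with exons."""
    lines = ["##gff-version 3"]
    used: Dict[str, int] = {}
    for ev in sorted(events, key=ASEvent.sort_key):
        eid = ev.event_id
        n = used.get(eid, 0)
        used[eid] = n + 1
        if n:
            eid = f"{eid}.{n}"
        span = ev.span
        lines.append(_gff3_line(
            ev.chrom, "altsplice", "gene", span.start, span.end, ev.strand,
            [("ID", eid), ("event_type", ev.event_type),
             ("source_gene", ev.gene_id)]))
        for vi, variant in ((1, ev.variant1), (2, ev.variant2)):
            mid = f"{eid}.variant{vi}"
            lines.append(_gff3_line(
                ev.chrom, "altsplice", "mRNA",
                variant[0].start, variant[-1].end, ev.strand,
                [("ID", mid), ("Parent", eid), ("variant", f"variant{vi}")]))
            for k, exon in enumerate(variant, 1):
                lines.append(_gff3_line(
                    ev.chrom, "altsplice", "exon", exon.start, exon.end,
                    ev.strand, [("ID", f"{mid}.exon{k}"), ("Parent", mid)]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_genes_gff3(genes: Sequence[Gene], path: str | Path) -> None:
    """Write a gene model back out as GFF3 (used for synthetic annotations)."""
    lines = ["##gff-version 3"]
    for gene in genes:
        span = gene.span
        lines.append(_gff3_line(gene.chrom, "altsplice", "gene",
                                span.start, span.end, gene.strand,
                                [("ID", gene.id)]))
        for tx in gene.transcripts:
            lines.append(_gff3_line(gene.chrom, "altsplice", "mRNA",
                                    tx.exons[0].start, tx.exons[-1].end,
                                    gene.strand,
                                    [("ID", tx.id), ("Parent", gene.id)]))
            for k, exon in enumerate(tx.exons, 1):
                lines.append(_gff3_line(gene.chrom, "altsplice", "exon",
                                        exon.start, exon.end, gene.strand,
                                        [("ID", f"{tx.id}.exon{k}"),
                                         ("Parent", tx.id)]))
    Path(path).write_text("\n".join(lines) + "\n")


def events_from_gff3(path: str | Path) -> List[ASEvent]:
    """Re-read a mini-gene GFF3 written by :func:`write_events_gff3`."""
    from .model import implied_intron

    genes = parse_annotation(path, dialect="gff3")
    events: List[ASEvent] = []
    for gene in genes:
        attrs = _event_attrs(path, gene.id)
        variants = {tx.id.rsplit(".", 1)[-1]: tuple(tx.exons)
                    for tx in gene.transcripts}
        v1, v2 = variants["variant1"], variants["variant2"]
        d1 = frozenset((i.start, i.end) for i in
                       (implied_intron(a, b) for a, b in zip(v1, v1[1:])))
        d2 = frozenset((i.start, i.end) for i in
                       (implied_intron(a, b) for a, b in zip(v2, v2[1:])))
        if attrs["event_type"] == "intron_retention":
            d1 = d2
        events.append(ASEvent(attrs["event_type"], attrs["source_gene"],
                              gene.chrom, gene.strand, v1, v2, d1, d2))
    return sorted(events, key=ASEvent.sort_key)


def _event_attrs(path: str | Path, gene_id: str) -> Dict[str, str]:
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 9 and fields[2] == "gene":
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";"))
            if attrs.get("ID") == gene_id:
                return attrs
    raise AnnotationFormatError(f"{path}: event {gene_id} not found")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_quantification_tsv(quantifications, sample_names: Sequence[str],
                             path: str | Path) -> None:
    """Canonical per-event quantification table, one row per event."""
    cols = ["event_id", "event_type", "gene", "strand"]
    for name in sample_names:
        cols += [f"{name}:inc_count", f"{name}:exc_count",
                 f"{name}:psi", f"{name}:confirmed"]
    rows = [cols]
    used: Dict[str, int] = {}
    for q in quantifications:
        eid = q.event.event_id
        n = used.get(eid, 0)
        used[eid] = n + 1
        if n:
            eid = f"{eid}.{n}"
        row = [eid, q.event.event_type, q.event.gene_id, q.event.strand]
        for s in range(q.n_samples):
            inc = sum(q.inclusion_counts[s]) / len(q.inclusion_counts[s])
            exc = sum(q.exclusion_counts[s]) / len(q.exclusion_counts[s])
            psi = "NA" if q.psi[s] is None else f"{q.psi[s]:.6g}"
            row += [f"{inc:.6g}", f"{exc:.6g}", psi,
                    "1" if q.confirmed[s] else "0"]
        rows.append(row)
    Path(path).write_text("\n".join("\t".join(r) for r in rows) + "\n")


def write_test_results_tsv(results, path: str | Path) -> None:
    cols = ["event_id", "event_type", "gene", "mean_psi_A", "mean_psi_B",
            "delta_psi", "lrt_stat", "p_value", "q_value", "tested"]
    rows = [cols]
    for r in results:
        fmt = lambda x: "NA" if x is None else f"{x:.6g}"
        rows.append([r.event_id, r.event_type, r.gene_id,
                     fmt(r.mean_psi_a), fmt(r.mean_psi_b), fmt(r.delta_psi),
                     f"{r.lrt_statistic:.6g}", f"{r.p_value:.6g}",
                     f"{r.q_value:.6g}", "1" if r.tested else "0"])
    Path(path).write_text("\n".join("\t".join(r) for r in rows) + "\n")


# ---------------------------------------------------------------------------
# graph serialization (JSON lines, one gene graph per line)
# ---------------------------------------------------------------------------

def graph_to_json(graph: SplicingGraph) -> str:
    return json.dumps({
        "gene_id": graph.gene_id,
        "chrom": graph.chrom,
        "strand": graph.strand,
        "nodes": [[v.start, v.end, graph.node_origin[v]]
                  for v in graph.nodes],
        "edges": [[u.start, u.end, v.start, v.end, graph.edge_origin[(u, v)]]
                  for u, v in sorted(graph.edges)],
    }, sort_keys=True)


def graph_from_json(line: str) -> SplicingGraph:
    data = json.loads(line)
    g = SplicingGraph(data["gene_id"], data["chrom"], data["strand"])
    for s, e, origin in data["nodes"]:
        g.add_node(GenomicInterval(s, e), origin)
    for us, ue, vs, ve, origin in data["edges"]:
        g.add_edge(GenomicInterval(us, ue), GenomicInterval(vs, ve), origin)
    return g


def write_graphs(graphs: Sequence[SplicingGraph], path: str | Path) -> None:
    Path(path).write_text("".join(graph_to_json(g) + "\n" for g in graphs))


def read_graphs(path: str | Path) -> List[SplicingGraph]:
    return [graph_from_json(line)
            for line in Path(path).read_text().splitlines() if line.strip()]
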