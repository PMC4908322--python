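"""Synthetic annotation, read and count generators with ground truth.

The generators emulate, at desk scale, a simulation study for splicing-event
discovery: multi-transcript gene models carrying implanted AS events of the
six supported types with known relative transcript abundances, spliced read
alignments drawn uniformly from those transcripts at a configurable depth,
and NB-distributed junction-count matrices for evaluating the differential
test.  A *reduced annotation* (first transcript per gene only) recreates the
discovery scenario where the alternative form must be recovered from read
evidence alone.

There is no sequencing-error or mapping-error model by default — evaluation
targets the graph/event machinery, not aligner robustness — but a mismatch
rate can be enabled for stress tests (reads then carry mismatching bases in
their NM tag only, since no reference sequence exists).

Default study conditions: 75 bp reads at 50x depth, exon lengths ~ U[80,200],
introns ~ U[100,300], inclusion-transcript abundance ~ U[0.2,0.8].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .events import ASEvent, EVENT_TYPES
from .model import Gene, GenomicInterval, Transcript, implied_intron

__all__ = [
    "TruthEvent",
    "TruthSet",
    "generate_gene_models",
    "reduce_annotation",
    "simulate_alignments",
    "write_alignments_bam",
    "true_psi",
    "evaluate_detection",
    "psi_agreement",
    "simulate_event_counts",
    "rank_auroc",
]

CHROM = "simchr"


@dataclass(slots=True)
class TruthEvent:
    """One implanted event with its defining introns and true PSI."""

    event_type: str
    gene_id: str
    strand: str
    diagnostic_introns1: FrozenSet[Tuple[int, int]]
    diagnostic_introns2: FrozenSet[Tuple[int, int]]
    inclusion_tx: Tuple[str, ...]
    true_psi: float

    @property
    def diagnostic_introns(self) -> FrozenSet[Tuple[int, int]]:
        return self.diagnostic_introns1 | self.diagnostic_introns2


@dataclass(slots=True)
class TruthSet:
    """Implanted events plus per-gene transcript abundances."""

    events: List[TruthEvent]
    abundances: Dict[str, Dict[str, float]]   # gene_id -> tx_id -> fraction

    def by_gene(self, gene_id: str) -> List[TruthEvent]:
        return [e for e in self.events if e.gene_id == gene_id]


def _intron_pairs(exons: Sequence[GenomicInterval]) -> FrozenSet[Tuple[int, int]]:
    return frozenset((i.start, i.end) for i in
                     (implied_intron(a, b) for a, b in zip(exons, exons[1:])))


#: Inclusion-abundance (= true PSI) ranges per event type.  Junction-defined
#: variants need only a single supporting spliced read, so their PSI may span
#: [0.2, 0.8]; a retained intron must additionally satisfy the coverage-ratio
#: retention criteria, which bounds its abundance from below.
PSI_RANGES: Dict[str, Tuple[float, float]] = {
    **{t: (0.2, 0.8) for t in EVENT_TYPES},
    "intron_retention": (0.4, 0.85),
}


def _build_gene(gene_id: str, strand: str, event_type: str, start: int,
                rng: np.random.Generator, p_inc: float,
                ):
    """Lay out one gene implanting one event.

    Returns (gene, truth, end, abundances)."""
    exon = lambda: int(rng.integers(80, 201))
    intron = lambda: int(rng.integers(100, 301))

    def iv(s: int, length: int) -> GenomicInterval:
        return GenomicInterval(s, s + length - 1)

    # The genomic layout of alt splice sites depends on strand: the label
    # refers to transcription direction, the coordinates to the genome.
    genomic_kind = event_type
    if event_type == "alt_3prime":
        genomic_kind = "vary_acceptor" if strand == "+" else "vary_donor"
    elif event_type == "alt_5prime":
        genomic_kind = "vary_donor" if strand == "+" else "vary_acceptor"

    if event_type == "exon_skip":
        e1 = iv(start, exon())
        e2 = iv(e1.end + 1 + intron(), exon())
        e3 = iv(e2.end + 1 + intron(), exon())
        t_inc = [e1, e2, e3]
        t_skip = [e1, e3]
        # either form may be the annotated one; both are recoverable
        first_inc = bool(rng.integers(2))
        txs = ([t_inc, t_skip] if first_inc else [t_skip, t_inc])
        inc_idx = 0 if first_inc else 1
        d1, d2 = _intron_pairs(t_inc), _intron_pairs(t_skip)
        end = e3.end
    elif event_type == "intron_retention":
        e1 = iv(start, exon())
        e2 = iv(e1.end + 1 + intron(), exon())
        retained = [GenomicInterval(e1.start, e2.end)]
        # the spliced form must be annotated: an unannotated intron inside a
        # single-exon gene is not recoverable from junctions alone
        txs = [[e1, e2], retained]
        inc_idx = 1
        d1 = d2 = _intron_pairs([e1, e2])
        end = e2.end
    elif genomic_kind == "vary_acceptor":
        e1 = iv(start, exon())
        shift = int(rng.integers(30, 71))
        long_len = exon() + shift
        a_long = iv(e1.end + 1 + intron(), long_len)
        a_short = GenomicInterval(a_long.start + shift, a_long.end)
        # annotate the longer exon: the shorter form is recoverable by
        # clipping it at the novel junction end
        txs = [[e1, a_long], [e1, a_short]]
        inc_idx = 0  # longer exonic sequence = inclusion
        d1 = _intron_pairs([e1, a_long])
        d2 = _intron_pairs([e1, a_short])
        end = a_long.end
    elif genomic_kind == "vary_donor":
        shift = int(rng.integers(30, 71))
        long_len = exon() + shift
        d_long = iv(start, long_len)
        d_short = GenomicInterval(d_long.start, d_long.end - shift)
        e2 = iv(d_long.end + 1 + intron(), exon())
        txs = [[d_long, e2], [d_short, e2]]
        inc_idx = 0
        d1 = _intron_pairs([d_long, e2])
        d2 = _intron_pairs([d_short, e2])
        end = e2.end
    elif event_type == "mutex_exons":
        e1 = iv(start, exon())
        eA = iv(e1.end + 1 + intron(), exon())
        eB = iv(eA.end + 1 + intron(), exon())
        e4 = iv(eB.end + 1 + intron(), exon())
        t_a = [e1, eA, e4]
        t_b = [e1, eB, e4]
        txs = [t_a, t_b]
        inc_idx = 0  # upstream exon = inclusion
        d1, d2 = _intron_pairs(t_a), _intron_pairs(t_b)
        end = e4.end
    elif event_type == "mult_exon_skip":
        e1 = iv(start, exon())
        m1 = iv(e1.end + 1 + intron(), exon())
        m2 = iv(m1.end + 1 + intron(), exon())
        e4 = iv(m2.end + 1 + intron(), exon())
        t_full = [e1, m1, m2, e4]
        t_skip = [e1, e4]
        txs = [t_full, t_skip]
        inc_idx = 0
        d1, d2 = _intron_pairs(t_full), _intron_pairs(t_skip)
        end = e4.end
    else:
        raise ValueError(f"unknown event type {event_type!r}")

    transcripts = [Transcript(f"{gene_id}.t{k + 1}", list(ex))
                   for k, ex in enumerate(txs)]
    gene = Gene(gene_id, CHROM, strand, transcripts)
    abundances = {transcripts[inc_idx].id: p_inc}
    other = [t for k, t in enumerate(transcripts) if k != inc_idx]
    for t in other:
        abundances[t.id] = (1.0 - p_inc) / len(other)
    truth = TruthEvent(event_type, gene_id, strand, d1, d2,
                       (transcripts[inc_idx].id,), p_inc)
    return gene, truth, end, abundances


def generate_gene_models(event_mix: Mapping[str, int], seed: int,
                         gene_gap: int = 5_000
                         ) -> Tuple[List[Gene], TruthSet]:
    """Generate one gene per requested event, deterministically from seed.

    ``event_mix`` maps event type -> number of genes implanting that type.
    Strands alternate between genes.  Inclusion abundances follow an evenly
    spaced titration grid over the per-type :data:`PSI_RANGES` (a fixed
    design gives the PSI-recovery evaluation a known, reproducible spread);
    the recorded true PSI is re-derived from the abundances with
    :func:`true_psi` for self-consistency.
    """
    unknown = set(event_mix) - set(EVENT_TYPES)
    if unknown:
        raise ValueError(f"unknown event types in mix: {sorted(unknown)}")
    if not event_mix or sum(event_mix.values()) < 1:
        raise ValueError("event_mix must request at least one event")
    rng = np.random.default_rng(seed)
    genes: List[Gene] = []
    truths: List[TruthEvent] = []
    abundances: Dict[str, Dict[str, float]] = {}
    cursor = 1_000
    idx = 0
    for etype in EVENT_TYPES:       # fixed order for determinism
        n_type = int(event_mix.get(etype, 0))
        lo, hi = PSI_RANGES[etype]
        for k in range(n_type):
            idx += 1
            strand = "+" if idx % 2 else "-"
            gene_id = f"g{idx:04d}_{etype}"
            p_inc = lo + (hi - lo) * (k + 0.5) / n_type
            gene, truth, end, ab = _build_gene(gene_id, strand, etype,
                                               cursor, rng, p_inc)
            # replace the drawn PSI with the formula-derived value (identical
            # by construction, asserted in tests)
            truth.true_psi = true_psi_from_parts(
                truth, gene.transcripts, ab)
            genes.append(gene)
            truths.append(truth)
            abundances[gene_id] = ab
            cursor = end + gene_gap
    return genes, TruthSet(truths, abundances)


def reduce_annotation(genes: Sequence[Gene]) -> List[Gene]:
    """Keep only each gene's first transcript (the discovery scenario)."""
    return [Gene(g.id, g.chrom, g.strand, [g.transcripts[0]])
            for g in genes]


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _tx_to_genomic(exons: Sequence[GenomicInterval], tx_start: int,
                   length: int) -> List[Tuple[int, int]]:
    """Map a transcript-coordinate window to genomic blocks (1-based incl.)."""
    blocks: List[Tuple[int, int]] = []
    offset = 0
    remaining = length
    pos = tx_start
    for exon in exons:
        elen = exon.length
        if pos >= offset + elen:
            offset += elen
            continue
        within = pos - offset
        take = min(remaining, elen - within)
        gstart = exon.start + within
        blocks.append((gstart, gstart + take - 1))
        remaining -= take
        pos += take
        offset += elen
        if remaining == 0:
            break
    return blocks


def _blocks_to_cigar(blocks: Sequence[Tuple[int, int]]) -> str:
    parts = []
    for k, (s, e) in enumerate(blocks):
        if k:
            gap = s - blocks[k - 1][1] - 1
            parts.append(f"{gap}N")
        parts.append(f"{e - s + 1}M")
    return "".join(parts)


def simulate_alignments(genes: Sequence[Gene],
                        abundances: Mapping[str, Mapping[str, float]],
                        depth: float, read_len: int, seed: int,
                        mismatch_rate: float = 0.0) -> List[dict]:
    """Draw perfect spliced reads uniformly along transcripts.

    Read numbers per transcript are Poisson with mean
    ``depth * abundance * L_tx / read_len`` so expected per-position coverage
    of a transcript region equals ``depth * abundance``.  Returns records
    sorted by position, ready for :func:`write_alignments_bam`.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    records: List[dict] = []
    for gene in genes:
        for tx in gene.transcripts:
            ab = abundances[gene.id][tx.id]
            tx_len = sum(e.length for e in tx.exons)
            eff_len = max(1, tx_len - read_len + 1)
            n_reads = rng.poisson(depth * ab * tx_len / read_len)
            if n_reads == 0:
                continue
            starts = rng.integers(0, eff_len, size=n_reads)
            for i, s in enumerate(sorted(starts.tolist())):
                length = min(read_len, tx_len - s)
                blocks = _tx_to_genomic(tx.exons, s, length)
                nm = int(rng.binomial(length, mismatch_rate)) if mismatch_rate else 0
                records.append({
                    "name": f"{tx.id}.r{i}",
                    "chrom": gene.chrom,
                    "pos": blocks[0][0],          # 1-based
                    "cigar": _blocks_to_cigar(blocks),
                    "mapq": 50,
                    "nm": nm,
                    "reverse": gene.strand == "-",
                })
    records.sort(key=lambda r: (r["chrom"], r["pos"], r["name"]))
    return records


def write_alignments_bam(records: Sequence[dict], genes: Sequence[Gene],
                         path) -> str:
    """Write simulated records to a sorted, indexed BAM; returns the path."""
    import pysam

    chrom_len = max(g.span.end for g in genes) + 1_000
    chroms = sorted({g.chrom for g in genes})
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_len} for c in chroms],
    }
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        tid = {c: i for i, c in enumerate(chroms)}
        for rec in records:
            a = pysam.AlignedSegment()
            a.query_name = rec["name"]
            a.flag = 16 if rec.get("reverse") else 0
            a.reference_id = tid[rec["chrom"]]
            a.reference_start = rec["pos"] - 1
            a.mapping_quality = rec["mapq"]
            a.cigarstring = rec["cigar"]
            qlen = sum(int(n) for n, op in _split_cigar(rec["cigar"])
                       if op in "MIS=X")
            a.query_sequence = "A" * qlen
            a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            a.set_tag("NM", rec.get("nm", 0))
            bam.write(a)
    pysam.index(path)
    return path


def _split_cigar(cigar: str) -> List[Tuple[str, str]]:
    out, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((num, ch))
            num = ""
    return out


# ---------------------------------------------------------------------------
# ground truth and scoring
# ---------------------------------------------------------------------------

def _tx_supports_junction_variant(tx: Transcript,
                                  diag: FrozenSet[Tuple[int, int]]) -> bool:
    tx_introns = {(i.start, i.end) for i in tx.introns}
    return diag <= tx_introns


def _tx_retains_intron(tx: Transcript, intron: Tuple[int, int]) -> bool:
    region = GenomicInterval(*intron)
    return any(e.contains(region) for e in tx.exons)


def true_psi_from_parts(event, transcripts: Sequence[Transcript],
                        abundances: Mapping[str, float]) -> Optional[float]:
    """True PSI from transcript abundances.

    Numerator: summed abundance of transcripts representing the inclusion
    variant.  Denominator: summed abundance of transcripts containing any of
    the event's exonic regions.  Undefined (None) when the denominator is 0.
    """
    if event.event_type == "intron_retention":
        (intron,) = event.diagnostic_introns2 if hasattr(
            event, "diagnostic_introns2") else event.diagnostic_introns
        inc_ids = [t.id for t in transcripts if _tx_retains_intron(t, intron)]
    else:
        inc_ids = [t.id for t in transcripts
                   if _tx_supports_junction_variant(t, event.diagnostic_introns1)]
    # transcripts containing any event exon: overlap of exonic regions with
    # the event span is the practical reading at mini-gene scale
    lo = min(s for s, e in event.diagnostic_introns)
    hi = max(e for s, e in event.diagnostic_introns)
    span = GenomicInterval(max(1, lo - 1), hi + 1)
    denom_ids = [t.id for t in transcripts
                 if any(e.overlaps(span) for e in t.exons)]
    denom = sum(abundances[t] for t in denom_ids)
    if denom == 0:
        return None
    num = sum(abundances[t] for t in inc_ids)
    return num / denom


def true_psi(event, gene: Gene, abundances: Mapping[str, float]
             ) -> Optional[float]:
    """Convenience wrapper over :func:`true_psi_from_parts`."""
    return true_psi_from_parts(event, gene.transcripts, abundances)


def evaluate_detection(predicted: Sequence[ASEvent], truth: TruthSet
                       ) -> Dict[str, Dict[str, float]]:
    """Precision/recall/F per event type, matching on exact diagnostic introns."""
    scores: Dict[str, Dict[str, float]] = {}
    for etype in EVENT_TYPES:
        truth_keys = {(t.gene_id.split("_")[0], t.diagnostic_introns)
                      for t in truth.events if t.event_type == etype}
        truth_introns = {t.diagnostic_introns for t in truth.events
                         if t.event_type == etype}
        pred = [p for p in predicted if p.event_type == etype]
        pred_introns = {p.diagnostic_introns for p in pred}
        tp = len(pred_introns & truth_introns)
        fp = len(pred_introns - truth_introns)
        fn = len(truth_introns - pred_introns)
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f = (2 * precision * recall / (precision + recall)
             if precision + recall else 0.0)
        scores[etype] = {"tp": tp, "fp": fp, "fn": fn,
                         "precision": precision, "recall": recall,
                         "f_score": f}
    return scores


def psi_agreement(predicted: Sequence[Optional[float]],
                  truth: Sequence[Optional[float]]) -> Optional[float]:
    """Pearson r over events with defined PSI on both sides (None if < 3)."""
    from scipy import stats

    pairs = [(p, t) for p, t in zip(predicted, truth)
             if p is not None and t is not None]
    if len(pairs) < 3:
        return None
    x, y = zip(*pairs)
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# count simulation for the differential test
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray | float,
             alpha: float, size=None) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_event_counts(n_events: int, n_per_group: int = 3,
                          depth: float = 200.0, alpha_disp: float = 0.2,
                          delta_psi: float = 0.0,
                          base_psi_range: Tuple[float, float] = (0.1, 0.4),
                          seed: int = 0, alpha_junction: float = 0.05
                          ) -> Tuple[np.ndarray, np.ndarray, np.ndarray,
                                     np.ndarray]:
    """NB junction-count matrices for GLM evaluation.

    Per event, a base PSI is drawn from ``base_psi_range``; group B's PSI is
    shifted by ``delta_psi``.  Counts are gamma-Poisson draws whose marginal
    dispersion is ``alpha_disp``, decomposed into an *expression* component
    shared between the inclusion and exclusion junctions of a sample (total
    event expression varies between biological replicates) and an
    independent *junction-level* component ``alpha_junction`` (splicing-
    ratio variability, the part no expression offset can remove).  Returns
    (inc, exc, groups, true_delta) with matrices shaped
    (n_events, 2 * n_per_group).
    """
    if not 0.0 <= alpha_junction <= alpha_disp:
        raise ValueError("need 0 <= alpha_junction <= alpha_disp")
    rng = np.random.default_rng(seed)
    groups = np.array([0] * n_per_group + [1] * n_per_group)
    n_samples = 2 * n_per_group
    psi_a = rng.uniform(*base_psi_range, size=n_events)
    psi_b = np.clip(psi_a + delta_psi, 0.0, 1.0)
    psi = np.where(groups[None, :] == 0, psi_a[:, None], psi_b[:, None])
    # cv^2 components multiply: (1+a_sh)(1+a_j) - 1 = alpha_disp
    alpha_shared = (alpha_disp - alpha_junction) / (1.0 + alpha_junction)
    shape = (n_events, n_samples)
    expr = (rng.gamma(1.0 / alpha_shared, alpha_shared, size=shape)
            if alpha_shared > 0 else np.ones(shape))
    g_inc = (rng.gamma(1.0 / alpha_junction, alpha_junction, size=shape)
             if alpha_junction > 0 else np.ones(shape))
    g_exc = (rng.gamma(1.0 / alpha_junction, alpha_junction, size=shape)
             if alpha_junction > 0 else np.ones(shape))
    inc = rng.poisson(depth * psi * expr * g_inc)
    exc = rng.poisson(depth * (1.0 - psi) * expr * g_exc)
    return inc, exc, groups, psi_b - psi_a


def quantifications_from_counts(inc: np.ndarray, exc: np.ndarray,
                                min_total: float = 10.0):
    """Wrap simulated count matrices as event quantifications for testing."""
    from .quantify import EventQuantification, compute_psi

    n_events, n_samples = inc.shape
    quants = []
    for i in range(n_events):
        ev = ASEvent(
            "exon_skip", f"sim{i:05d}", CHROM, "+",
            (GenomicInterval(1, 100), GenomicInterval(201, 300),
             GenomicInterval(401, 500)),
            (GenomicInterval(1, 100), GenomicInterval(401, 500)),
            frozenset({(101, 200), (301, 400)}), frozenset({(101, 400)}))
        q = EventQuantification(ev)
        for s in range(n_samples):
            q.inclusion_counts.append([float(inc[i, s])])
            q.exclusion_counts.append([float(exc[i, s])])
            q.exon_means1.append([0.0])
            q.exon_means2.append([0.0])
            q.psi.append(compute_psi("exon_skip", [float(inc[i, s])],
                                     [float(exc[i, s])], min_total))
            q.confirmed.append(True)
        quants.append(q)
    return quants


def rank_auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank-sum identity."""
    from scipy import stats

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both positive and negative labels")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))
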