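# altsplice

Splicing-graph analysis of alternative splicing (AS) from RNA-Seq: augment a
gene annotation with novel splice structure found in read alignments, extract
AS events as two-variant mini-genes, quantify percent-spliced-in (PSI) per
sample, and test events for differential usage between sample groups.

The package is aimed at transcriptomics analysts who have a GFF3/GTF
annotation and coordinate-sorted, indexed BAM files and want event-level
splicing phenotypes — a much cheaper and often more robust target than full
transcript reconstruction.

## The model

Each gene is collapsed into a **splicing graph** G = (V, E): nodes are
distinct exons v = (g_start, g_end) (1-based, inclusive), and a directed edge
(u, v) is the intron (u_end + 1, v_start − 1).  Transcripts are paths from a
start-terminal (in-degree 0) to an end-terminal (out-degree 0) node.

Evidence from alignments turns G into an augmented graph Ĝ ⊇ G in four
steps: (1) build G from the annotation; (2) insert **cassette exons**
implied by non-overlapping junction pairs whose outer ends anchor on
existing exons; (3) insert **intron retentions** for edges whose intron is
covered like an exon; (4) insert **novel intron edges** for junctions whose
ends coincide with (or clip into) existing exons, iterated to a fixpoint.
With several samples, edges supported by too few samples can be pruned.

Events are local motifs of Ĝ — exon skip, intron retention, alternative
3′/5′ splice site, mutually exclusive exons, multiple exon skip — each
reported as a mini-gene with an inclusion and an exclusion variant.  For
counting, nodes are decomposed into a **segment graph** of maximal
non-overlapping exonic segments so no genomic position is piled up twice.
Per sample,

PSI = inc / (inc + exc),

where inc and exc are the mean spliced-alignment counts over each variant's
diagnostic introns (mean intron coverage for the retained variant).

Differential usage between two replicate groups models the inclusion count
k_s of sample s as NB(μ_s, α) with log μ_s = β₀ + β₁·group_s + log(sf_s ·
max(1, inc_s + exc_s)), so the offset absorbs expression differences and β₁
captures relative usage.  Dispersion α is estimated per event by method of
moments within groups and stabilised against a mean–dispersion trend
(α = max(trend, raw)); the test is a likelihood-ratio test of β₁ against
χ²(1), with Benjamini–Hochberg control across events.

## Worked example

`examples/02_discover_novel_events.py` implants one event in each of 24
synthetic genes, hides the alternative transcript from the annotation,
simulates three replicates of 75 bp spliced reads at 50× and runs the full
pipeline:

```
24 genes, one implanted event each; annotation reduced to one transcript per gene
simulated 3 replicates, ~5873 spliced 75 bp reads each (50x depth)
augmentation added 16 novel exon nodes across all genes

event type         precision  recall     F
exon_skip               1.00    1.00  1.00
intron_retention        1.00    1.00  1.00
alt_3prime              1.00    1.00  1.00
alt_5prime              1.00    1.00  1.00
mutex_exons             1.00    1.00  1.00
mult_exon_skip          1.00    1.00  1.00
```

F = 1.0 means every implanted event was recovered with exactly matching
diagnostic intron coordinates and nothing spurious was reported.  The other
examples build graphs by hand (`01`), compare estimated to true PSI
(`03` — prints Pearson r 0.985 on eight skip events), and run the
differential test on simulated counts (`04` — 99/100 shifted events found
at FDR 0.05 with 2 false calls).

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
altsplice build    -a annotation.gff3 -b s1.bam -b s2.bam -o out/   # graphs
altsplice events   -a annotation.gff3 -b s1.bam -b s2.bam -o out/   # events.gff3
altsplice quantify -a annotation.gff3 -b s1.bam -b s2.bam -o out/   # + PSI TSV
altsplice test     -a annotation.gff3 -b a1.bam -b a2.bam -b b1.bam -b b2.bam \
    --group-a a1.bam,a2.bam --group-b b1.bam,b2.bam -o out/         # + test TSV
```

`--confidence {0..3}` selects junction-filter stringency presets; outputs are
deterministic given identical inputs and seeds.

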