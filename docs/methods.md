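# Methods

This note documents the models and procedures implemented in `altsplice`,
the parameters that matter with their defaults and rationale, what the
synthetic generators do and do not emulate, and the numerical choices made
where the design was genuinely open.

## Coordinates and gene model

All coordinates are 1-based and inclusive at both ends throughout the
package; an intron is written (first intronic base, last intronic base), so
an edge between exons u and v realises the intron (u.end + 1, v.start − 1).
The single conversion from BAM's 0-based half-open convention happens at the
alignment I/O boundary and nowhere else.  Genes are processed independently,
keyed by (chromosome, strand); graphs are stored in forward-genome
coordinates regardless of strand, and strand enters only where labels depend
on transcription direction (alternative 3′ vs 5′ sites).  Duplicate
transcripts in an annotation are dropped silently — they contribute no new
node or edge.

## Splicing and segment graphs

The splicing graph identifies exons by their coordinate pair; edges always
point from lower to higher coordinates, so acyclicity holds by construction.
Segment-graph construction uses breakpoints {node starts} ∪ {node ends + 1}:
segments are the exon-covered stretches between consecutive breakpoints.
This is equivalent to the cumulative start/end-array formulation on
inclusive positions but avoids double-booking boundary bases; every node is
an exact concatenation of consecutive segments (asserted against a
position-wise brute-force oracle in the tests).  Segment count is bounded by
2·|V| − 1.

## Augmentation

Junction extraction filters per read (primary, MAPQ > 0, NM ≤
max_mismatches, anchor length on both sides of each gap) and per junction
(supporting reads, intron length in [30, 350 000]).  Four stringency presets
0–3 map to (min_anchor, max_mismatches, min_reads) = (1, ∞, 1), (3, 3, 1),
(5, 2, 2), (8, 1, 2); the defaults are deliberately tiered rather than
empirically fitted, and every threshold is configurable.  Preset 1 is the
pipeline default.

Cassette insertion considers non-overlapping junction pairs (gap ≥ 1 base,
candidate pairs capped at 10 000 per gene to bound the quadratic scan): the
upstream intron's start must extend an existing node end, the downstream
intron's end must meet a later node start, and the implied exon must be
novel.  When a coverage track is available (the pipeline always passes one,
averaged across samples) the candidate region must additionally be
read-covered over ≥ 90 % of its positions.  This coverage condition is part
of the confidence criteria for this step: junction pairs drawn from two
*different* alternative paths (e.g. the two variants of a mutually exclusive
pair) would otherwise fabricate an exon spanning an uncovered intron.

Intron retention requires ≥ 90 % of intron positions covered (threshold 1
read), intron mean coverage ≥ 5, and the smaller flanking exon mean at most
3× the intron mean.  The retention node spans source start to target end and
inherits all incoming edges of the source and outgoing edges of the target.

Intron-edge insertion distinguishes whether the junction start matches an
existing node end and/or the junction end a node start: both → add the
missing edge; one side → clip an exon overlapping the unanchored end into a
novel node that inherits the clipped exon's edges on its outer side;
neither → skipped by default (a speculative two-sided mode exists behind a
flag; unanchored exons are a major false-positive source).  The step runs to
a fixpoint, capped at 5 iterations (a warning is logged if the cap binds;
two iterations suffice on all fixtures).  Newly added nodes sharing a
boundary with an existing node inherit that node's edges at the shared
boundary.

Augmentation is monotone (Ĝ ⊇ G) and idempotent on fixed evidence.
Multi-sample evidence is merged before editing (junction counts summed,
coverage averaged); per-sample junction lists are kept for pruning, which
removes edges supported by fewer than min_samples samples (default 2 when
≥ 3 samples are given, else disabled) and then removes novel nodes *made*
orphan by that removal.  Annotated nodes are never removed, and a novel node
that legitimately never had an edge (a retention node in a two-exon gene)
survives pruning.

## Events

All six event types are local subgraph motifs; detectors are pure functions
of the graph and are validated against exhaustive tuple enumeration on
random graphs.  Mutually exclusive exons are disqualified only by a *direct*
edge between the two middle exons — longer connecting paths do not count,
consistent with the locality of the representation.  Multiple exon skips
report chains of 2–5 skipped exons (configurable cap).  Alternative-site
events require the differing exons to overlap; non-overlapping alternatives
belong to the skip/mutex classes.  Alternative transcript starts and ends
are deliberately not event types: they arise from transcription, not
splicing.  Events of one type sharing identical diagnostic introns and
differing only in outer flank extent merge to the intersection of their
flanks; an empty intersection keeps them separate with a logged warning.
Output ordering is fully deterministic (sorted by type, diagnostic introns,
variants).

## Quantification and PSI

Counting happens once per sample on the segment graph; exon means are
length-weighted over overlapped segments, junction counts require the gap
coordinates to match the intron exactly and the read to pass the same
per-read filters as augmentation.  Multi-mapped reads (MAPQ 0) are excluded
by default; duplicates are not removed.

PSI = mean(inclusion diagnostics) / (mean(inclusion) + mean(exclusion)),
undefined below a total of 10 (min_total).  Per type, inclusion is: the
cassette path's junctions (exon skip, multiple exon skip), the mean intron
coverage (retention — a per-position depth used as a pseudo-count comparable
to junction depth, documented as an approximation), the longer-exon
variant's junction (alternative sites), and the upstream-exon variant's
junctions (mutex).  A sample confirms an event when every diagnostic feature
of *both* variants reaches min_diag_count (default 3) — both alternatives
observed — and an event is confirmed when at least one sample confirms it.

## Differential testing

Inclusion counts per event are modelled NB with a log link; the offset
log(size factor) + log(max(1, inc + exc)) targets relative usage rather than
expression.  Size factors are DESeq-style median-of-ratios over the
per-event total counts.  Events with total diagnostic count below 10 in
either group, or with PSI undefined throughout a group, are excluded before
testing (this filter shrinks the BH denominator and is reported via the
`tested` flag).

Dispersion is estimated per event by method of moments pooled over the two
replicate groups on offset-adjusted fitted means, with the Bessel-style
n/(n−1) correction applied to the squared residuals only.  A trend
α(μ) = a₀ + a₁/μ is fitted across events by least squares (median fallback
for degenerate inputs) and the dispersion used for testing is
**max(trend, raw)**.  The conservative maximum, rather than a weighted
blend, is used because with 3 replicates per group the per-event estimate
carries ~4 degrees of freedom: trusting it when it falls *below* the trend
makes the χ²(1) likelihood-ratio test anticonservative (measured rejection
up to 0.11 at nominal 0.05 in the calibration simulations), while an excess
above the trend is kept as real signal.  With the maximum rule the null
rejection rate measures 0.04–0.06 across simulation seeds and power at a
PSI shift of 0.3 exceeds 0.95 under the default simulation conditions.  The
LRT statistic is the deviance difference of the nested fits (statsmodels
GLM, Poisson family when α < 1e−8), compared to χ²(1); BH adjustment is
applied across tested events.

## Synthetic data: what it emulates, what it does not

`generate_gene_models` implants exactly one event per gene (two transcripts,
1–3 for future mixes), with exon lengths ~ U[80, 200], introns ~ U[100,
300], genes spaced 5 kb on one synthetic chromosome, strands alternating.
Inclusion abundances follow an evenly spaced titration grid over [0.2, 0.8]
per type ([0.4, 0.85] for intron retention, whose retained variant must
satisfy the coverage-ratio criteria to be discoverable at all) — a fixed
design that gives the PSI evaluation a known spread.  The annotated "first"
transcript is chosen so that the hidden variant is recoverable from reads by
the augmentation rules (spliced form annotated for retentions, longer exon
for alternative sites); for exon skips either variant may be hidden.  True
PSI is derived from the abundances as inclusion-transcript abundance over
the abundance of all transcripts overlapping the event region.

`simulate_alignments` draws read starts uniformly along transcripts with
Poisson read numbers (expected coverage = depth × abundance), emits exact
gap CIGARs at transcript introns, and has no error model by default (a
mismatch-rate knob fills the NM tag for filter stress tests).  The default
study uses three replicates of 75 bp reads at 50×.  Not emulated: sequencing
errors, mapping ambiguity, fragment-length and GC biases, positional
coverage bias, incomplete splicing in rRNA-depleted libraries.  Perfect
F-scores on these fixtures therefore validate the graph/event machinery and
the counting paths, not robustness to alignment artefacts.

`simulate_event_counts` produces junction counts for the testing module:
marginal NB dispersion 0.2 per the calibration study design, decomposed into
a shared gamma factor (biological expression variability, common to the
inclusion and exclusion counts of a sample) and an independent junction-
level gamma with dispersion 0.05 (splicing-ratio variability).  The split
reflects how replicate variability is usually structured — expression noise
dominates and cancels in a ratio — and it is what makes a usage test
worthwhile: if all overdispersion were independent per junction, the group
log-ratio would have standard deviation at least √(2α/n) regardless of
sequencing depth, and no test could be both calibrated and powerful at a
PSI shift of 0.3 with 3 vs 3 replicates.  Differential implants shift base
PSI ~ U[0.1, 0.4] upward by 0.3 (a minor-to-major isoform switch, the
canonical regulated-splicing scenario).  Default depth 200 junction reads
per event.

## Numerical and degenerate-input choices

* Interval order is lexicographic by (start, end); all tie-breaks use it.
* Junction processing is order-independent (inputs are sorted internally);
  permutation tests assert this.
* PSI with zero total evidence is undefined (None), never 0/0.
* `lrt_pvalue` clamps statistics within −1e−6 of zero and raises beyond.
* GLM non-convergence (non-finite coefficients) marks the event untested
  rather than propagating a bogus p-value.
* Events with empty flank intersection during merging are kept separate.
* Pruning with min_samples = 0 is the identity.

## Known limitations

* Intron-retention PSI mixes a coverage mean with a junction count; the two
  scale similarly with depth but not identically, biasing retention PSI
  slightly upward (visible, and tolerated, in the PSI-recovery study).
* The two-sided case of novel-edge insertion (neither end anchored) is off
  by default; genuinely novel exons with two novel flanking introns inside
  annotated genes are not discovered.
* The differential module supports exactly two groups without covariates or
  pairing.
* Confidence presets are design defaults, not values fitted to a benchmark;
  real datasets may need tuning, especially for intron retention in
  rRNA-depleted libraries.
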