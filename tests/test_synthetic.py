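"""Synthetic generators: determinism, self-consistency, truth formulas."""

import numpy as np
import pytest

from altsplice import synthetic as syn
from altsplice.events import EVENT_TYPES, detect_events
from altsplice.io import open_alignments
from altsplice.model import build_splicing_graph


class TestGenerateGeneModels:
    def test_deterministic_given_seed(self):
        mix = {"exon_skip": 3, "alt_3prime": 2}
        a_genes, a_truth = syn.generate_gene_models(mix, seed=9)
        b_genes, b_truth = syn.generate_gene_models(mix, seed=9)
        assert [g.id for g in a_genes] == [g.id for g in b_genes]
        assert [[t.exons for t in g.transcripts] for g in a_genes] == \
            [[t.exons for t in g.transcripts] for g in b_genes]
        assert [t.true_psi for t in a_truth.events] == \
            [t.true_psi for t in b_truth.events]

    def test_event_mix_counts_respected(self):
        mix = {"exon_skip": 10}
        genes, truth = syn.generate_gene_models(mix, seed=2)
        assert len(genes) == 10
        assert all(t.event_type == "exon_skip" for t in truth.events)
        assert len(truth.events) == 10

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_gene_models({"exon_hop": 1}, seed=0)

    def test_abundances_sum_to_one(self):
        genes, truth = syn.generate_gene_models(
            {t: 2 for t in EVENT_TYPES}, seed=3)
        for gene in genes:
            total = sum(truth.abundances[gene.id].values())
            assert total == pytest.approx(1.0)

    def test_implanted_events_detectable_on_full_annotation(self):
        genes, truth = syn.generate_gene_models(
            {t: 3 for t in EVENT_TYPES}, seed=5)
        detected = []
        for gene in genes:
            detected.extend(detect_events(build_splicing_graph(gene)))
        scores = syn.evaluate_detection(detected, truth)
        for etype in EVENT_TYPES:
            assert scores[etype]["recall"] == 1.0, etype

    def test_reduced_annotation_keeps_first_transcript(self):
        genes, _ = syn.generate_gene_models({"exon_skip": 2}, seed=6)
        reduced = syn.reduce_annotation(genes)
        for full, red in zip(genes, reduced):
            assert len(red.transcripts) == 1
            assert red.transcripts[0].exons == full.transcripts[0].exons


class TestSimulateAlignments:
    def test_gaps_match_transcript_introns(self, tmp_path):
        genes, truth = syn.generate_gene_models({"exon_skip": 1}, seed=7)
        gene = genes[0]
        only_tx = gene.transcripts[0]
        abundances = {gene.id: {t.id: (1.0 if t.id == only_tx.id else 0.0)
                                for t in gene.transcripts}}
        recs = syn.simulate_alignments(genes, abundances, depth=30,
                                       read_len=75, seed=1)
        bam = syn.write_alignments_bam(recs, genes, tmp_path / "a.bam")
        from altsplice.augment import JunctionFilter, extract_junctions
        with open_alignments(bam) as af:
            juncs = extract_junctions(
                af, (gene.chrom, gene.span),
                JunctionFilter(1, float("inf"), 1, 10))
        tx_introns = {(i.start, i.end) for i in only_tx.introns}
        assert {(j.start, j.end) for j in juncs} <= tx_introns

    def test_coverage_tracks_depth(self, tmp_path):
        genes, truth = syn.generate_gene_models({"intron_retention": 1},
                                                seed=8)
        gene = genes[0]
        tx = gene.transcripts[0]
        abundances = {gene.id: {t.id: (1.0 if t.id == tx.id else 0.0)
                                for t in gene.transcripts}}
        recs = syn.simulate_alignments(genes, abundances, depth=60,
                                       read_len=75, seed=2)
        bam = syn.write_alignments_bam(recs, genes, tmp_path / "a.bam")
        from altsplice.augment import JunctionFilter, coverage_from_alignments
        with open_alignments(bam) as af:
            track = coverage_from_alignments(
                af, gene.chrom, gene.span, JunctionFilter(1, float("inf"), 1))
        # interior of the first exon should sit near 60x (within 10%)
        exon = tx.exons[0]
        interior = type(exon)(exon.start + 20, exon.end - 20)
        assert track.mean(interior) == pytest.approx(60, rel=0.10)

    def test_identical_seed_gives_identical_records(self):
        genes, truth = syn.generate_gene_models({"mutex_exons": 2}, seed=9)
        a = syn.simulate_alignments(genes, truth.abundances, 20, 75, seed=3)
        b = syn.simulate_alignments(genes, truth.abundances, 20, 75, seed=3)
        assert a == b

    def test_depth_must_be_positive(self):
        genes, truth = syn.generate_gene_models({"exon_skip": 1}, seed=1)
        with pytest.raises(ValueError):
            syn.simulate_alignments(genes, truth.abundances, 0, 75, seed=1)


class TestTruePsi:
    def test_inclusion_fraction_is_direct_ratio(self):
        genes, truth = syn.generate_gene_models({"exon_skip": 4}, seed=11)
        for gene, tev in zip(genes, truth.events):
            ab = truth.abundances[gene.id]
            expected = sum(ab[t] for t in tev.inclusion_tx)
            assert syn.true_psi(tev, gene, ab) == pytest.approx(expected)
            assert tev.true_psi == pytest.approx(expected)

    def test_all_inclusion_transcripts_give_one(self):
        genes, truth = syn.generate_gene_models({"mult_exon_skip": 1}, seed=12)
        gene, tev = genes[0], truth.events[0]
        ab = {t.id: 0.0 for t in gene.transcripts}
        for t in tev.inclusion_tx:
            ab[t] = 1.0 / len(tev.inclusion_tx)
        assert syn.true_psi(tev, gene, ab) == pytest.approx(1.0)

    def test_zero_denominator_is_undefined(self):
        genes, truth = syn.generate_gene_models({"exon_skip": 1}, seed=13)
        gene, tev = genes[0], truth.events[0]
        ab = {t.id: 0.0 for t in gene.transcripts}
        assert syn.true_psi(tev, gene, ab) is None

    def test_retention_psi_counts_retaining_transcripts(self):
        genes, truth = syn.generate_gene_models({"intron_retention": 3},
                                                seed=14)
        for gene, tev in zip(genes, truth.events):
            ab = truth.abundances[gene.id]
            retained_tx = [t for t in gene.transcripts if len(t.exons) == 1]
            expected = sum(ab[t.id] for t in retained_tx)
            assert tev.true_psi == pytest.approx(expected)


class TestEvaluateDetection:
    def test_perfect_prediction_scores_one(self):
        genes, truth = syn.generate_gene_models({t: 2 for t in EVENT_TYPES},
                                                seed=15)
        predicted = []
        for gene in genes:
            predicted.extend(detect_events(build_splicing_graph(gene)))
        scores = syn.evaluate_detection(predicted, truth)
        for etype in EVENT_TYPES:
            assert scores[etype]["precision"] == 1.0
            assert scores[etype]["recall"] == 1.0
            assert scores[etype]["f_score"] == 1.0

    def test_partial_prediction_formulas(self):
        genes, truth = syn.generate_gene_models({"exon_skip": 4}, seed=16)
        predicted = []
        for gene in genes[:2]:   # drop half -> recall 0.5
            predicted.extend(detect_events(build_splicing_graph(gene)))
        scores = syn.evaluate_detection(predicted, truth)["exon_skip"]
        assert scores["precision"] == 1.0
        assert scores["recall"] == 0.5
        assert scores["f_score"] == pytest.approx(2 * 0.5 / 1.5)

    def test_empty_predictions_score_zero(self):
        _, truth = syn.generate_gene_models({"exon_skip": 2}, seed=17)
        scores = syn.evaluate_detection([], truth)["exon_skip"]
        assert (scores["precision"], scores["recall"], scores["f_score"]) == \
            (0.0, 0.0, 0.0)


class TestPsiAgreement:
    def test_identity_and_anticorrelation(self):
        vals = [0.1, 0.5, 0.9, 0.3]
        assert syn.psi_agreement(vals, vals) == pytest.approx(1.0)
        assert syn.psi_agreement([1 - v for v in vals], vals) == \
            pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(18)
        x, y = rng.uniform(size=20), rng.uniform(size=20)
        r = syn.psi_agreement(x, y)
        expected = (np.mean((x - x.mean()) * (y - y.mean()))
                    / (x.std() * y.std()))
        assert r == pytest.approx(expected)

    def test_fewer_than_three_pairs_undefined(self):
        assert syn.psi_agreement([0.1, None], [0.2, 0.3]) is None


class TestSimulateEventCounts:
    def test_marginal_dispersion_matches_target(self):
        inc, exc, groups, _ = syn.simulate_event_counts(
            4000, n_per_group=25, depth=200.0, alpha_disp=0.2,
            seed=19)
        a = inc[:, groups == 0]
        mu = a.mean(axis=1)
        v = a.var(axis=1, ddof=1)
        alpha_hat = np.median((v - mu) / mu ** 2)
        assert alpha_hat == pytest.approx(0.2, abs=0.04)

    def test_delta_shifts_group_b_only(self):
        inc, exc, groups, delta = syn.simulate_event_counts(
            500, depth=500.0, delta_psi=0.3, seed=20)
        psi = inc / (inc + exc)
        shift = psi[:, groups == 1].mean() - psi[:, groups == 0].mean()
        assert shift == pytest.approx(0.3, abs=0.03)
        assert np.all(delta == pytest.approx(0.3))

    def test_rank_auroc_degenerate_and_perfect(self):
        assert syn.rank_auroc([1, 2, 3, 10, 11, 12],
                              [0, 0, 0, 1, 1, 1]) == 1.0
        assert syn.rank_auroc([1, 2, 3, 4], [0, 1, 1, 0]) == 0.5


def test_differential_recovery_auroc():
    """Half the events get a 0.3 PSI shift; the GLM ranks them apart from
    the null half with AUROC >= 0.9."""
    from altsplice.difftest import test_events as run_difftest

    null_inc, null_exc, groups, _ = syn.simulate_event_counts(
        300, n_per_group=3, depth=200.0, alpha_disp=0.2, delta_psi=0.0,
        seed=51)
    alt_inc, alt_exc, _, _ = syn.simulate_event_counts(
        300, n_per_group=3, depth=200.0, alpha_disp=0.2, delta_psi=0.3,
        seed=52)
    inc = np.vstack([null_inc, alt_inc])
    exc = np.vstack([null_exc, alt_exc])
    labels = np.array([0] * 300 + [1] * 300)
    quants = syn.quantifications_from_counts(inc, exc)
    results = run_difftest(quants, groups)
    by_id = {q.event.event_id: lab
             for q, lab in zip(quants, labels)}
    scores = [-np.log10(r.p_value) for r in results if r.tested]
    labs = [by_id[r.event_id] for r in results if r.tested]
    assert syn.rank_auroc(scores, labs) >= 0.9


def test_expected_psi_invariant_to_depth(tmp_path):
    """Doubling read depth leaves PSI estimates unchanged within noise."""
    from altsplice.pipeline import PipelineConfig, run_pipeline

    mix = {"exon_skip": 5, "alt_3prime": 5}
    genes, truth = syn.generate_gene_models(mix, seed=53)
    reduced = syn.reduce_annotation(genes)
    psis = {}
    for depth in (50, 100):
        bams = []
        for rep in range(2):
            recs = syn.simulate_alignments(genes, truth.abundances,
                                           depth=depth, read_len=75,
                                           seed=54 + rep + depth)
            bams.append(syn.write_alignments_bam(
                recs, genes, tmp_path / f"d{depth}_{rep}.bam"))
        res = run_pipeline(reduced, bams, PipelineConfig())
        psis[depth] = {q.event.diagnostic_introns: q.mean_psi()
                       for q in res.quantifications}
    shared = set(psis[50]) & set(psis[100])
    assert len(shared) >= 8
    diffs = [psis[100][k] - psis[50][k] for k in shared
             if psis[50][k] is not None and psis[100][k] is not None]
    # no systematic shift with depth, and per-event scatter stays small
    assert abs(np.median(diffs)) < 0.05
    assert np.mean(np.abs(diffs)) < 0.10
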