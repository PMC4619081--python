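"""Exon catalog construction, context utilities and splice-site scoring."""

import numpy as np
import pytest

from exonchrom.catalog import (
    AnnotationError,
    AnnotationModel,
    PwmScorer,
    Transcript,
    build_exon_triplets,
    distance_to_annotated_tss,
    load_annotation,
    mappable_fraction,
    select_candidate_exons,
    splice_site_strength,
)
from exonchrom.intervals import ExonRecord, GenomicInterval
from exonchrom.tracks import SignalTrack

from conftest import random_model, write_annotation


class TestLoadAnnotation:
    def test_toy_two_transcript_fixture(self, tmp_path):
        """Two transcripts sharing one exon: 2 transcripts, 5 distinct exons."""
        genes = [
            {
                "gene_id": "G1",
                "strand": "+",
                "exons": [(100, 200), (500, 600), (900, 1000), (1300, 1400), (1700, 1800)],
                "transcripts": [[0, 1, 2], [0, 3, 4]],
            }
        ]
        gtf, fasta = write_annotation(tmp_path, genes)
        model = load_annotation(gtf, fasta)
        assert len(model.transcripts) == 2
        assert len(model.distinct_exons()) == 5
        t1 = model.transcripts["G1.t1"]
        assert [iv.start for iv in t1.exons] == [100, 500, 900]

    def test_empty_gtf(self, tmp_path):
        gtf = tmp_path / "empty.gtf"
        gtf.write_text("")
        model = load_annotation(gtf)
        assert len(model) == 0

    def test_missing_chromosome_is_hard_error(self, tmp_path):
        genes = [
            {"gene_id": "G1", "strand": "+", "exons": [(10, 60), (100, 160)],
             "transcripts": [[0, 1]]}
        ]
        gtf, fasta = write_annotation(tmp_path, genes, chrom="chrZ", chrom_len=500)
        # rewrite FASTA with a different chromosome name
        fasta.write_text(">chr1\n" + "A" * 60 + "\n")
        with pytest.raises(AnnotationError, match="chrZ"):
            load_annotation(gtf, fasta)

    def test_malformed_line_reports_line_number(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text('chr1\tt\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
                       "chr1\tbroken\n")
        with pytest.raises(AnnotationError, match="line 2"):
            load_annotation(gtf)


class TestSelectCandidateExons:
    def test_hand_enumerated_criteria(self, criteria_fixture):
        """Exactly the two hand-verified exons pass all six criteria."""
        import pyfaidx

        gtf, fasta = criteria_fixture
        model = load_annotation(gtf, fasta)
        genome = pyfaidx.Fasta(str(fasta))
        records = select_candidate_exons(model, genome)
        got = {(r.interval.start, r.interval.end) for r in records}
        assert got == {(1000, 1100), (1800, 1900)}

    def test_exclusion_reasons(self, criteria_fixture):
        """Each planted failure mode excludes its exon for that reason alone."""
        import pyfaidx

        gtf, fasta = criteria_fixture
        model = load_annotation(gtf, fasta)
        genome = pyfaidx.Fasta(str(fasta))
        # relaxing length bounds admits the 700 bp and 40 bp exons
        relaxed = select_candidate_exons(model, genome, min_len=1, max_len=10000)
        got = {(r.interval.start, r.interval.end) for r in relaxed}
        assert (2600, 3300) in got and (4100, 4140) in got
        # the GC-donor exon stays excluded even with relaxed length
        assert (4800, 4900) not in got
        # the close-to-TSS exon comes back only when the distance rule is relaxed
        assert (7300, 7400) not in got
        relaxed_tss = select_candidate_exons(model, genome, min_tss_tts_distance=100)
        assert (7300, 7400) in {(r.interval.start, r.interval.end) for r in relaxed_tss}
        # first-in-one-transcript exon and overlapping pair never qualify
        for bad in [(12800, 12900), (15800, 15900), (15790, 15910)]:
            assert bad not in got

    def test_junctions_recorded_in_transcription_direction(self, criteria_fixture):
        import pyfaidx

        gtf, fasta = criteria_fixture
        model = load_annotation(gtf, fasta)
        genome = pyfaidx.Fasta(str(fasta))
        rec = {(r.interval.start, r.interval.end): r for r in select_candidate_exons(model, genome)}
        r = rec[(1000, 1100)]
        assert r.upstream_junction == (200, 1000)
        assert r.downstream_junction == (1100, 1800)
        assert r.skip_junction == (200, 1800)

    def test_catalog_matches_naive_rescan(self, tmp_path):
        """Catalog equals an independent brute-force re-check of all six
        criteria on a generated annotation."""
        import pyfaidx

        from exonchrom.catalog import fetch_seq
        from exonchrom.simulate import SimConfig, generate_genome_annotation, write_bundle, simulate_bundle

        cfg = SimConfig(n_genes=12, seed=7)
        bundle = simulate_bundle(cfg, out_dir=tmp_path / "b")
        model = load_annotation(tmp_path / "b" / "annotation.gtf", tmp_path / "b" / "genome.fa")
        genome = pyfaidx.Fasta(str(tmp_path / "b" / "genome.fa"))
        records = select_candidate_exons(model, genome)
        got = {(r.interval.chrom, r.interval.start, r.interval.end) for r in records}

        # naive re-scan
        members = {}
        for t in model.transcripts.values():
            for i, iv in enumerate(t.exons):
                members.setdefault((iv.chrom, iv.start, iv.end, iv.strand), []).append((t, i))
        all_exons = list(members)
        expected = set()
        for key, ctx in members.items():
            chrom, s, e, strand = key
            if not (50 <= e - s <= 450):
                continue
            if any(i == 0 or i == len(t.exons) - 1 for t, i in ctx):
                continue
            if any(
                (os, oe) != (s, e) and os < e and oe > s
                for (oc, os, oe, _ost) in all_exons
                if oc == chrom
            ):
                continue
            gene_ids = {t.gene_id for t, _ in ctx}
            pts = [
                p
                for gid in gene_ids
                for tid in model.genes[gid]
                for p in (model.transcripts[tid].tss, model.transcripts[tid].tts)
            ]
            iv = GenomicInterval(chrom, s, e, strand)
            if any(iv.distance_to_point(p) < 600 for p in pts):
                continue
            ok = True
            for t, i in ctx:
                for a, b in ((t.exons[i - 1].end, s), (e, t.exons[i + 1].start)):
                    left = fetch_seq(genome, chrom, a, a + 2)
                    right = fetch_seq(genome, chrom, b - 2, b)
                    if strand == "+":
                        ok &= left == "GT" and right == "AG"
                    else:
                        ok &= left == "CT" and right == "AC"
            if ok:
                expected.add((chrom, s, e))
        assert got == expected and len(got) > 0

    def test_strand_mirror_symmetry(self, tmp_path):
        """Mirroring the whole fixture (coordinates reflected, strands
        flipped, genome reverse-complemented) mirrors the catalog."""
        import pyfaidx

        L = 20000
        genes = [
            {
                "gene_id": "GA",
                "strand": "+",
                "exons": [(100, 200), (1000, 1100), (1800, 1900), (2600, 2700), (3400, 3500)],
                "transcripts": [[0, 1, 2, 3, 4], [0, 1, 3, 4]],
            }
        ]
        mirrored = [
            {
                "gene_id": "GA",
                "strand": "-",
                "exons": [(L - e, L - s) for s, e in reversed(genes[0]["exons"])],
                "transcripts": [
                    [len(genes[0]["exons"]) - 1 - i for i in reversed(idx)]
                    for idx in genes[0]["transcripts"]
                ],
            }
        ]
        d1, d2 = tmp_path / "fwd", tmp_path / "rev"
        d1.mkdir(), d2.mkdir()
        gtf1, fa1 = write_annotation(d1, genes, chrom_len=L)
        gtf2, fa2 = write_annotation(d2, mirrored, chrom_len=L)
        m1 = load_annotation(gtf1, fa1)
        m2 = load_annotation(gtf2, fa2)
        r1 = select_candidate_exons(m1, pyfaidx.Fasta(str(fa1)))
        r2 = select_candidate_exons(m2, pyfaidx.Fasta(str(fa2)))
        fwd = sorted((r.interval.start, r.interval.end) for r in r1)
        rev = sorted((L - r.interval.end, L - r.interval.start) for r in r2)
        assert fwd == rev and len(fwd) > 0


class TestMappableFraction:
    def _exon(self, start=5000, end=5100, strand="+"):
        return ExonRecord(GenomicInterval("chr1", start, end, strand), "g")

    def test_fully_mappable(self):
        track = SignalTrack.constant({"chr1": 10000}, 1.0)
        assert mappable_fraction(self._exon(), track) == 1.0

    def test_partial_window(self):
        """600 of 900 positions mappable -> 2/3 (fails the 0.75 filter)."""
        # acceptor at 5000; window [4550, 5450); unmappable on [4550, 4850)
        track = SignalTrack(
            {"chr1": (np.array([0, 4550, 4850]), np.array([4550, 4850, 10000]),
                      np.array([1.0, 0.0, 1.0]))}
        )
        assert mappable_fraction(self._exon(), track) == pytest.approx(600 / 900)

    def test_threshold_rule(self):
        """Positions with value < 1 count as unmappable."""
        track = SignalTrack.constant({"chr1": 10000}, 0.5)
        assert mappable_fraction(self._exon(), track) == 0.0

    def test_truncated_at_chromosome_end(self):
        track = SignalTrack.constant({"chr1": 5200}, 1.0)
        # acceptor of a minus-strand exon is its genomic end - 1
        frac = mappable_fraction(self._exon(strand="-"), track)
        assert frac == 1.0


class TestExonTriplets:
    def _model(self):
        exons = tuple(
            GenomicInterval("chr1", s, s + 100, "+") for s in (100, 1000, 2000, 3000, 4000)
        )
        t = Transcript("t1", "g1", "chr1", "+", exons)
        return AnnotationModel({"t1": t}), exons

    def _record(self, exons, i=2):
        return ExonRecord(
            exons[i], "g1", frozenset(["t1"]),
            (exons[i - 1].end, exons[i].start), (exons[i].end, exons[i + 1].start),
        )

    def test_adjacent_nonsignificant_flanks(self):
        model, exons = self._model()
        results = {f"chr1:{s}-{s + 100}:+": 0.9 for s in (1000, 3000)}
        trip = build_exon_triplets(self._record(exons), results, model)
        assert trip.complete
        assert trip.upstream.start == 1000 and trip.downstream.start == 3000

    def test_significant_neighbor_skipped(self):
        model, exons = self._model()
        results = {"chr1:1000-1100:+": 0.001}  # upstream neighbor regulated
        trip = build_exon_triplets(self._record(exons), results, model)
        assert trip.upstream.start == 100  # next-nearest
        assert trip.downstream.start == 3000

    def test_first_exon_neighbor_incomplete(self):
        model, exons = self._model()
        rec = self._record(exons, i=1)  # neighbor on the left is the first exon
        results = {"chr1:100-200:+": 0.001}  # and it is significant
        trip = build_exon_triplets(rec, results, model)
        assert trip.upstream is None and not trip.complete


class TestTssDistance:
    def test_single_tss(self):
        exons = (
            GenomicInterval("chr1", 100, 200, "+"),
            GenomicInterval("chr1", 1100, 1200, "+"),
            GenomicInterval("chr1", 2000, 2100, "+"),
        )
        model = AnnotationModel({"t1": Transcript("t1", "g", "chr1", "+", exons)})
        rec = ExonRecord(exons[1], "g", frozenset(["t1"]))
        assert distance_to_annotated_tss(rec, model) == 1000

    def test_minimum_over_transcripts(self):
        shared = GenomicInterval("chr1", 2700, 2800, "+")
        t1 = Transcript("t1", "g", "chr1", "+",
                        (GenomicInterval("chr1", 2000, 2100, "+"), shared,
                         GenomicInterval("chr1", 3500, 3600, "+")))
        t2 = Transcript("t2", "g", "chr1", "+",
                        (GenomicInterval("chr1", 700, 800, "+"), shared,
                         GenomicInterval("chr1", 3500, 3600, "+")))
        model = AnnotationModel({"t1": t1, "t2": t2})
        rec = ExonRecord(shared, "g", frozenset(["t1", "t2"]))
        assert distance_to_annotated_tss(rec, model) == 700

    def test_matches_brute_force_on_random_models(self, rng):
        for _ in range(200):
            model = random_model(rng)
            t = list(model.transcripts.values())[0]
            iv = t.exons[2]
            members = [
                tid for tid, tr in model.transcripts.items() if iv in tr.exons
            ]
            rec = ExonRecord(iv, "G0", frozenset(members))
            oracle = min(
                abs(iv.five_prime - model.transcripts[tid].tss) for tid in members
            )
            assert distance_to_annotated_tss(rec, model) == oracle


class TestSpliceSiteStrength:
    def test_uniform_pwm_scores_zero(self, tmp_path):
        genes = [{"gene_id": "g", "strand": "+",
                  "exons": [(100, 200), (1000, 1100), (2000, 2100)],
                  "transcripts": [[0, 1, 2]]}]
        gtf, fasta = write_annotation(tmp_path, genes)
        import pyfaidx

        rec = ExonRecord(GenomicInterval("chr1", 1000, 1100, "+"), "g",
                         frozenset(["g.t1"]), (200, 1000), (1100, 2000))
        score = splice_site_strength(rec, pyfaidx.Fasta(str(fasta)), PwmScorer())
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_consensus_pwm_is_maximal(self):
        """A PWM concentrated on one sequence scores that sequence highest."""
        rng = np.random.default_rng(0)
        donor = rng.dirichlet([0.2] * 4, size=9)
        scorer = PwmScorer(donor_pwm=donor)
        consensus = "".join("ACGT"[i] for i in donor.argmax(axis=1))
        best = scorer.donor_score(consensus)
        for _ in range(50):
            other = "".join(rng.choice(list("ACGT"), size=9))
            assert scorer.donor_score(other) <= best + 1e-12

    def test_matches_naive_log_odds_sum(self, rng):
        donor = rng.dirichlet([1] * 4, size=9)
        acceptor = rng.dirichlet([1] * 4, size=23)
        scorer = PwmScorer(donor, acceptor)
        seq = "".join(rng.choice(list("ACGT"), size=23))
        naive = sum(
            np.log2(acceptor[i, "ACGT".index(b)] / 0.25) for i, b in enumerate(seq)
        )
        assert scorer.acceptor_score(seq) == pytest.approx(naive, rel=1e-10)

    def test_n_in_window_is_undefined(self):
        scorer = PwmScorer()
        assert np.isnan(scorer.donor_score("ACGNACGTA"))
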