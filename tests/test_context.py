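"""CAGE expression and TSS distances, ChIA-PET overlap, chromHMM runs,
motif enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from exonchrom.context import (
    CageCluster,
    ChiaPetLink,
    cage_occupancy_in_exons,
    compare_tss_proximity,
    count_chia_pet_interactions,
    distance_to_used_tss,
    gene_expression_from_cage,
    motif_enrichment,
    same_state_extension,
    tss_vs_exon_mark_shift,
)
from exonchrom.intervals import ExonRecord, GenomicInterval
from exonchrom.tracks import SignalTrack


def C(start, end, score, chrom="chr1"):
    return CageCluster(GenomicInterval(chrom, start, end), score)


class TestGeneExpression:
    def test_single_cluster_within_radius(self):
        expr = gene_expression_from_cage([C(1040, 1060, 7.0)], {"g": [("chr1", "+", 1000)]})
        assert expr["g"] == 7.0

    def test_cluster_beyond_radius_ignored(self):
        expr = gene_expression_from_cage([C(1150, 1160, 7.0)], {"g": [("chr1", "+", 1000)]})
        assert expr["g"] == 0.0

    def test_two_tss_scores_summed(self):
        clusters = [C(990, 1010, 3.0), C(5030, 5050, 4.0)]
        expr = gene_expression_from_cage(
            clusters, {"g": [("chr1", "+", 1000), ("chr1", "+", 5000)]}
        )
        assert expr["g"] == 7.0

    def test_equidistant_tie_goes_upstream(self):
        clusters = [C(1995, 2006, 5.0)]  # midpoint 2000, TSSs at 1950 and 2050
        expr = gene_expression_from_cage(
            clusters, {"a": [("chr1", "+", 1950)], "b": [("chr1", "+", 2051)]}
        )
        # distances: to 1950 -> 45; to 2051 -> 46; closest wins
        assert expr == {"a": 5.0, "b": 0.0}

    def test_additivity_under_cluster_split(self, rng):
        """Splitting one cluster into two adjacent halves with the same total
        score leaves gene expression unchanged."""
        tss = {"g": [("chr1", "+", 1000)]}
        whole = [C(980, 1020, 6.0)]
        split = [C(980, 1000, 2.5), C(1000, 1020, 3.5)]
        assert gene_expression_from_cage(whole, tss)["g"] == pytest.approx(
            gene_expression_from_cage(split, tss)["g"]
        )


class TestUsedTssDistance:
    def _exon(self, start=5000, end=5100):
        return ExonRecord(GenomicInterval("chr1", start, end, "+"), "g")

    def test_min_score_filter(self):
        """Nearby low-score cluster ignored in favour of distant scored one."""
        clusters = [C(4480, 4500, 0.5), C(7100, 7120, 3.0)]
        d, cl = distance_to_used_tss(self._exon(), clusters)
        assert d == 2001 and cl.score == 3.0

    def test_cluster_inside_exon_distance_zero(self):
        d, _ = distance_to_used_tss(self._exon(), [C(5040, 5060, 2.0)])
        assert d == 0

    def test_no_qualifying_cluster(self):
        d, cl = distance_to_used_tss(self._exon(), [C(100, 120, 0.2)])
        assert d is None and cl is None

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            clusters = [
                C(int(s), int(s) + 10, float(rng.uniform(0, 3)))
                for s in rng.integers(0, 100_000, size=20)
            ]
            s = int(rng.integers(0, 99_000))
            exon = self._exon(s, s + int(rng.integers(50, 400)))
            d, _ = distance_to_used_tss(exon, clusters)
            iv = exon.interval
            brute = [
                iv.distance_to(c.interval) for c in clusters if c.score >= 1
            ]
            assert d == (min(brute) if brute else None)


class TestTssProximityTally:
    def test_categories(self):
        tally = compare_tss_proximity([1000, 300, 50, None], [5000, 300, 20, 10])
        assert tally == {
            "closer_in_Chigher": 1, "closer_in_Clower": 1, "same": 1, "undefined": 1,
        }


class TestChiaPet:
    def _exon(self):
        return ExonRecord(GenomicInterval("chr1", 5000, 5100, "+"), "g")

    def test_anchored_link_counts(self):
        links = [ChiaPetLink(GenomicInterval("chr1", 5050, 5250), GenomicInterval("chr1", 9000, 9200))]
        n, has = count_chia_pet_interactions(self._exon(), links)
        assert (n, has) == (1, True)

    def test_abutting_anchor_half_open(self):
        """Anchor starting exactly at the exon end does not overlap."""
        links = [ChiaPetLink(GenomicInterval("chr1", 5100, 5300), GenomicInterval("chr1", 9000, 9200))]
        n, has = count_chia_pet_interactions(self._exon(), links)
        assert (n, has) == (0, False)

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            links = [
                ChiaPetLink(
                    GenomicInterval("chr1", int(a), int(a) + 150),
                    GenomicInterval("chr1", int(b), int(b) + 150),
                )
                for a, b in zip(rng.integers(0, 50_000, 15), rng.integers(50_000, 99_000, 15))
            ]
            s = int(rng.integers(0, 98_000))
            exon = ExonRecord(GenomicInterval("chr1", s, s + 120, "+"), "g")
            n, _ = count_chia_pet_interactions(exon, links)
            iv = exon.interval
            brute = sum(
                1
                for ln in links
                if (ln.anchor1.start < iv.end and iv.start < ln.anchor1.end)
                or (ln.anchor2.start < iv.end and iv.start < ln.anchor2.end)
            )
            assert n == brute


class TestSameStateExtension:
    def _seg(self, rows):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": s, "end": e, "state": st} for s, e, st in rows]
        )

    def _exon(self, start=5000, end=5100):
        return ExonRecord(GenomicInterval("chr1", start, end, "+"), "g")

    def test_same_segment(self):
        seg = self._seg([(0, 10000, "Tss")])
        assert same_state_extension(self._exon(), 800, seg)

    def test_different_state_between(self):
        seg = self._seg([(0, 2000, "Tss"), (2000, 4000, "Quies"), (4000, 10000, "Tss")])
        assert not same_state_extension(self._exon(), 800, seg)

    def test_adjacent_same_label_merged(self):
        seg = self._seg([(0, 3000, "Tss"), (3000, 10000, "Tss")])
        assert same_state_extension(self._exon(), 800, seg)

    def test_coverage_gap_breaks_run(self):
        seg = self._seg([(0, 2000, "Tss"), (4000, 10000, "Tss")])
        assert not same_state_extension(self._exon(), 800, seg)


class TestMotifEnrichment:
    def test_closed_form(self):
        """All 10 foreground exons hit, 100 background clean: p = 1/C(110,10)."""
        ids = [f"e{i}" for i in range(110)]
        occ = pd.DataFrame({"M1": [1] * 10 + [0] * 100}, index=ids)
        out = motif_enrichment(ids[:10], ids[10:], occ)
        assert out.loc["M1", "p"] == pytest.approx(1 / math.comb(110, 10), rel=1e-12)

    def test_absent_motif_p_one(self):
        ids = ["a", "b", "c", "d"]
        occ = pd.DataFrame({"M1": [0, 0, 0, 0]}, index=ids)
        out = motif_enrichment(ids[:2], ids[2:], occ)
        assert out.loc["M1", "p"] == 1.0

    def test_empty_foreground_error(self):
        occ = pd.DataFrame({"M1": [1]}, index=["a"])
        with pytest.raises(ValueError):
            motif_enrichment([], ["a"], occ)

    def test_uniform_hits_rarely_significant(self):
        """50 % hit rate everywhere: significant in <= 6 % of null draws."""
        hits = 0
        reps = 400
        ids = [f"e{i}" for i in range(60)]
        for i in range(reps):
            rng = np.random.default_rng(i)
            occ = pd.DataFrame({"M1": rng.integers(0, 2, size=60)}, index=ids)
            out = motif_enrichment(ids[:15], ids[15:], occ)
            hits += int(out["q"].iloc[0] < 0.05)
        assert hits / reps <= 0.06


class TestTssVsExonShift:
    def _setup(self, exon_extra=2.0, tss_extra=0.0):
        exon = ExonRecord(GenomicInterval("chr1", 5000, 5100, "+"), "g")
        tss = 1000
        tracks = {}
        for cell, bump in (("hi", 1.0), ("lo", 0.0)):
            base = np.full(200, 4.0)
            starts = np.arange(0, 10000, 50)
            vals = np.full(len(starts), 4.0)
            vals[(starts >= 800) & (starts < 1200)] += tss_extra * bump
            vals[(starts >= 5000) & (starts < 5100)] += exon_extra * bump
            tracks[cell] = {
                "H3K9ac": SignalTrack({"chr1": (starts, starts + 50, vals)})
            }
        calls = pd.DataFrame(
            [{"exon_id": exon.exon_id, "c_higher": "hi", "c_lower": "lo"}]
        )
        return calls, {exon.exon_id: exon}, {exon.exon_id: tss}, tracks

    def test_exon_only_shift_detected_in_medians(self):
        calls, exons, tss, tracks = self._setup(exon_extra=4.0)
        out = tss_vs_exon_mark_shift(calls, exons, tss, tracks, marks=("H3K9ac",))
        assert out.loc["H3K9ac", "median_delta_exon"] > out.loc["H3K9ac", "median_delta_tss"]

    def test_antisymmetry_under_role_swap(self):
        calls, exons, tss, tracks = self._setup(exon_extra=4.0)
        swapped = calls.copy()
        swapped[["c_higher", "c_lower"]] = swapped[["c_lower", "c_higher"]].to_numpy()
        a = tss_vs_exon_mark_shift(calls, exons, tss, tracks, marks=("H3K9ac",))
        b = tss_vs_exon_mark_shift(swapped, exons, tss, tracks, marks=("H3K9ac",))
        assert a.loc["H3K9ac", "median_delta_exon"] == pytest.approx(
            -b.loc["H3K9ac", "median_delta_exon"]
        )


class TestCageOccupancy:
    def test_zero_everywhere(self):
        track = SignalTrack({"chr1": (np.array([0]), np.array([1]), np.array([0.0]))})
        exons = [ExonRecord(GenomicInterval("chr1", 100, 200, "+"), "g")]
        out = cage_occupancy_in_exons(exons, track)
        assert (out["eas"] == 0).all()

    def test_exon_signal_marginal_vs_tss(self):
        track = SignalTrack(
            {"chr1": (np.array([0, 900, 1100]), np.array([900, 1100, 10000]),
                      np.array([0.1, 50.0, 0.1]))}
        )
        exons = [ExonRecord(GenomicInterval("chr1", 5000, 5100, "+"), "g")]
        tss = [GenomicInterval("chr1", 900, 1100)]
        out = cage_occupancy_in_exons(exons, track, tss_intervals=tss)
        exon_med = out.loc[out["set"] == "exon", "eas"].median()
        tss_med = out.loc[out["set"] == "tss", "eas"].median()
        assert exon_med < 0.05 * tss_med
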