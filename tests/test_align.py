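"""Mapping modes, the Lm/Lu split, pileups and allele ranking."""

import numpy as np
import pytest

from hetcorr import align as al
from hetcorr import dp
from hetcorr import simulate as sim
from hetcorr.simulate import Read, ReadSet, revcomp


def brute_force_sw(a, b, match=1, mismatch=-1, gap=-2):
    """Independent quadratic Smith-Waterman score (plain python)."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
            best = max(best, H[i][j])
    return best


class TestDPKernels:
    def test_smith_waterman_matches_brute_force(self, rng):
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(3, 14)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(3, 14)))
            assert dp.smith_waterman(a, b).score == brute_force_sw(a, b)

    def test_exact_overlap_score_and_spans(self):
        res = dp.smith_waterman("AAAACGTACGT", "CGTACGTTTTT")
        assert res.score == 7  # shared CGTACGT
        assert res.query_span == (4, 11)
        assert res.target_span == (0, 7)
        assert res.ops == [("=", 7)]

    def test_semiglobal_places_full_query(self):
        res = dp.semiglobal("CGTA", "AAACGTAAAA")
        assert res.score == 4
        assert res.target_span == (3, 7)
        assert res.query_span == (0, 4)


class TestMapReads:
    def test_exact_substring_maps_fully(self, small_haplome):
        g = small_haplome.ref
        read = Read(id="x", sequence=g[1000:1300])
        (aln,) = al.map_reads([read], "ref", g, mode="seeded")
        assert aln.pct_mapped == 1.0
        assert aln.target_start == 1000
        assert aln.ops == [("=", 300)]

    def test_reverse_complement_same_locus(self, small_haplome):
        g = small_haplome.ref
        read = Read(id="x", sequence=revcomp(g[1000:1300]))
        (aln,) = al.map_reads([read], "ref", g, mode="seeded")
        assert aln.target_start == 1000
        assert aln.strand == "-"
        assert aln.pct_mapped == 1.0

    def test_seeded_agrees_with_exhaustive_oracle(self, small_haplome):
        reads = sim.simulate_reads(
            small_haplome, 5.5, 500, 450,
            sim.ErrorModelParams.long_read(0.12), seed=3,
        ).reads[:50]
        assert len(reads) == 50
        g = small_haplome.ref
        seeded = {a.read_id: a for a in al.map_reads(reads, "ref", g, mode="seeded", both_strands=False)}
        exact = {a.read_id: a for a in al.map_reads(reads, "ref", g, mode="exhaustive", both_strands=False)}
        for r in reads:
            assert r.id in seeded
            diff = seeded[r.id].pct_mapped - exact[r.id].pct_mapped
            assert abs(diff) <= 0.01
            # the heuristic never claims more mapped bases than the oracle
            assert diff <= 0.01

    def test_truth_anchored_requires_spans(self, small_haplome):
        read = Read(id="x", sequence="ACGTACGT")
        with pytest.raises(ValueError):
            al.map_reads([read], "ref", small_haplome.ref, mode="truth_anchored")

    def test_truth_anchored_recovers_noiseless_placement(self, small_haplome):
        reads = sim.simulate_reads(
            small_haplome, 1, 300, 100, sim.ErrorModelParams(0, 0, 0), seed=8
        )
        alns = al.map_reads(reads, "ref", small_haplome.hap1, mode="truth_anchored")
        by_id = {a.read_id: a for a in alns}
        for r in reads:
            start, end, _, hap = r.truth_span
            a = by_id[r.id]
            assert a.target_start == start
            # hap2 reads mismatch hap1 only at het sites
            n_sub = sum(n for op, n in a.ops if op == "X")
            if hap == 1:
                assert n_sub == 0 and a.pct_mapped == 1.0
            else:
                assert n_sub <= len(small_haplome.het_sites)


class TestSplitLongReads:
    def _aln(self, rid, n_match, n_ins):
        ops = [("=", n_match)] + ([("I", n_ins)] if n_ins else [])
        return al.Alignment(rid, "ref", 0, ops, read_length=n_match + n_ins)

    def test_partition_boundaries(self):
        reads = ReadSet([Read(id=i, sequence="A" * 100) for i in ("hi", "exact", "none")])
        alns = [self._aln("hi", 95, 5), self._aln("exact", 90, 10)]
        Lm, Lu = al.split_long_reads(reads, alns, 0.90)
        assert [r.id for r in Lm] == ["hi"]  # 0.95 > 0.90
        assert [r.id for r in Lu] == ["exact", "none"]  # 0.90 exactly, unmapped
        assert len(Lm) + len(Lu) == len(reads)


class TestPileup:
    def _reads(self, seqs):
        return {f"r{i}": Read(id=f"r{i}", sequence=s) for i, s in enumerate(seqs)}

    def test_uniform_column(self):
        reads = self._reads(["A", "A", "A"])
        alns = [al.Alignment(f"r{i}", "t", 10, [("=", 1)], 1) for i in range(3)]
        p = al.build_pileup(alns, reads, 20)
        assert p.column(10).counts == {"A": 3}
        assert p.column(10).depth == 3

    def test_deletion_counts_as_null(self):
        reads = self._reads(["CAC", "CAC", "CC"])
        alns = [
            al.Alignment("r0", "t", 0, [("=", 3)], 3),
            al.Alignment("r1", "t", 0, [("=", 3)], 3),
            al.Alignment("r2", "t", 0, [("=", 1), ("D", 1), ("=", 1)], 2),
        ]
        p = al.build_pileup(alns, reads, 3)
        assert p.column(1).counts == {"A": 2, "N": 1}
        assert p.column(1).depth == 3

    def test_manual_tally_fixture(self):
        # five alignments with mixed ops over a 6-long target
        reads = self._reads(["ACGTAC", "ACCTAC", "CGXTA".replace("X", "G"), "ACG", "GTAC"])
        alns = [
            al.Alignment("r0", "t", 0, [("=", 6)], 6),
            al.Alignment("r1", "t", 0, [("=", 2), ("X", 1), ("=", 3)], 6),
            al.Alignment("r2", "t", 1, [("=", 5)], 5),
            al.Alignment("r3", "t", 0, [("=", 2), ("I", 1)], 3),
            al.Alignment("r4", "t", 1, [("D", 1), ("=", 4)], 4),
        ]
        p = al.build_pileup(alns, reads, 6)
        assert p.column(0).counts == {"A": 3}
        assert p.column(1).counts == {"C": 4, "N": 1}
        assert p.column(2).counts == {"G": 3, "C": 1}
        assert p.n_insertions == 1
        # conservation: total depth equals total =/X/D columns
        expect = sum(n for a in alns for op, n in a.ops if op in "=XD")
        assert int(p.depth().sum()) == expect

    def test_spacer_mask_zeroes_columns(self):
        reads = self._reads(["AAAA"])
        alns = [al.Alignment("r0", "t", 0, [("=", 4)], 4)]
        mask = np.array([False, True, True, False])
        p = al.build_pileup(alns, reads, 4, spacer_mask=mask)
        assert p.column(0).depth == 1 and p.column(1).depth == 0


class TestRankAlleles:
    @pytest.mark.parametrize(
        "counts,expected,d",
        [
            ({"A": 5, "C": 5}, [("A", 5), ("C", 5)], 2),  # tie broken A first
            ({"T": 7}, [("T", 7)], 1),
            (
                {"A": 3, "C": 2, "G": 1, "T": 1, "N": 1},
                [("A", 3), ("C", 2), ("G", 1), ("T", 1), ("N", 1)],
                5,
            ),
        ],
    )
    def test_ordering_and_d(self, counts, expected, d):
        rc = al.rank_alleles(al.PileupColumn(0, counts))
        assert rc.alleles == expected
        assert rc.d == d

    def test_suffix_totals(self):
        rc = al.rank_alleles(al.PileupColumn(0, {"A": 3, "C": 2, "G": 1, "T": 1, "N": 1}))
        assert rc.suffix_totals() == [8, 5, 3, 2, 1]

    def test_count_multiset_preserved(self, rng):
        for _ in range(20):
            counts = {a: int(c) for a, c in zip("ACGTN", rng.integers(0, 9, 5))}
            rc = al.rank_alleles(al.PileupColumn(0, counts))
            assert sorted(rc.counts, reverse=True) == rc.counts
            assert sorted(rc.counts) == sorted(c for c in counts.values() if c > 0)


class TestMapShortToLu:
    def test_exact_short_read_contributes(self, small_haplome):
        g = small_haplome.ref
        lu = ReadSet([Read(id="lu0", sequence=g[2000:2500])])
        S = ReadSet([Read(id="s0", sequence=g[2100:2200])])
        maps = al.map_short_to_lu(S, lu)
        alns, pileup = maps["lu0"]
        assert len(alns) == 1 and alns[0].target_start == 100
        assert pileup.column(150).counts == {g[2150]: 1}

    def test_unmappable_lu_read_gets_empty_pileup(self, rng):
        lu = ReadSet([Read(id="lu0", sequence="".join(rng.choice(list("ACGT"), 300)))])
        S = ReadSet([Read(id="s0", sequence="".join(rng.choice(list("ACGT"), 100)))])
        maps = al.map_short_to_lu(S, lu)
        assert maps["lu0"][1].depth().sum() == 0

    def test_manual_pileup_with_four_short_reads(self, small_haplome):
        g = small_haplome.ref
        lu = ReadSet([Read(id="lu0", sequence=g[3000:3400])])
        S = ReadSet(
            [
                Read(id="s0", sequence=g[3000:3100]),
                Read(id="s1", sequence=g[3050:3150]),
                Read(id="s2", sequence=revcomp(g[3050:3150])),
                Read(id="s3", sequence=g[3300:3400]),
            ]
        )
        maps = al.map_short_to_lu(S, lu)
        _, pileup = maps["lu0"]
        assert pileup.column(75).counts == {g[3075]: 3}
        assert pileup.column(350).counts == {g[3350]: 1}


class TestSamRoundTrip:
    def test_alignments_survive_sam(self, small_haplome, tmp_path):
        g = small_haplome.ref
        reads = sim.simulate_reads(
            small_haplome, 0.2, 400, 200,
            sim.ErrorModelParams.long_read(0.1), seed=5, rc_fraction=0.5,
        )
        alns = al.map_reads(reads, "ref", g, mode="seeded")
        path = str(tmp_path / "out.sam")
        al.write_sam(path, alns, reads.by_id(), "ref", len(g))
        back, back_reads = al.read_sam(path, g)
        by_id = {a.read_id: a for a in back}
        orig_reads = reads.by_id()
        for a in alns:
            b = by_id[a.read_id]
            assert (b.target_start, b.strand, b.ops) == (a.target_start, a.strand, a.ops)
            assert back_reads.by_id()[a.read_id].sequence == orig_reads[a.read_id].sequence
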