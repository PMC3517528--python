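import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import random_seq
from mitekit.annotate import (
    ClassifyParams, classify_copy, detect_tir, detect_tsd, gene_context, orf_scan,
)
from mitekit.mining import ElementCopy
from mitekit.seqio import GenomicInterval, revcomp

TIR = "CAGGGGTAGGC"


def make_copy(seq, left="A" * 30, right="T" * 30):
    return ElementCopy(
        interval=GenomicInterval("chr1", 100, 100 + len(seq)),
        aligned_query_span=(0, len(seq)),
        identity=1.0,
        copy_seq=seq,
        left_flank=left,
        right_flank=right,
    )


class TestDetectTir:
    def test_perfect_11bp_tir(self, rng):
        interior = random_seq(rng, 300)
        seq = TIR + interior + revcomp(TIR)
        ann = detect_tir(seq, min_tir=5, max_tir=30, budget=0)
        assert ann.present
        assert ann.length >= 11
        assert ann.mismatches == 0
        assert ann.left_seq == seq[: ann.length]
        assert ann.right_seq == seq[-ann.length :]

    def test_palindrome_free_sequence_absent(self):
        # constructed so no prefix L in [5,30] matches revcomp(suffix L):
        # prefix is all A, suffix is all T, so revcomp(suffix) is all A...
        # use all-A prefix with all-A suffix instead: revcomp = all T
        seq = "A" * 40 + "C" * 20 + "A" * 40
        ann = detect_tir(seq, min_tir=5, max_tir=30, budget=0)
        assert not ann.present
        # brute force confirms no qualifying L
        for L in range(5, 31):
            assert sum(
                x != y for x, y in zip(seq[:L], revcomp(seq[-L:]))
            ) > 0

    def test_one_substitution_within_budget(self, rng):
        interior = random_seq(rng, 200)
        damaged = "T" + TIR[1:]
        seq = damaged + interior + revcomp(TIR)
        ann = detect_tir(seq, min_tir=11, max_tir=11, budget=1)
        assert ann.present and ann.mismatches == 1

    def test_longest_qualifying_length_returned(self, rng):
        x = "ACGGTTCAACGGT"  # 13 bp terminal repeat
        seq = x + random_seq(rng, 100) + revcomp(x)
        ann = detect_tir(seq, min_tir=5, max_tir=13, budget=0)
        assert ann.length == 13

    def test_too_short_copy_raises(self):
        with pytest.raises(ValueError):
            detect_tir("ACGTACGT", min_tir=5, max_tir=30, budget=0)

    def test_planted_inverted_repeat_always_found(self, rng):
        """Any X-prefixed, revcomp(X)-suffixed copy has a TIR >= |X|."""
        for _ in range(20):
            L = int(rng.integers(5, 31))
            x = random_seq(rng, L)
            seq = x + random_seq(rng, 150) + revcomp(x)
            ann = detect_tir(seq, min_tir=5, max_tir=30, budget=0)
            assert ann.present and ann.length >= L


class TestDetectTsd:
    def test_scaf72_style_one_mismatch(self):
        ann = detect_tsd("A" * 22 + "CTCTACCC", "CTCTACTC" + "A" * 22,
                         tsd_len=8, budget=1)
        assert ann.present and ann.mismatches == 1
        assert ann.left_seq == "CTCTACCC"
        assert ann.right_seq == "CTCTACTC"

    def test_identical_flanking_words(self):
        ann = detect_tsd("GGGGTACAGATT", "TACAGATTCCCC", tsd_len=8, budget=0)
        assert ann.present and ann.mismatches == 0

    def test_unrelated_flanks_absent(self):
        ann = detect_tsd("A" * 8, "TGTGTGTG", tsd_len=8, budget=1)
        assert not ann.present and ann.mismatches > 1

    def test_short_flank_raises(self):
        with pytest.raises(ValueError):
            detect_tsd("ACGT", "ACGTACGT", tsd_len=8, budget=1)

    def test_symmetric_under_locus_revcomp(self, rng):
        """Reverse-complementing the whole locus swaps and revcomps the
        flanks but leaves the mismatch count unchanged."""
        for _ in range(20):
            left = random_seq(rng, 12)
            right = random_seq(rng, 12)
            a = detect_tsd(left, right, 8, 1)
            b = detect_tsd(revcomp(right), revcomp(left), 8, 1)
            assert a.mismatches == b.mismatches


class TestClassifyCopy:
    def _tir(self, present=True):
        return detect_tir(TIR + "A" * 300 + revcomp(TIR), 5, 30, 1) if present \
            else detect_tir("A" * 40 + "C" * 20 + "A" * 40, 5, 30, 0)

    def _tsd(self, present=True):
        if present:
            return detect_tsd("G" * 22 + "AAATAAAA", "AAATAAAA" + "G" * 22, 8, 1)
        return detect_tsd("A" * 8, "TGTGTGTG", 8, 1)

    def test_intact_mite(self):
        copy = make_copy("A" * 610)
        cls = classify_copy(copy, self._tir(), self._tsd(), reference_len=610)
        assert cls.label == "intact_mite"

    def test_internally_deleted_copy_degenerate(self):
        copy = make_copy("A" * 300)
        cls = classify_copy(copy, self._tir(False), self._tsd(), reference_len=610)
        assert cls.label == "degenerate"
        assert "tir" in cls.rationale

    def test_long_copy_full_length_candidate(self):
        copy = make_copy("A" * 2400)
        cls = classify_copy(copy, self._tir(False), self._tsd(False),
                            reference_len=610)
        assert cls.label == "full_length_candidate"

    def test_length_window_boundaries(self):
        params = ClassifyParams(len_lo=0.8, len_hi=1.2)
        tir, tsd = self._tir(), self._tsd()
        assert classify_copy(make_copy("A" * 488), tir, tsd, 610, params).label == "intact_mite"
        assert classify_copy(make_copy("A" * 487), tir, tsd, 610, params).label == "degenerate"


class TestOrfScan:
    def test_simple_orf_with_stop(self):
        seq = "ATG" + "GCT" * 30 + "TAA"
        orfs = orf_scan(seq, min_aa=20)
        assert orfs == [(1, 0, len(seq), 31)]

    def test_orf_without_stop_excluded(self):
        seq = "ATG" + "GCT" * 40  # runs off the end, no stop
        assert orf_scan(seq, min_aa=20) == []

    def test_revcomp_reported_on_reverse_frame(self):
        seq = "ATG" + "GCT" * 30 + "TAA"
        rc = revcomp(seq)
        orfs = orf_scan(rc, min_aa=20)
        assert len(orfs) == 1
        frame, start, end, aa = orfs[0]
        assert frame < 0
        assert (start, end, aa) == (0, len(seq), 31)

    def test_against_biopython_translation(self, rng):
        """Brute-force oracle: six-frame translation via Bio.Seq."""
        seq = random_seq(rng, 600)
        found = {(f, s, e, aa) for f, s, e, aa in orf_scan(seq, min_aa=15)}
        expected = set()
        for sense, s in ((1, seq), (-1, revcomp(seq))):
            for off in range(3):
                tail = s[off:]
                tail = tail[: len(tail) - len(tail) % 3]
                prot = str(Seq(tail).translate())
                i = 0
                while True:
                    m = prot.find("M", i)
                    if m == -1:
                        break
                    stop = prot.find("*", m)
                    if stop == -1:
                        break
                    aa = stop - m
                    if aa >= 15:
                        lo = off + 3 * m
                        hi = off + 3 * (stop + 1)
                        if sense == -1:
                            lo, hi = len(seq) - hi, len(seq) - lo
                        expected.add((sense * (off + 1), lo, hi, aa))
                    i = stop + 1
        assert found == expected


class TestGeneContext:
    genes = [GenomicInterval("chr1", 10_000, 12_000)]

    def _at(self, start, end):
        return ElementCopy(
            interval=GenomicInterval("chr1", start, end),
            aligned_query_span=(0, end - start), identity=1.0,
            copy_seq="A" * (end - start), left_flank="", right_flank="",
        )

    def test_overlapping_copy_inside(self):
        assert gene_context([self._at(11_000, 11_600)], self.genes) == ["inside"]

    def test_1999_bp_away_is_near(self):
        assert gene_context([self._at(13_999, 14_500)], self.genes) == ["near"]

    def test_2000_bp_away_is_distal(self):
        assert gene_context([self._at(14_000, 14_500)], self.genes) == ["distal"]

    def test_adjacent_distance_zero_is_near(self):
        assert gene_context([self._at(12_000, 12_600)], self.genes) == ["near"]

    def test_unknown_seq_id_raises(self):
        with pytest.raises(ValueError):
            gene_context([self._at(0, 10)],
                         [GenomicInterval("chrX", 0, 10)],
                         known_seq_ids={"chr1"})

    def test_no_genes_on_contig_distal(self):
        assert gene_context([self._at(0, 600)],
                            [GenomicInterval("chr2", 0, 10)]) == ["distal"]
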