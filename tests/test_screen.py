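import numpy as np
import pytest

from recodon.errors import InvalidParameterError, PatternError
from recodon.genetics import reverse_complement
from recodon.screen import (
    DesignConstraints,
    MotifPattern,
    find_at_runs,
    find_direct_repeats,
    find_inverted_repeats,
    find_palindromes,
    scan_motifs,
    screen,
)

from oracles import (
    brute_at_runs,
    brute_direct_repeats,
    brute_inverted_repeats,
    brute_motif_hits,
    brute_palindromes,
)


def _random_seq(rng, n):
    return "".join(rng.choice(np.array(list("ACGT")), size=n))


class TestScanMotifs:
    def test_single_occurrence(self):
        hits = scan_motifs("GGGAATAAAGGG", [MotifPattern("AATAAA", "polyA")])
        assert [(v.start, v.end) for v in hits] == [(3, 9)]
        assert hits[0].matched == "AATAAA"

    def test_degeneracy_expansion(self):
        assert scan_motifs("ATTTA", [MotifPattern("RTTTR", "are")])

    def test_overlapping_occurrences_match_brute_force(self):
        seq = "AATAATAAA"
        hits = scan_motifs(seq, [MotifPattern("AATAAA", "polyA")])
        assert {(v.start, v.end) for v in hits} == brute_motif_hits(seq, "AATAAA")
        assert [(v.start, v.end) for v in hits] == [(3, 9)]

    def test_both_strands_maps_coordinates(self):
        # TTTATT reverse-complements to AATAAA
        seq = "GGTTTATTGG"
        hits = scan_motifs(
            seq, [MotifPattern("AATAAA", "polyA")], both_strands=True
        )
        assert [(v.start, v.end, v.strand) for v in hits] == [(2, 8, "-")]
        assert hits[0].matched == "TTTATT"

    def test_bad_pattern_rejected(self):
        with pytest.raises(PatternError, match="polyA"):
            MotifPattern("AAZAAA", "polyA")
        with pytest.raises(PatternError):
            MotifPattern("ACG", "too-short")


class TestAtRuns:
    def test_mixed_run_by_hand(self):
        hits = find_at_runs("GGATATATAGG", 6)
        assert [(v.start, v.end, v.matched) for v in hits] == [(2, 9, "ATATATA")]

    def test_gc_only_sequence_clean(self):
        assert find_at_runs("GCGCGC", 6) == []

    def test_whole_sequence_run(self):
        hits = find_at_runs("AAAAAA", 6)
        assert [(v.start, v.end) for v in hits] == [(0, 6)]

    def test_random_sequences_match_oracle(self, rng):
        for _ in range(30):
            seq = _random_seq(rng, int(rng.integers(10, 300)))
            impl = {(v.start, v.end) for v in find_at_runs(seq, 4)}
            assert impl == brute_at_runs(seq, 4)


class TestDirectRepeats:
    def test_planted_ten_mer_pair(self, rng):
        unit = "AAGGTTCCGG"
        middle = "CATCGCATCGACGATCAGCT"
        seq = unit + middle + unit
        hits = find_direct_repeats(seq, 10)
        assert len(hits) == 1
        v = hits[0]
        assert (v.start, v.end) == (0, 10)
        assert v.mate == (30, 40)
        assert v.matched == unit

    def test_short_sequence_empty(self):
        assert find_direct_repeats("ACGTACGTAC", 10) == []

    def test_random_sequences_match_oracle(self, rng):
        for _ in range(40):
            seq = _random_seq(rng, int(rng.integers(20, 300)))
            for min_len in (6, 10):
                impl = {
                    (v.start, v.end, *v.mate)
                    for v in find_direct_repeats(seq, min_len)
                }
                assert impl == brute_direct_repeats(seq, min_len)


class TestInvertedRepeats:
    def test_twelve_bp_stem_with_loop_found(self):
        stem = "ACGTACCGGATC"
        seq = "GG" + stem + "TTTT" + reverse_complement(stem) + "GG"
        hits = find_inverted_repeats(seq, 12)
        assert len(hits) == 1
        v = hits[0]
        assert (v.start, v.end) == (2, 14)
        assert v.mate == (18, 30)

    def test_eleven_bp_arms_below_threshold(self):
        stem = "ACGTACCGGAT"  # 11 bp
        seq = "GG" + stem + "TTTT" + reverse_complement(stem) + "GG"
        assert find_inverted_repeats(seq, 12) == []

    def test_zero_loop_palindrome_is_a_stem(self):
        pal = "ACGTACCGGATC" + reverse_complement("ACGTACCGGATC")
        hits = find_inverted_repeats(pal, 12)
        assert [(v.start, v.end, v.mate) for v in hits] == [(0, 12, (12, 24))]
        pal_hits = find_palindromes(pal, 24)
        assert [(v.start, v.end) for v in pal_hits] == [(0, 24)]

    def test_random_sequences_match_oracle(self, rng):
        for _ in range(40):
            seq = _random_seq(rng, int(rng.integers(20, 300)))
            for min_stem in (4, 6, 12):
                impl = {
                    (v.start, v.end, *v.mate)
                    for v in find_inverted_repeats(seq, min_stem)
                }
                assert impl == brute_inverted_repeats(seq, min_stem)


class TestPalindromes:
    def test_ecori_site(self):
        hits = find_palindromes("GAATTC", 6)
        assert [(v.start, v.end) for v in hits] == [(0, 6)]

    def test_homopolymer_not_palindromic(self):
        assert find_palindromes("AAAAAAAA", 6) == []

    def test_odd_min_len_rejected(self):
        with pytest.raises(InvalidParameterError):
            find_palindromes("ACGT", 7)

    def test_random_sequences_match_oracle(self, rng):
        for _ in range(40):
            seq = _random_seq(rng, int(rng.integers(10, 250)))
            for min_len in (6, 8):
                impl = {(v.start, v.end) for v in find_palindromes(seq, min_len)}
                assert impl == brute_palindromes(seq, min_len)


class TestScreen:
    def test_clean_sequence_empty_report(self):
        # GC-rich, no runs/repeats/motifs; target matched
        seq = "GCCACCGTCGAGGACCTGCGGCAAGTCCGC"
        c = DesignConstraints(gc_target=70.0, gc_window=5.0)
        report = screen(seq, c)
        assert report.clean
        assert report.gc_ok

    def test_planted_motif_and_stem_found(self):
        stem = "ACGTACCGGATC"
        seq = (
            "GCCGCC" + "AATAAA"
            + "CCG" + stem + "TTCC" + reverse_complement(stem) + "GCCGCC"
        )
        c = DesignConstraints(gc_target=60.0, gc_window=40.0, min_at_run=8)
        report = screen(seq, c)
        kinds = sorted(v.kind for v in report.violations)
        assert kinds == ["inverted_repeat", "motif"]

    def test_gc_window_violation_for_low_gc_sequence(self):
        # a 45%-GC sequence against the host average target of 55 +/- 3
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        seq = "".join(
            rng.choice(bases, size=400, p=[0.275, 0.225, 0.225, 0.275])
        )
        c = DesignConstraints(gc_target=55.0, gc_window=3.0)
        report = screen(seq, c)
        assert not report.gc_ok
        assert any(v.kind == "gc_window" for v in report.violations)

    def test_violations_stay_in_bounds_and_match_slices(self, rng):
        c = DesignConstraints(gc_target=50.0, gc_window=50.0)
        for _ in range(20):
            seq = _random_seq(rng, int(rng.integers(30, 300)))
            report = screen(seq, c)
            for v in report.violations:
                assert 0 <= v.start < v.end <= len(seq)
                assert v.matched == seq[v.start : v.end]
                if v.mate is not None:
                    s, e = v.mate
                    assert 0 <= s < e <= len(seq)

    def test_palindromes_are_inverted_repeats_with_zero_loop(self, rng):
        for _ in range(20):
            seq = _random_seq(rng, 200)
            stem_spans = {
                (v.start, v.mate[1]) for v in find_inverted_repeats(seq, 4)
            }
            for v in find_palindromes(seq, 8):
                assert (v.start, v.end) in stem_spans

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(20):
            seq = _random_seq(rng, 250)
            rc = reverse_complement(seq)
            assert len(find_palindromes(seq, 6)) == len(find_palindromes(rc, 6))
            assert len(find_inverted_repeats(seq, 5)) == len(
                find_inverted_repeats(rc, 5)
            )
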