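"""Global alignment, identity, indel-element delineation, TSS mapping."""

import itertools

import numpy as np
import pytest

from atpromoter import (
    PairwiseAlignment,
    PromoterPairSpec,
    ScoringScheme,
    SequenceRecord,
    detect_indel_elements,
    global_align,
    make_promoter_pair,
    map_tss,
    percent_identity,
)


def brute_force_best_score(a: str, b: str, s: ScoringScheme) -> float:
    """Exhaustive enumeration of all global alignments (affine gap runs).

    Recursion over (i, j, last_move) accumulating the score of every
    monotone alignment path; independent of the DP implementation.
    """

    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -float("inf")
        if i < len(a) and j < len(b):
            sc = s.match if a[i] == b[j] else s.mismatch
            best = max(best, sc + rec(i + 1, j + 1, "D"))
        if i < len(a):
            gap = s.gap_extend if last == "U" else s.gap_open
            best = max(best, gap + rec(i + 1, j, "U"))
        if j < len(b):
            gap = s.gap_extend if last == "L" else s.gap_open
            best = max(best, gap + rec(i, j + 1, "L"))
        return best

    return rec(0, 0, "D")


def alignment_score(aln: PairwiseAlignment, s: ScoringScheme) -> float:
    """Score an alignment string pair independently, run-aware."""
    total = 0.0
    prev = None
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-" or y == "-":
            kind = "ga" if x == "-" else "gb"
            total += s.gap_extend if prev == kind else s.gap_open
            prev = kind
        else:
            total += s.match if x == y else s.mismatch
            prev = "m"
    return total


class TestGlobalAlign:
    def test_identity_alignment(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.aligned_a == "ACGT" and aln.aligned_b == "ACGT"
        assert aln.score == pytest.approx(4 * ScoringScheme().match)

    def test_forced_indel(self):
        aln = global_align("AAAA", "AA")
        assert aln.aligned_a == "AAAA"
        assert aln.aligned_b.count("-") == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_degapping_recovers_inputs(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), size=80))
        b = "".join(rng.choice(list("ACGT"), size=95))
        aln = global_align(a, b)
        assert aln.degapped_a() == a
        assert aln.degapped_b() == b

    @pytest.mark.parametrize("seed", range(12))
    def test_dp_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 8)), int(rng.integers(1, 8))
        a = "".join(rng.choice(list("ACGT"), size=n))
        b = "".join(rng.choice(list("ACGT"), size=m))
        scoring = ScoringScheme()
        aln = global_align(a, b, scoring)
        assert aln.score == pytest.approx(brute_force_best_score(a, b, scoring))
        assert alignment_score(aln, scoring) == pytest.approx(aln.score)

    def test_dp_matches_enumeration_under_cheap_gaps(self):
        # gap runs cheaper than mismatches: optimum uses adjacent indels
        scoring = ScoringScheme(match=2, mismatch=-20, gap_open=-4, gap_extend=-1)
        rng = np.random.default_rng(99)
        for _ in range(6):
            a = "".join(rng.choice(list("ACGT"), size=6))
            b = "".join(rng.choice(list("ACGT"), size=6))
            aln = global_align(a, b, scoring)
            assert aln.score == pytest.approx(
                brute_force_best_score(a, b, scoring)
            )

    def test_planted_insertion_yields_single_gap_block(self):
        rng = np.random.default_rng(17)
        flank = "".join(rng.choice(list("ACGT"), size=300))
        insert = "".join(rng.choice(list("ACGT"), size=50))
        host = flank[:150] + insert + flank[150:]
        aln = global_align(flank, host)
        runs = [len(list(g)) for ch, g in itertools.groupby(aln.aligned_a) if ch == "-"]
        assert runs == [50]


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity(global_align("ACGT", "ACGT")) == 100.0

    def test_half(self):
        aln = PairwiseAlignment("a", "b", "AC", "AG", 0.0)
        assert percent_identity(aln) == 50.0

    def test_region_and_errors(self):
        aln = PairwiseAlignment("a", "b", "ACGT", "ACTT", 0.0)
        assert percent_identity(aln, region=(0, 2)) == 100.0
        with pytest.raises(ValueError):
            percent_identity(aln, region=(2, 2))

    def test_matches_naive_column_tally(self):
        rng = np.random.default_rng(8)
        a = "".join(rng.choice(list("ACGT"), size=100))
        b = "".join(rng.choice(list("ACGT"), size=100))
        aln = global_align(a, b)
        tally = sum(
            x == y and x != "-" for x, y in zip(aln.aligned_a, aln.aligned_b)
        )
        assert percent_identity(aln) == pytest.approx(100 * tally / len(aln))


class TestDetectIndelElements:
    def test_gapless_alignment_yields_nothing(self):
        aln = global_align("ACGTACGTAC", "ACGTACGTAC")
        assert detect_indel_elements(aln) == []

    def test_merge_rule_spans_interleaved_matches(self):
        # two 30-bp gap runs separated by 5 matched columns, merge_gap=10:
        # summed gap length 60 passes min_len=50; the host interval spans
        # the merged region (65 host bases)
        mid = "ATGCA"
        ins1 = "TTGAC" * 6
        ins2 = "GCTAG" * 6
        short = "ACGTACGTACGTACGTACGT" + mid + "TGCATGCATGCATGCATGCA"
        host = (
            "ACGTACGTACGTACGTACGT" + ins1 + mid + ins2 + "TGCATGCATGCATGCATGCA"
        )
        aligned_a = (
            "ACGTACGTACGTACGTACGT" + "-" * 30 + mid + "-" * 30 + "TGCATGCATGCATGCATGCA"
        )
        aln = PairwiseAlignment("short", "host", aligned_a, host, 0.0)
        (el,) = detect_indel_elements(aln, min_len=50, merge_gap=10)
        assert el.host_id == "host"
        assert el.length == 65
        assert host[el.interval.start : el.interval.end] == ins1 + mid + ins2

    def test_short_runs_below_min_len_dropped(self):
        aligned_a = "ACGT" + "-" * 10 + "ACGT"
        aligned_b = "ACGT" + "TTTTTTTTTT" + "ACGT"
        aln = PairwiseAlignment("a", "b", aligned_a, aligned_b, 0.0)
        assert detect_indel_elements(aln, min_len=50) == []

    def test_recovers_planted_elements_exactly(self, promoter_pair):
        a, b, manifest = promoter_pair
        aln = global_align(a, b)
        els = detect_indel_elements(
            aln, tss_a=manifest["tss_a"], tss_b=manifest["tss_b"]
        )
        assert [el.label for el in els] == ["ATRS2", "ATRS1"]  # position order
        by_label = {el.label: el for el in els}
        truth1, truth2 = manifest["atrs1"], manifest["atrs2"]
        assert (by_label["ATRS1"].interval.start, by_label["ATRS1"].interval.end) == (
            truth1["start"],
            truth1["end"],
        )
        assert (by_label["ATRS2"].interval.start, by_label["ATRS2"].interval.end) == (
            truth2["start"],
            truth2["end"],
        )
        assert by_label["ATRS1"].length == 495
        assert by_label["ATRS2"].length == 98
        assert by_label["ATRS1"].at_fraction == pytest.approx(
            truth1["at_fraction"]
        )

    def test_labelling_proximal_first(self, promoter_pair):
        a, b, manifest = promoter_pair
        aln = global_align(a, b)
        els = detect_indel_elements(
            aln, tss_a=manifest["tss_a"], tss_b=manifest["tss_b"]
        )
        by_label = {el.label: el for el in els}
        # ATRS1 sits between HSE2 and HSE3: closer to the TSS than ATRS2
        assert abs(by_label["ATRS1"].tss_relative_start) < abs(
            by_label["ATRS2"].tss_relative_start
        )

    def test_symmetry_under_argument_swap(self, promoter_pair):
        a, b, manifest = promoter_pair
        els_ab = detect_indel_elements(global_align(a, b))
        els_ba = detect_indel_elements(global_align(b, a))
        ivs_ab = {(e.host_id, e.interval.start, e.interval.end) for e in els_ab}
        ivs_ba = {(e.host_id, e.interval.start, e.interval.end) for e in els_ba}
        assert ivs_ab == ivs_ba


class TestMapTss:
    def test_exact_substring(self):
        rng = np.random.default_rng(21)
        g = "".join(rng.choice(list("ACGT"), size=1000))
        cdna = SequenceRecord("c", g[200:800])
        assert map_tss(cdna, SequenceRecord("g", g)) == 200

    def test_tolerates_two_mismatches_in_anchor(self):
        rng = np.random.default_rng(22)
        g = "".join(rng.choice(list("ACGT"), size=1000))
        anchor = list(g[200:800])
        for pos in (10, 30):
            anchor[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[anchor[pos]]
        cdna = SequenceRecord("c", "".join(anchor))
        assert map_tss(cdna, SequenceRecord("g", g)) == 200

    def test_scrambled_cdna_has_no_anchor(self):
        rng = np.random.default_rng(23)
        g = "".join(rng.choice(list("ACGT"), size=400))
        scrambled = "".join(rng.permutation(list(g[100:300])))
        with pytest.raises(ValueError, match="anchor"):
            map_tss(SequenceRecord("c", scrambled), SequenceRecord("g", g))
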