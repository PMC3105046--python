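"""Matched-control selection: each stage and the end-to-end screen."""

import math

import numpy as np
import pytest

from atpromoter import (
    ControlCandidate,
    EmptyCandidateSetError,
    GeneAnnotation,
    Interval,
    Motif,
    SelectorConfig,
    SequenceRecord,
    at_fraction,
    default_exclusion_library,
    enumerate_candidates,
    filter_intergenic,
    filter_tfbs_free,
    iupac_match,
    pick_fragment,
    select_control,
    select_control_sequence,
)
from atpromoter.motif_scan import HSE_UNIT
from atpromoter.seqio import reverse_complement


def cfg_for(length, at, **kw):
    return SelectorConfig(target_length=length, target_at=at, **kw)


class TestPickFragment:
    def test_unique_choice_when_fragment_fills_chromosome(self, rng):
        genome = [SequenceRecord("c1", "ACGT" * 2500)]
        cfg = cfg_for(98, 50.0, fragment_length=10_000)
        frag = pick_fragment(genome, cfg, rng)
        assert (frag.chrom, frag.start, frag.end) == ("c1", 0, 10_000)

    def test_no_long_enough_chromosome_rejected(self, rng):
        genome = [SequenceRecord("c1", "ACGT" * 2500)]
        cfg = cfg_for(98, 50.0, fragment_length=5_000_000)
        with pytest.raises(ValueError):
            pick_fragment(genome, cfg, rng)

    def test_equal_chromosomes_drawn_equally(self, rng):
        genome = [
            SequenceRecord("c1", "A" * 3000),
            SequenceRecord("c2", "A" * 3000),
        ]
        cfg = cfg_for(98, 100.0, fragment_length=3000)
        n = 10_000
        c1 = sum(
            pick_fragment(genome, cfg, rng).chrom == "c1" for _ in range(n)
        )
        se = math.sqrt(0.25 / n)
        assert abs(c1 / n - 0.5) < 3 * se


class TestEnumerateCandidates:
    def test_exact_full_length_match(self):
        cfg = cfg_for(98, 100.0, fragment_length=98)
        cands = enumerate_candidates("A" * 98, cfg)
        assert len(cands) == 1
        assert cands[0].at_fraction == 1.0

    def test_no_match_when_composition_off(self):
        cfg = cfg_for(98, 50.0, fragment_length=98)
        assert enumerate_candidates("A" * 98, cfg) == []

    def test_matches_naive_recomputation(self, rng):
        seq = "".join(rng.choice(list("ACGT"), p=[0.33, 0.17, 0.17, 0.33], size=5000))
        cfg = cfg_for(98, 100 * 64 / 98, at_tolerance=0.3, fragment_length=5000)
        got = {c.interval.start for c in enumerate_candidates(seq, cfg)}
        want = {
            s
            for s in range(len(seq) - 98 + 1)
            if abs(100 * at_fraction(seq[s : s + 98]) - cfg.target_at)
            <= cfg.at_tolerance
        }
        assert got == want

    def test_offset_places_intervals_in_chromosome_coordinates(self):
        cfg = cfg_for(10, 100.0, fragment_length=20)
        cands = enumerate_candidates("A" * 20, cfg, chrom="chr9", offset=500)
        assert cands[0].interval.chrom == "chr9"
        assert cands[0].interval.start == 500


class TestFilterIntergenic:
    def make_cand(self, start, length=98):
        return ControlCandidate(
            Interval("chr1", start, start + length), 0.5, "A" * length
        )

    def test_plus_strand_exclusion_zone(self):
        genes = [GeneAnnotation("g", Interval("chr1", 1000, 2000, "+"))]
        cfg = cfg_for(98, 50.0, fragment_length=98)
        # zone is [700, 2200): candidate [650, 748) overlaps
        assert filter_intergenic([self.make_cand(650)], genes, cfg) == []
        # candidate [600, 698) is clear
        assert len(filter_intergenic([self.make_cand(600)], genes, cfg)) == 1
        # right edge: [2200, 2298) is clear, [2150, 2248) is not
        assert len(filter_intergenic([self.make_cand(2200)], genes, cfg)) == 1
        assert filter_intergenic([self.make_cand(2150)], genes, cfg) == []

    def test_minus_strand_mirrors_flanks(self):
        genes = [GeneAnnotation("g", Interval("chr1", 1000, 2000, "-"))]
        cfg = cfg_for(98, 50.0, fragment_length=98)
        # zone is [800, 2300): candidate [650, 748) is kept
        assert len(filter_intergenic([self.make_cand(650)], genes, cfg)) == 1
        assert filter_intergenic([self.make_cand(750)], genes, cfg) == []

    def test_gene_free_fragment_keeps_all(self):
        cfg = cfg_for(98, 50.0, fragment_length=98)
        cands = [self.make_cand(s) for s in range(0, 1000, 100)]
        assert filter_intergenic(cands, [], cfg) == cands

    def test_other_chromosome_not_excluded(self):
        genes = [GeneAnnotation("g", Interval("chr2", 0, 5000, "+"))]
        cfg = cfg_for(98, 50.0, fragment_length=98)
        assert len(filter_intergenic([self.make_cand(100)], genes, cfg)) == 1


class TestFilterTfbsFree:
    def test_empty_library_is_identity(self):
        cands = [ControlCandidate(Interval("c", 0, 4), 0.5, "ACGT")]
        assert filter_tfbs_free(cands, []) == cands

    def test_candidate_with_planted_dimer_removed(self):
        dimer = "TTTCGAGAATATTCTCGAAA"
        seq = "G" * 40 + dimer + "G" * 38
        cands = [
            ControlCandidate(Interval("c", 0, 98), 0.5, seq),
            ControlCandidate(Interval("c", 100, 198), 0.5, "GC" * 49),
        ]
        lib = [Motif("HSE_dimer", HSE_UNIT + HSE_UNIT, both_strands=False)]
        kept = filter_tfbs_free(cands, lib)
        assert len(kept) == 1
        assert kept[0].interval.start == 100

    def test_matches_naive_oracle(self, rng):
        lib = default_exclusion_library()
        cands = []
        for i in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=98))
            cands.append(ControlCandidate(Interval("c", i, i + 98), 0.5, seq))
        kept = {c.interval.start for c in filter_tfbs_free(cands, lib)}

        def naive_clean(seq):
            for m in lib:
                L = len(m.consensus)
                for i in range(len(seq) - L + 1):
                    if iupac_match(seq[i : i + L], m.consensus):
                        return False
                    if m.both_strands and iupac_match(
                        reverse_complement(seq[i : i + L]), m.consensus
                    ):
                        return False
            return True

        want = {c.interval.start for c in cands if naive_clean(c.sequence)}
        assert kept == want


class TestSelectControl:
    def test_singleton(self, rng):
        c = ControlCandidate(Interval("c", 0, 4), 0.5, "ACGT")
        assert select_control([c], rng) is c

    def test_empty_reports_stage_counts(self, rng):
        with pytest.raises(EmptyCandidateSetError) as exc:
            select_control([], rng, stage_counts={"at_matched": 5, "tfbs_free": 0})
        assert exc.value.stage_counts["tfbs_free"] == 0

    def test_uniform_choice(self, rng):
        cands = [
            ControlCandidate(Interval("c", i, i + 4), 0.5, "ACGT") for i in range(3)
        ]
        n = 30_000
        counts = np.zeros(3)
        for _ in range(n):
            counts[select_control(cands, rng).interval.start] += 1
        se = math.sqrt((1 / 3) * (2 / 3) / n)
        assert np.all(np.abs(counts / n - 1 / 3) < 3 * se)


class TestEndToEnd:
    def test_quantisation_infeasible_target_raises_with_counts(self, small_genome):
        records, genes, _ = small_genome
        # no 98-bp window can be within 0.3 pp of exactly 65%: A+T counts
        # sit on a 1/98 grid whose nearest points are 64.29% and 65.31%
        cfg = cfg_for(98, 65.0, fragment_length=200_000)
        with pytest.raises(EmptyCandidateSetError) as exc:
            select_control_sequence(
                records, genes, cfg, default_exclusion_library(), seed=0
            )
        assert exc.value.stage_counts["at_matched"] == 0

    def test_selected_control_meets_all_requirements(self, small_genome):
        records, genes, _ = small_genome
        cfg = cfg_for(98, 100 * 64 / 98, fragment_length=200_000)
        chosen, prov = select_control_sequence(
            records, genes, cfg, default_exclusion_library(), seed=3
        )
        assert chosen.interval.length() == 98
        assert abs(100 * chosen.at_fraction - cfg.target_at) <= cfg.at_tolerance
        assert at_fraction(chosen.sequence) == pytest.approx(chosen.at_fraction)
        for g in genes:
            iv = g.interval
            lo = iv.start - (300 if iv.strand == "+" else 200)
            hi = iv.end + (200 if iv.strand == "+" else 300)
            assert not (
                chosen.interval.start < hi and lo < chosen.interval.end
            )
        assert prov["stage_counts"]["tfbs_free"] >= 1

    def test_determinism_under_seed(self, small_genome):
        records, genes, _ = small_genome
        cfg = cfg_for(495, 100 * 371 / 495, fragment_length=200_000)
        lib = default_exclusion_library()
        a, _ = select_control_sequence(records, genes, cfg, lib, seed=9)
        b, _ = select_control_sequence(records, genes, cfg, lib, seed=9)
        assert a == b
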