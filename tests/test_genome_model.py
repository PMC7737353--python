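"""Karyotype data model: events, conservation, viability, profiles."""

import numpy as np
import pytest

from karyoweave import (
    CellPopulation, Clone, DerivativeChromosome, Karyotype, RearrangementEvent,
    SegmentInterval, apply_event, copy_number_profile, count_chromosomes,
    homologue_dosage_profile, validate_chromosome,
)
from karyoweave.genome import CoordinateError, GenomeMap
from karyoweave.karyotype import normal_chromosome


@pytest.fixture()
def pair_kt(genome):
    members = (
        normal_chromosome("10", genome, "blue", "10.blue.1", "10a"),
        normal_chromosome("10", genome, "green", "10.green.1", "10b"),
        normal_chromosome("11", genome, "blue", "11.blue.1", "11a"),
        normal_chromosome("11", genome, "green", "11.green.1", "11b"),
    )
    return Karyotype("toy", members)


class TestGenomeMap:
    def test_centromere_must_be_interior(self):
        with pytest.raises(CoordinateError):
            GenomeMap(lengths={"1": 100}, centromeres={"1": (50, 200)})

    def test_unknown_chromosome_is_reference_error(self, genome):
        with pytest.raises(CoordinateError):
            genome.length("chr99")

    def test_subtelomere_windows(self, genome):
        assert genome.in_subtelomere("1", 10_000, "p")
        assert genome.in_subtelomere("1", genome.length("1") - 10_000, "q")
        assert not genome.in_subtelomere("1", 1_000_000, "p")


class TestApplyEvent:
    def test_balanced_translocation_conserves_base_content(self, genome, pair_kt):
        # the t(10;11)(p12.31;q14.2) of the fixture, on normal 10 and 11
        ev = RearrangementEvent("balanced-translocation", chrom="10",
                               pos=21_500_000, member="10b", chrom2="11",
                               pos2=86_000_000, member2="11a")
        out = apply_event(pair_kt, ev, genome)
        assert out.total_bp == pair_kt.total_bp
        assert count_chromosomes(out) == count_chromosomes(pair_kt)
        der10 = out.member("der(10b)t(10b;11a)")
        chroms = [s.chrom for s in der10.segments]
        assert set(chroms) == {"10", "11"}

    def test_deletion_removes_exactly_the_interval(self, genome, pair_kt):
        ev = RearrangementEvent("deletion", chrom="10", start=50_000_001,
                               end=60_000_000, member="10a")
        out = apply_event(pair_kt, ev, genome)
        assert pair_kt.total_bp - out.total_bp == 10_000_000

    def test_duplication_and_amplification_add_copies(self, genome, pair_kt):
        dup = RearrangementEvent("tandem-duplication", chrom="10",
                                 start=50_000_001, end=60_000_000, member="10a")
        out = apply_event(pair_kt, dup, genome)
        assert out.total_bp - pair_kt.total_bp == 10_000_000
        amp = RearrangementEvent("amplification", chrom="10", start=50_000_001,
                                 end=52_000_000, member="10a", count=4)
        out = apply_event(pair_kt, amp, genome)
        assert out.member("10a").copies("10", 50_000_001, 52_000_000) == 4

    def test_inverted_duplication_flips_orientation(self, genome, pair_kt):
        ev = RearrangementEvent("inverted-duplication", chrom="10",
                                start=50_000_001, end=60_000_000, member="10a")
        out = apply_event(pair_kt, ev, genome)
        orientations = [s.orientation for s in out.member("10a").segments]
        assert "-" in orientations

    def test_wgd_copies_share_genotype_source(self, genome, pair_kt):
        ev = RearrangementEvent("whole-genome-duplication",
                                complement=("10b", "11b"))
        out = apply_event(pair_kt, ev, genome)
        assert count_chromosomes(out) == 6
        copy = out.member("10b~2")
        orig = out.member("10b")
        assert copy.segments[0].homologue == orig.segments[0].homologue

    def test_wgd_three_copy_region_yields_thirds_bands(self, genome, pair_kt):
        # two-copy + duplicated homologue: het probe bands 1/3 and 2/3, never 1/2
        from karyoweave.arrays import baf_band_set

        out = apply_event(pair_kt, RearrangementEvent(
            "whole-genome-duplication", complement=("10b",)), genome)
        pop = CellPopulation("toy3", (Clone(out, 1.0),))
        dosage = homologue_dosage_profile(pop, "10", 1_000_000, 2_000_000)
        bands = baf_band_set(((int(dosage["blue"]), int(dosage["green"]), 1.0),))
        assert bands == [0.0, pytest.approx(1 / 3), pytest.approx(2 / 3), 1.0]

    def test_breakpoint_outside_chromosome_is_coordinate_error(self, genome, pair_kt):
        with pytest.raises(CoordinateError):
            apply_event(pair_kt, RearrangementEvent(
                "deletion", chrom="10", start=1, end=10**10, member="10a"), genome)

    def test_unknown_member_is_reference_error(self, genome, pair_kt):
        from karyoweave.karyotype import ReferenceError_

        with pytest.raises(ReferenceError_):
            apply_event(pair_kt, RearrangementEvent(
                "deletion", chrom="10", start=1_000_001, end=2_000_000,
                member="nope"), genome)


class TestViability:
    def test_normal_chromosome_viable(self, genome):
        der = normal_chromosome("7", genome, "blue", "7.blue.1")
        rep = validate_chromosome(der, genome)
        assert rep.verdict == "viable"
        assert rep.active_centromeres == 1
        assert rep.p_telomere and rep.q_telomere

    def test_acentric_fragment(self, genome):
        der = DerivativeChromosome(
            "frag", (SegmentInterval("16", 1, 30_000_000, "blue"),))
        assert validate_chromosome(der, genome).verdict == "acentric"

    def test_unterminated_end(self, genome):
        der = DerivativeChromosome(
            "broken", (SegmentInterval("7", 1, 100_000_000, "blue"),))
        assert validate_chromosome(der, genome).verdict == "unterminated"

    def test_assumed_telomere_rescues_broken_end(self, genome):
        der = DerivativeChromosome(
            "capped", (SegmentInterval("7", 1, 100_000_000, "blue"),),
            telomere_assumed=(False, True))
        assert validate_chromosome(der, genome).verdict == "viable"

    def test_reverse_oriented_terminal_segment_telomere(self, genome):
        # q-end outward face of a "-" segment is its genomic start
        der = DerivativeChromosome(
            "der", (SegmentInterval("7", 1, 100_000_000, "blue"),
                    SegmentInterval("6", 1, 10_000_000, "blue", "-")))
        rep = validate_chromosome(der, genome)
        assert rep.q_telomere


class TestProfiles:
    def test_count_chromosomes_empty_and_increment(self, genome, pair_kt):
        assert count_chromosomes(pair_kt) == 4
        bigger = pair_kt.add_member(normal_chromosome("12", genome, "blue",
                                                      "12.blue.1", "12a"))
        assert count_chromosomes(bigger) == 5

    def test_absent_chromosome_profile_is_zero(self, genome, pair_kt):
        pop = CellPopulation("toy", (Clone(pair_kt, 1.0),))
        assert copy_number_profile(pop, "5", 1, 1_000_000) == 0.0

    def test_interval_outside_map_raises(self, genome, pair_kt):
        pop = CellPopulation("toy", (Clone(pair_kt, 1.0),))
        with pytest.raises(CoordinateError):
            copy_number_profile(pop, "10", 1, 10**10, genome)

    def test_partial_overlap_prorated(self, genome):
        der = DerivativeChromosome(
            "half", (SegmentInterval("10", 1, 1_000_000, "blue"),))
        pop = CellPopulation("h", (Clone(Karyotype("k", (der,)), 1.0),))
        assert copy_number_profile(pop, "10", 1, 2_000_000) == pytest.approx(0.5)

    def test_dosage_components_sum_to_total_on_random_intervals(self, genome, pop):
        rng = np.random.default_rng(7)
        chroms = ["5", "6", "11", "20"]
        for _ in range(25):
            chrom = chroms[rng.integers(0, len(chroms))]
            n = genome.length(chrom)
            a = int(rng.integers(1, n - 1))
            b = int(rng.integers(a, n))
            total = copy_number_profile(pop, chrom, a, b)
            parts = homologue_dosage_profile(pop, chrom, a, b)
            assert total == pytest.approx(sum(parts.values()), abs=1e-9)

    def test_clone_fractions_must_sum_to_one(self, genome, pair_kt):
        with pytest.raises(ValueError):
            CellPopulation("bad", (Clone(pair_kt, 0.5), Clone(pair_kt, 0.6)))

    def test_iscn_like_summary_string(self, stemline):
        from karyoweave.karyotype import iscn_like

        text = iscn_like(stemline.member("der(11)t(11;16;20)"))
        assert text.startswith("der(11)t(11;16;20)(16:1->30000000::")
        assert "20:8000000->1" in text  # reverse-oriented terminal 20p segment
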