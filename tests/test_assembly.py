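"""Derivative composition, homologue assignment and capture detection."""

import pytest

from karyoweave import (
    call_segments, classify_rearrangement_homologues, compose_derivatives,
    composition_from_derivative, detect_centromere_capture,
    detect_telomere_capture, solve_homologue_assignment,
)
from karyoweave.assembly import (
    DerivativeComposition, Placement, UNPLACED, evidence_from_fish,
)
from karyoweave.fish import FishProbe, probe_from_dict
from karyoweave.inference import ScoredConfig, SegmentCall
from karyoweave.u937 import U937_FISH_PROBES

PROBES = {d["name"]: d for d in U937_FISH_PROBES}


def _call(chrom, start, end, clones, n_probes=100):
    total = sum(f * (a + b) for a, b, f in clones)
    cfg = ScoredConfig(tuple(clones), 0.0, (0.0, 1.0), 0.0)
    call = SegmentCall(chrom, start, end, n_probes, 0.0, None,
                       [cfg], cfg, False)
    d1, d2 = cfg.mean_dosage
    call.n_major, call.n_minor = max(d1, d2), min(d1, d2)
    assert call.cn_total == pytest.approx(total)
    return call


class TestCompose:
    def _evidence(self, stemline, genome, names):
        probes = [probe_from_dict(PROBES[n]) for n in names] + \
            [FishProbe("D20Z1", "centromere", "20"),
             FishProbe("D11Z1", "centromere", "11")]
        return evidence_from_fish(probes, stemline, genome=genome)

    def test_amplified_20p_material_placed_on_der20_only(self, stemline, genome):
        ev = self._evidence(stemline, genome, ["RP11-500O11"])
        d = PROBES["RP11-500O11"]
        calls = [_call("20", d["start"] - 1000, d["end"] + 1000,
                       [(6, 0, 1.0)])]
        comps, conflicts = compose_derivatives(calls, ev, genome)
        by_name = {c.name: c for c in comps}
        placed = {n: sum(s.copies for s in c.segments)
                  for n, c in by_name.items() if c.segments}
        assert placed["der(20)t(15;20)"] == pytest.approx(4.0)
        assert "der(11)t(11;16;20)" not in placed
        assert not conflicts

    def test_copies_conserved_including_unplaced(self, stemline, genome):
        ev = self._evidence(stemline, genome, ["RP11-702M08"])
        d = PROBES["RP11-702M08"]
        calls = [_call("20", d["start"] - 1000, d["end"] + 1000,
                       [(3, 0, 1.0)])]
        comps, _ = compose_derivatives(calls, ev, genome)
        total = sum(s.copies for c in comps for s in c.segments)
        assert total == pytest.approx(3.0)
        # the retained 20q11.21 copy is split between der(11) and der(20)
        by_name = {c.name: c for c in comps}
        assert by_name["der(11)t(11;16;20)"].segments
        assert by_name["der(20)t(15;20)"].segments

    def test_segment_without_fish_evidence_fully_unplaced(self, stemline, genome):
        ev = self._evidence(stemline, genome, ["RP11-500O11"])
        calls = [_call("20", 60_000_000, 62_000_000, [(2, 0, 1.0)])]
        comps, _ = compose_derivatives(calls, ev, genome)
        unplaced = next(c for c in comps if c.name == UNPLACED)
        assert sum(s.copies for s in unplaced.segments) == pytest.approx(2.0)

    def test_excess_fish_copies_produce_conflict_report(self, stemline, genome):
        ev = self._evidence(stemline, genome, ["RP11-500O11"])
        d = PROBES["RP11-500O11"]
        calls = [_call("20", d["start"] - 1000, d["end"] + 1000,
                       [(2, 0, 1.0)])]  # array says 2, FISH accounts for 6
        comps, conflicts = compose_derivatives(calls, ev, genome)
        assert len(conflicts) == 1
        total = sum(s.copies for c in comps for s in c.segments)
        assert total == pytest.approx(2.0)  # conserved despite the conflict


class TestCaptureDetectors:
    def test_fixture_flags_exactly_der11_and_der7(self, pop, genome):
        seen = {}
        for clone in pop.clones:
            for m in clone.karyotype.members:
                seen.setdefault(m.name, m)
        captures = []
        for m in seen.values():
            comp = composition_from_derivative(m, genome)
            captures += detect_centromere_capture(comp, genome)
            captures += detect_telomere_capture(comp, genome)
        assert {(c.derivative, c.kind) for c in captures} == {
            ("der(11)t(11;16;20)", "centromere"),
            ("der(7)t(6;7)", "telomere"),
        }

    def test_der11_donor_is_six_megabases_of_chr11(self, stemline, genome):
        comp = composition_from_derivative(
            stemline.member("der(11)t(11;16;20)"), genome)
        calls = detect_centromere_capture(comp, genome)
        assert len(calls) == 1
        assert calls[0].donor == "11"
        assert calls[0].donor_length == 6_000_000

    def test_simple_reciprocal_translocation_not_flagged(self, stemline, genome):
        comp = composition_from_derivative(
            stemline.member("der(11)t(10;11)"), genome)
        assert detect_centromere_capture(comp, genome) == []
        assert detect_telomere_capture(comp, genome) == []

    def test_majority_donor_never_flagged(self, genome):
        comp = DerivativeComposition("toy", [
            Placement("toy", "19", 1, 58_000_000, 1.0),
            Placement("toy", "21", 1, 5_000_000, 1.0),
        ], centromeres={"19": 1})
        assert detect_centromere_capture(comp, genome) == []

    def test_constructed_shattered_rescue_flagged(self, genome):
        # five acentric chr19 fragments rescued by a small chr21 centromeric piece
        frags = [Placement("mar", "19", a, a + 4_000_000, 1.0)
                 for a in range(1_000_000, 21_000_001, 5_000_000)]
        donor = Placement("mar", "21", 9_500_000, 14_000_000, 1.0)
        comp = DerivativeComposition("mar", frags + [donor],
                                     centromeres={"21": 1})
        calls = detect_centromere_capture(comp, genome)
        assert len(calls) == 1 and calls[0].donor == "21"

    def test_empty_composition_is_an_error(self, genome):
        with pytest.raises(ValueError):
            detect_centromere_capture(
                DerivativeComposition("x", [], {"1": 1}), genome)

    def test_native_ends_no_telomere_call(self, stemline, genome):
        comp = composition_from_derivative(stemline.member("9"), genome)
        assert detect_telomere_capture(comp, genome) == []


class TestHomologueAssignment:
    def _chr16_setup(self, genome):
        placements = [
            Placement("16", "16", 1, genome.length("16"), 1.0),
            Placement("der(16)t(4;16)", "16", 22_000_001, genome.length("16"), 1.0),
            Placement("der(11)t(11;16;20)", "16", 1, 30_000_000, 1.0),
        ]
        calls = [
            _call("16", 1, 22_000_000, [(1, 1, 1.0)]),
            _call("16", 22_000_001, 30_000_000, [(2, 1, 1.0)]),
            _call("16", 30_000_001, 36_000_000, [(2, 0, 1.0)]),
            _call("16", 38_500_000, genome.length("16"), [(2, 0, 1.0)]),
        ]
        return placements, calls

    def test_chr16_derivatives_on_different_homologues(self, genome):
        placements, calls = self._chr16_setup(genome)
        result = solve_homologue_assignment("16", calls, placements)
        assert result.unique
        verdict = classify_rearrangement_homologues(
            "der(16)t(4;16)", "der(11)t(11;16;20)", "16", calls, placements)
        assert verdict == "different"

    def test_self_comparison_is_same(self, genome):
        placements, calls = self._chr16_setup(genome)
        assert classify_rearrangement_homologues(
            "der(16)t(4;16)", "der(16)t(4;16)", "16", calls, placements) == "same"

    def test_balanced_dosage_is_ambiguous(self, genome):
        # three interchangeable placements in a (2, 1) region: which one
        # carries the minor homologue is unidentifiable
        placements = [
            Placement("A", "16", 1, 40_000_000, 1.0),
            Placement("B", "16", 1, 40_000_000, 1.0),
            Placement("C", "16", 1, 40_000_000, 1.0),
        ]
        calls = [_call("16", 1, 40_000_000, [(2, 1, 1.0)])]
        result = solve_homologue_assignment("16", calls, placements)
        assert not result.unique
        assert classify_rearrangement_homologues(
            "A", "B", "16", calls, placements) == "ambiguous"

    def test_no_consistent_assignment_reports_violations(self, genome):
        placements = [Placement("A", "16", 1, 40_000_000, 1.0)]
        calls = [_call("16", 1, 40_000_000, [(3, 2, 1.0)])]
        result = solve_homologue_assignment("16", calls, placements)
        assert not result.consistent
        assert result.violated

    def test_absent_chromosome_is_an_error(self, genome):
        placements, calls = self._chr16_setup(genome)
        with pytest.raises(ValueError):
            classify_rearrangement_homologues(
                "16", "der(16)t(4;16)", "7", calls, placements)

    def test_random_two_derivative_truth_recovered(self, genome):
        """When the two derivatives carry different homologue dosages the
        assignment must match the simulated truth (seeded draws)."""
        import numpy as np

        rng = np.random.default_rng(9)
        n_checked = 0
        for _ in range(100):
            same = bool(rng.integers(0, 2))
            # normal pair plus two derivatives carrying partial 16p copies
            b1 = int(rng.integers(10_000_000, 20_000_000))
            b2 = int(rng.integers(22_000_000, 34_000_000))
            placements = [
                Placement("16a", "16", 1, genome.length("16"), 1.0),
                Placement("16b", "16", 1, genome.length("16"), 1.0),
                Placement("derA", "16", 1, b1, 1.0),
                Placement("derB", "16", 1, b2, 1.0),
            ]
            # truth: 16a=h1, 16b=h2, derA=h1, derB=h1 (same) or h2 (different)
            hb = "h1" if same else "h2"
            regions = [(1, b1), (b1 + 1, b2), (b2 + 1, 36_000_000)]
            calls = []
            for a, b in regions:
                h1 = 1 + (1 if b <= b1 else 0) + \
                    (1 if (hb == "h1" and b <= b2) else 0)
                h2 = 1 + (1 if (hb == "h2" and b <= b2) else 0)
                calls.append(_call("16", a, b, [(h1, h2, 1.0)]))
            verdict = classify_rearrangement_homologues(
                "derA", "derB", "16", calls, placements)
            n_checked += 1
            assert verdict == ("same" if same else "different")
        assert n_checked == 100
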