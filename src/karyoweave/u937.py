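"""Encoded U937 cell-line fixture: three clones, homologue-tagged derivatives,
cross-cutting 5q11.2 mosaic deletions, and the targeted FISH probe panel.

U937 is a widely used myeloid (monocytic) cell line with a near-triploid
karyotype: a whole-genome duplication of one haploid complement
("triploidisation") followed by many structural rearrangements, three major
clones, loss of the myeloid 20q12 common deleted region, a centromere-capture
derivative der(11)t(11;16;20) stabilised by a ~6 Mb chromosome-11
pericentromeric segment, and a telomere-capture der(7)t(6;7) capped by a 6q
subtelomeric segment.

Coordinates are GRCh38, 1-based inclusive.  Published breakpoint coordinates
(FISH clone positions, the 11q24 boundary intervals) are encoded exactly;
band-level breakpoints are encoded at round numbers inside the stated band.
Homologue labels are ``"blue"`` and ``"green"`` following the two-colour
convention of cytogenomic homologue tracking; for most chromosomes the green
homologue is the one duplicated at triploidisation.
"""

from __future__ import annotations

from .genome import GenomeMap, grch38_map
from .karyotype import (
    CellPopulation, Clone, DerivativeChromosome, Karyotype, SegmentInterval,
    SubMosaic, normal_chromosome,
)

# --- key fixture coordinates (bp, GRCh38) ----------------------------------

#: der(11)t(11;16;20) pericentromeric chromosome-11 donor segment: 6.0 Mb
#: spanning the 11 centromere.
CHR11_CAPTURE_SEGMENT = (49_500_000, 55_500_000 - 1)

#: Printed boundary-uncertainty coordinates of the 11q24.2->11q24.3 segment on
#: the der(11)t(11;16;20): proximal boundary lies between the first pair,
#: distal boundary between the second pair.
CHR11_Q24_PROXIMAL_BOUNDS = (127_168_221, 127_348_488)
CHR11_Q24_DISTAL_BOUNDS = (129_066_363, 129_199_648)

#: 5q11.2 deletions from the der(5)t(5;13): the smaller deletion (base
#: structure, in cells without the larger one) and the larger overlapping
#: deletion (cross-cutting sub-mosaic).
CHR5_DEL_SMALL = (51_200_000, 56_000_000)
CHR5_DEL_LARGE = (50_500_000, 57_500_000)
#: Nominal fraction of cells carrying the larger deletion (one third of cells;
#: the region between the two deletions' proximal edges is then present in
#: two thirds of cells).
CHR5_LARGE_DEL_FRACTION = 1.0 / 3.0
#: Array-visible region present in cells without the larger deletion only.
REGION_5Q_MOSAIC_A = ("5", 50_500_000, 51_199_999)
REGION_5Q_MOSAIC_B = ("5", 56_000_001, 57_500_000)

#: Chromosome 6 copy-number segment boundaries (the six-state profile).
CHR6_BREAKS = (25_000_000, 30_000_000, 33_000_000, 48_000_000, 160_600_000)
REGION_6_AMPLICON = ("6", 30_000_000, 32_999_999)
REGION_6P22_6P21 = ("6", 25_000_001, 29_999_999)
REGION_6_MID_Q = ("6", 48_000_001, 160_599_999)
#: Copies of the 6p21.3 amplicon carried by the der(6)del(6)dup(6).
CHR6_AMPLICON_COPIES = 10

#: 20q12 common deleted region (contains the D20S108 locus).
REGION_20Q12_CDR = ("20", 41_000_000, 43_000_000)
#: 20p11.21 region of probe RP11-500O11 (4 copies on the der(20)t(15;20)).
REGION_RP11_500O11 = ("20", 22_409_751, 22_462_800)

_CHR20_BLOCK3 = (21_400_000, 33_400_000)          # 20p11.22->20q11.21, spans centromere
_CHR20_EXTRA1 = (22_300_000, 23_700_000)          # short-arm duplication block
_CHR20_EXTRA2 = (22_350_000, 23_000_000)          # inverted repeat of the amplified region
_CHR20_EXTRA3 = (22_380_000, 22_600_000)
_CHR20_DER11_Q_SEG = (31_590_000, 32_000_000)     # 20q11.21 piece on the der(11)
_CHR20_DER11_P_SEG = (1, 8_000_000)               # 20p12.3->20pter on the der(11)

_DER7_T67_BP7 = 87_000_000                        # 7q21.12
_DER7_T67_SEG6 = (160_600_000, 170_805_979)       # 6q26->6qter capping segment


def _seg(chrom: str, start: int, end: int, hom: str, founder: str,
         ori: str = "+") -> SegmentInterval:
    return SegmentInterval(chrom, start, end, hom, ori, founder)


def _normal(chrom: str, hom: str, copy: int, name: str,
            genome: GenomeMap) -> DerivativeChromosome:
    return DerivativeChromosome(
        name, (_seg(chrom, 1, genome.length(chrom), hom, f"{chrom}.{hom}.{copy}"),))


# ---------------------------------------------------------------------------
# derivative builders (stemline members)
# ---------------------------------------------------------------------------

def _members_stemline(g: GenomeMap) -> list[DerivativeChromosome]:
    L = g.length
    m: list[DerivativeChromosome] = []

    # X duplicated (male-derived line, Y lost): genotype-identical copies.
    m.append(_normal("X", "blue", 1, "X", g))
    m.append(_normal("X", "blue", 2, "X~2", g))

    # chromosome 1: normal, terminal del(1)(q12), der(1)t(1;5), (1p also in psu dic)
    m.append(_normal("1", "green", 1, "1", g))
    m.append(DerivativeChromosome(
        "del(1)(q12)", (_seg("1", 1, 127_000_000, "blue", "1.blue.1"),),
        telomere_assumed=(False, True)))
    m.append(DerivativeChromosome(
        "der(1)t(1;5)",
        (_seg("5", 136_000_000, L("5"), "blue", "5.blue.2", "-"),
         _seg("1", 88_000_001, L("1"), "green", "1.green.2"))))

    # chromosome 2
    m.append(_normal("2", "blue", 1, "2", g))
    m.append(DerivativeChromosome(
        "del(2)(p11.2)", (_seg("2", 84_000_000, L("2"), "green", "2.green.1"),),
        telomere_assumed=(True, False)))
    m.append(DerivativeChromosome(
        "der(2)dup(2)del(2)",
        (_seg("2", 1, 200_000_000, "green", "2.green.2"),
         _seg("2", 160_000_000, 200_000_000, "green", "2.green.2")),
        telomere_assumed=(False, True)))

    # chromosome 3 (+ psu dic(3;1) with an inactive 1 centromere)
    m.append(_normal("3", "blue", 1, "3", g))
    m.append(DerivativeChromosome(
        "del(3)(q13.33q24)",
        (_seg("3", 1, 114_000_000, "green", "3.green.1"),
         _seg("3", 147_000_001, L("3"), "green", "3.green.1"))))
    m.append(DerivativeChromosome(
        "psu dic(3;1)",
        (_seg("3", 1, 155_000_000, "green", "3.green.2"),
         _seg("1", 1, 123_000_000, "green", "1.green.3", "-")),
        inactive_centromeres=frozenset({1})))

    # chromosome 4 (4p material also in der(16)t(4;16))
    m.append(_normal("4", "blue", 1, "4", g))
    m.append(_normal("4", "green", 1, "4~2", g))

    # chromosome 5: the der(5)t(5;13) carries the smaller 5q11.2 deletion in its
    # base structure; the larger overlapping deletion is a cross-cutting
    # sub-mosaic (see u937_fixture).
    m.append(_normal("5", "blue", 1, "5", g))
    m.append(DerivativeChromosome(
        "der(5)t(1;5)",
        (_seg("5", 1, 128_000_000, "blue", "5.blue.2"),
         _seg("1", 1, 88_000_000, "green", "1.green.2", "-"))))
    m.append(_der5_t513_small(g))

    # chromosome 6: two normals plus der(6)t(2;6); the der(6)del(6)dup(6) is a
    # clone-2 member only.
    m.append(_normal("6", "blue", 1, "6", g))
    m.append(_normal("6", "green", 1, "6~2", g))
    m.append(DerivativeChromosome(
        "der(6)t(2;6)",
        (_seg("2", 1, 72_000_000, "blue", "2.blue.2"),
         _seg("6", CHR6_BREAKS[0], L("6"), "blue", "6.blue.2"))))

    # chromosome 7: four copies, one carrying a 7p15 duplication.
    m.append(_normal("7", "blue", 1, "7", g))
    m.append(_normal("7", "blue", 2, "7~2", g))
    m.append(_normal("7", "green", 1, "7~3", g))
    m.append(DerivativeChromosome(
        "dup(7)",
        (_seg("7", 1, 29_000_000, "green", "7.green.2"),
         _seg("7", 24_000_000, 29_000_000, "green", "7.green.2"),
         _seg("7", 29_000_001, L("7"), "green", "7.green.2"))))

    # chromosome 8: trisomy plus a subtelomeric 8p duplication on one copy.
    m.append(_normal("8", "blue", 1, "8", g))
    m.append(_normal("8", "green", 1, "8~2", g))
    m.append(DerivativeChromosome(
        "dup(8p)",
        (_seg("8", 1, 800_000, "green", "8.green.2"),
         _seg("8", 1, L("8"), "green", "8.green.2"))))

    # chromosome 9
    m.append(_normal("9", "blue", 1, "9", g))
    m.append(_normal("9", "green", 1, "9~2", g))

    # chromosomes 10/11: the balanced t(10;11) pair plus the duplicated/converted
    # der(10) and the centromere-capture der(11)t(11;16;20).
    m.append(_normal("10", "blue", 1, "10", g))
    m.append(DerivativeChromosome(
        "der(10)t(10;11)",
        (_seg("11", 86_000_001, L("11"), "blue", "11.blue.1", "-"),
         _seg("10", 21_500_001, 101_000_000, "green", "10.green.1"),
         _seg("10", 101_000_001, 113_000_000, "green", "10.green.1"),
         _seg("10", 101_000_001, 113_000_000, "blue", "10.blue.2"),
         _seg("10", 113_000_001, L("10"), "blue", "10.blue.2"))))
    m.append(_normal("11", "green", 1, "11", g))
    m.append(DerivativeChromosome(
        "der(11)t(10;11)",
        (_seg("11", 1, 86_000_000, "blue", "11.blue.1"),
         _seg("10", 1, 21_500_000, "green", "10.green.1", "-"))))
    m.append(_der11_t11_16_20(g))

    # trisomies 12, 15, 18, 19, 21, 22 (12 and 22 mosaic: lost in clone 3)
    for chrom in ("12", "15", "18", "19", "21", "22"):
        m.append(_normal(chrom, "blue", 1, chrom, g))
        m.append(_normal(chrom, "green", 1, f"{chrom}~2", g))
        m.append(_normal(chrom, "green", 2, f"{chrom}~3", g))

    # chromosome 13: two copies; the green homologue carries a submicroscopic
    # 13q21.31 deletion shared with the der(5)t(5;13) 13 segment (the only
    # abnormal chromosome duplicated at triploidisation).
    m.append(_normal("13", "blue", 1, "13", g))
    m.append(DerivativeChromosome(
        "13~2",
        (_seg("13", 1, 63_999_999, "green", "13.green.1"),
         _seg("13", 64_600_001, L("13"), "green", "13.green.1"))))

    # chromosome 14
    m.append(_normal("14", "blue", 1, "14", g))
    m.append(_normal("14", "green", 1, "14~2", g))

    # chromosome 16: normal plus der(16)t(4;16) (duplicated green homologue);
    # the blue 16p lives on the der(11)t(11;16;20).
    m.append(_normal("16", "green", 1, "16", g))
    m.append(DerivativeChromosome(
        "der(16)t(4;16)",
        (_seg("4", 1, 8_800_000, "green", "4.green.2"),
         _seg("4", 10_500_000, 15_800_000, "green", "4.green.2"),
         _seg("4", 16_400_000, 36_800_000, "green", "4.green.2"),
         _seg("4", 37_400_000, 42_000_000, "green", "4.green.2"),
         _seg("16", 22_000_001, L("16"), "green", "16.green.2"))))

    # chromosome 17: two copies; 17p LOH (gene conversion) and a cryptic 17q25
    # deletion on the blue copy.
    m.append(_normal("17", "green", 1, "17", g))
    m.append(DerivativeChromosome(
        "17~2",
        (_seg("17", 1, 22_000_000, "green", "17.green.2"),
         _seg("17", 22_000_001, 80_000_000, "blue", "17.blue.1"),
         _seg("17", 81_500_001, L("17"), "blue", "17.blue.1"))))

    # chromosome 20: two normal copies of ONE homologue plus the complex
    # der(20)t(15;20); the 20q12 CDR is carried by the normal copies only.
    m.append(_normal("20", "green", 1, "20", g))
    m.append(_normal("20", "green", 2, "20~2", g))
    m.append(_der20_t15_20(g))

    return m


def _der5_t513_small(g: GenomeMap) -> DerivativeChromosome:
    """der(5)t(5;13) with the smaller 5q11.2 deletion (base structure)."""
    return _der5_t513(g, CHR5_DEL_SMALL)


def _der5_t513_large(g: GenomeMap) -> DerivativeChromosome:
    """Variant carrying the larger overlapping 5q11.2 deletion."""
    return _der5_t513(g, CHR5_DEL_LARGE)


def _der5_t513(g: GenomeMap, del5: tuple[int, int]) -> DerivativeChromosome:
    segs = (
        _seg("5", 1, del5[0] - 1, "green", "5.green.1"),
        _seg("5", del5[1] + 1, 58_900_000, "green", "5.green.1"),
        _seg("13", 45_200_000, 63_999_999, "green", "13.green.2"),
        _seg("13", 64_600_001, g.length("13"), "green", "13.green.2"),
    )
    return DerivativeChromosome("der(5)t(5;13)", segs)


def _der11_t11_16_20(g: GenomeMap) -> DerivativeChromosome:
    """16pter->16p11.2 :: 11 pericentromere :: 11q24 :: 20q11.21 :: 20p12.3->20pter."""
    return DerivativeChromosome(
        "der(11)t(11;16;20)",
        (_seg("16", 1, 30_000_000, "blue", "16.blue.1"),
         _seg("11", CHR11_CAPTURE_SEGMENT[0], CHR11_CAPTURE_SEGMENT[1],
              "green", "11.green.2"),
         _seg("11", CHR11_Q24_PROXIMAL_BOUNDS[1], CHR11_Q24_DISTAL_BOUNDS[0],
              "green", "11.green.2"),
         _seg("20", _CHR20_DER11_Q_SEG[0], _CHR20_DER11_Q_SEG[1], "blue", "20.blue.1"),
         _seg("20", _CHR20_DER11_P_SEG[0], _CHR20_DER11_P_SEG[1], "blue", "20.blue.1",
              "-")))


def _der20_t15_20(g: GenomeMap) -> DerivativeChromosome:
    """20pter->20p12.2 :: 15q14->15q25.3 (with internal dups) ::
    20p11.22->20q11.21 :: amplified 20p11.21 blocks (broken end)."""
    segs = (
        _seg("20", 1, 10_000_000, "blue", "20.blue.1"),
        _seg("15", 37_200_000, 50_499_999, "blue", "15.blue.2"),
        _seg("15", 50_500_000, 59_000_000, "blue", "15.blue.2"),
        _seg("15", 50_500_000, 59_000_000, "blue", "15.blue.2"),
        _seg("15", 59_000_001, 80_399_999, "blue", "15.blue.2"),
        _seg("15", 80_400_000, 81_600_000, "blue", "15.blue.2"),
        _seg("15", 80_400_000, 81_600_000, "blue", "15.blue.2"),
        _seg("15", 81_600_001, 82_800_000, "blue", "15.blue.2"),
        _seg("20", _CHR20_BLOCK3[0], _CHR20_BLOCK3[1], "blue", "20.blue.1"),
        _seg("20", _CHR20_EXTRA1[0], _CHR20_EXTRA1[1], "blue", "20.blue.1"),
        _seg("20", _CHR20_EXTRA2[0], _CHR20_EXTRA2[1], "blue", "20.blue.1", "-"),
        _seg("20", _CHR20_EXTRA3[0], _CHR20_EXTRA3[1], "blue", "20.blue.1"),
    )
    return DerivativeChromosome("der(20)t(15;20)", segs,
                                telomere_assumed=(False, True))


def _der6_del_dup(g: GenomeMap) -> DerivativeChromosome:
    """der(6)del(6)amp(6)dup(6): 6p terminal deletion, ten-copy 6p21.3
    amplicon, duplicated 6p21.3->6p12.3, then 6p12.3->6qter (clone 2 only)."""
    b1, b2, b3 = CHR6_BREAKS[1], CHR6_BREAKS[2], CHR6_BREAKS[3]
    segs = tuple(
        [_seg("6", b1, b2 - 1, "green", "6.green.2")] * CHR6_AMPLICON_COPIES
        + [_seg("6", b2, b3, "green", "6.green.2")] * 2
        + [_seg("6", b3 + 1, g.length("6"), "green", "6.green.2")]
    )
    return DerivativeChromosome("der(6)del(6)dup(6)", segs,
                                telomere_assumed=(True, False))


def _der7_t67(g: GenomeMap) -> DerivativeChromosome:
    """der(7)t(6;7): 7q-deleted chromosome capped by a 6q subtelomeric segment
    from the blue homologue (telomere capture; clone 3 only)."""
    return DerivativeChromosome(
        "der(7)t(6;7)",
        (_seg("7", 1, _DER7_T67_BP7, "green", "7.green.1"),
         _seg("6", _DER7_T67_SEG6[0], _DER7_T67_SEG6[1], "blue", "6.blue.2")))


def _del7_q22q34(g: GenomeMap) -> DerivativeChromosome:
    """del(7)(q22.1q34) interstitial deletion (clone 2 only)."""
    return DerivativeChromosome(
        "del(7)(q22.1q34)",
        (_seg("7", 1, 99_000_000, "green", "7.green.1"),
         _seg("7", 141_000_001, g.length("7"), "green", "7.green.1")))


# ---------------------------------------------------------------------------
# public fixture
# ---------------------------------------------------------------------------

#: Clone fractions: "nominal" rounds to the narrative 30/50/20 split (the
#: der(6)del(6)dup(6)-bearing clone is "about 50% of cells"); "counts" uses
#: the observed G-banded cell counts 21/37/13 of 71.
CLONE_FRACTIONS = {
    "nominal": (0.30, 0.50, 0.20),
    "counts": (21 / 71, 37 / 71, 13 / 71),
}


def u937_stemline(genome: GenomeMap | None = None) -> Karyotype:
    """The 62-chromosome stemline karyotype (clone 1)."""
    g = genome or grch38_map()
    return Karyotype("U937 stemline", tuple(_members_stemline(g)))


def u937_fixture(mode: str = "nominal",
                 genome: GenomeMap | None = None) -> CellPopulation:
    """The three-clone U937 cell population.

    Clone 1 is the 62-chromosome stemline; clone 2 (the major clone) adds the
    der(6)del(6)dup(6) and replaces one chromosome 7 with the del(7)(q22.1q34);
    clone 3 lacks the der(6)del(6)dup(6), one 12 and one 22, and carries the
    der(7)t(6;7) in place of the del(7)-bearing chromosome.  The larger 5q11.2
    deletion of the der(5)t(5;13) is a cross-cutting sub-mosaic in one third
    of cells (the paper could not assign it to a clone).
    """
    if mode not in CLONE_FRACTIONS:
        raise ValueError(f"mode must be 'nominal' or 'counts', got {mode!r}")
    g = genome or grch38_map()
    f1, f2, f3 = CLONE_FRACTIONS[mode]

    stem = u937_stemline(g)

    clone2 = stem.add_member(_der6_del_dup(g)).replace_member("7~3", _del7_q22q34(g))
    clone2 = Karyotype("U937 clone 2", clone2.members)

    clone3 = stem.replace_member("7~3", _der7_t67(g)) \
                 .replace_member("12~3", None) \
                 .replace_member("22~3", None)
    clone3 = Karyotype("U937 clone 3", clone3.members)

    sub = SubMosaic(
        name="5q11.2 larger deletion",
        fraction=CHR5_LARGE_DEL_FRACTION,
        member="der(5)t(5;13)",
        variant=_der5_t513_large(g),
    )
    return CellPopulation(
        f"U937 ({mode})",
        (Clone(stem, f1), Clone(clone2, f2), Clone(clone3, f3)),
        (sub,),
    )


def minimum_11q24_segment_length() -> int:
    """Minimum length (bp) of the 11q24.2->11q24.3 der(11) segment implied by
    the printed boundary-uncertainty coordinates: the segment must at least
    span from the outermost proximal bound to the innermost distal bound."""
    return CHR11_Q24_DISTAL_BOUNDS[0] - CHR11_Q24_PROXIMAL_BOUNDS[1] + 1


# ---------------------------------------------------------------------------
# targeted FISH probe panel (Table-style: name, band, chrom, start, end, kind)
# ---------------------------------------------------------------------------

#: Locus and centromere probes used to resolve the chromosome 11/15/16/20
#: derivatives.  Positions are the published GRCh38 clone coordinates.
U937_FISH_PROBES: list[dict] = [
    {"name": "D11Z1", "kind": "centromere", "chrom": "11", "band": "11cen"},
    {"name": "KMT2A", "kind": "locus", "chrom": "11", "band": "11q23.3",
     "start": 118_436_490, "end": 118_525_221},
    {"name": "RP11-754N12", "kind": "locus", "chrom": "11", "band": "11q24.3",
     "start": 128_311_087, "end": 128_485_203},
    {"name": "FLI1", "kind": "locus", "chrom": "11", "band": "11q24.3",
     "start": 128_694_094, "end": 128_812_000},
    {"name": "MYH11", "kind": "locus", "chrom": "16", "band": "16p13.11",
     "start": 15_703_135, "end": 15_857_030},
    {"name": "RP11-597G23", "kind": "locus", "chrom": "15", "band": "15q14",
     "start": 37_089_671, "end": 37_297_139},
    {"name": "RP11-607G03", "kind": "locus", "chrom": "15", "band": "15q21.2",
     "start": 51_495_000, "end": 51_629_079},
    {"name": "RP11-366L09", "kind": "locus", "chrom": "15", "band": "15q22.2",
     "start": 60_041_031, "end": 60_218_374},
    {"name": "RP11-775C24", "kind": "locus", "chrom": "15", "band": "15q25.1",
     "start": 80_970_069, "end": 81_137_763},
    {"name": "RP11-500O11", "kind": "locus", "chrom": "20", "band": "20p11.21",
     "start": 22_409_751, "end": 22_462_800},
    {"name": "RP11-755M18", "kind": "locus", "chrom": "20", "band": "20p11.21",
     "start": 22_756_464, "end": 22_940_284},
    {"name": "RP11-218C14", "kind": "locus", "chrom": "20", "band": "20p11.21",
     "start": 23_530_430, "end": 23_671_508},
    {"name": "RP11-717H21", "kind": "locus", "chrom": "20", "band": "20p11.21",
     "start": 24_130_923, "end": 24_332_313},
    {"name": "RP11-580L12", "kind": "locus", "chrom": "20", "band": "20p11.21",
     "start": 24_568_986, "end": 24_763_965},
    {"name": "RP11-156D15", "kind": "locus", "chrom": "20", "band": "20p11.21",
     "start": 25_124_608, "end": 25_306_738},
    {"name": "RP11-384D7", "kind": "locus", "chrom": "20", "band": "20p11.21",
     "start": 25_306_022, "end": 25_435_715},
    {"name": "RP11-269F15", "kind": "locus", "chrom": "20", "band": "20p11.1",
     "start": 25_925_848, "end": 26_084_581},
    {"name": "D20Z1", "kind": "centromere", "chrom": "20", "band": "20cen"},
    {"name": "RP11-602P9", "kind": "locus", "chrom": "20", "band": "20q11.21",
     "start": 31_245_645, "end": 31_409_837},
    {"name": "RP11-802B20", "kind": "locus", "chrom": "20", "band": "20q11.21",
     "start": 31_435_456, "end": 31_585_732},
    {"name": "RP11-363M16", "kind": "locus", "chrom": "20", "band": "20q11.21",
     "start": 31_483_476, "end": 31_684_958},
    {"name": "RP11-702M08", "kind": "locus", "chrom": "20", "band": "20q11.21",
     "start": 31_592_650, "end": 31_760_766},
    {"name": "RP11-243J16", "kind": "locus", "chrom": "20", "band": "20q11.21",
     "start": 31_705_215, "end": 31_874_074},
    {"name": "RP11-71I02", "kind": "locus", "chrom": "20", "band": "20q11.21",
     "start": 31_902_727, "end": 32_053_101},
    {"name": "RP11-620H13", "kind": "locus", "chrom": "20", "band": "20q11.21",
     "start": 31_935_170, "end": 32_131_327},
    {"name": "RP11-483M19", "kind": "locus", "chrom": "20", "band": "20q11.21",
     "start": 32_022_592, "end": 32_204_778},
    {"name": "RP11-724J12", "kind": "locus", "chrom": "20", "band": "20q11.21",
     "start": 32_385_910, "end": 32_580_055},
    {"name": "RP11-49G10", "kind": "locus", "chrom": "20", "band": "20q11.21",
     "start": 33_132_629, "end": 33_305_883},
    {"name": "RP11-120F10", "kind": "locus", "chrom": "20", "band": "20q11.22",
     "start": 33_458_641, "end": 33_609_412},
    {"name": "RP11-541L2", "kind": "locus", "chrom": "20", "band": "20q11.22",
     "start": 33_747_044, "end": 33_935_043},
    {"name": "RP11-642P13", "kind": "locus", "chrom": "20", "band": "20q11.22",
     "start": 34_110_945, "end": 34_261_427},
    {"name": "D20S108", "kind": "locus", "chrom": "20", "band": "20q12",
     "start": 42_201_817, "end": 42_202_000},
    {"name": "RP11-317O24", "kind": "locus", "chrom": "5", "band": "5q11.1",
     "start": 50_768_911, "end": 50_961_846},
    {"name": "RP11-101B14", "kind": "locus", "chrom": "5", "band": "5q11.2",
     "start": 57_029_637, "end": 57_212_477},
    {"name": "RP11-313I12", "kind": "locus", "chrom": "5", "band": "5q11.2",
     "start": 58_287_078, "end": 58_423_150},
]

#: Expected metaphase-FISH symbols for chromosome-20-target probes on the two
#: abnormal chromosome-20-containing derivatives (one symbol per probe:
#: "+"-run = copy count, "(+)" = reduced/partial signal, "–" = absent).
TABLE_CHR20_SYMBOLS: dict[str, tuple[str, str]] = {
    # probe: (der(11)t(11;16;20), der(20)t(15;20))
    "RP11-500O11": ("–", "++++"),
    "RP11-755M18": ("–", "+++"),
    "RP11-218C14": ("–", "++"),
    "RP11-717H21": ("–", "+"),
    "RP11-580L12": ("–", "+"),
    "RP11-156D15": ("–", "+"),
    "RP11-384D7": ("–", "+"),
    "RP11-269F15": ("–", "+"),
    "D20Z1": ("–", "+"),
    "RP11-602P9": ("–", "+"),
    "RP11-802B20": ("–", "+"),
    "RP11-363M16": ("(+)", "+"),
    "RP11-702M08": ("+", "+"),
    "RP11-243J16": ("+", "+"),
    "RP11-71I02": ("(+)", "+"),
    "RP11-620H13": ("(+)", "+"),
    "RP11-483M19": ("–", "+"),
    "RP11-724J12": ("–", "+"),
    "RP11-49G10": ("–", "+"),
    "RP11-120F10": ("–", "–"),
    "RP11-541L2": ("–", "–"),
    "RP11-642P13": ("–", "–"),
    "D20S108": ("–", "–"),
}
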