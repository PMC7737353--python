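"""Reference genome map: chromosome lengths, centromeres, subtelomeres, coarse bands.

Coordinates are 1-based inclusive throughout the package (matching the
convention of cytogenetic position reporting); BED export converts to
0-based half-open.  The bundled map carries GRCh38 chromosome lengths and
coarse centromere intervals adequate for viability checking and simulation;
it is not a substitute for a full cytoband annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class CoordinateError(ValueError):
    """A position or interval falls outside the chromosome it references."""


#: GRCh38 primary-assembly chromosome lengths (bp).
GRCH38_LENGTHS: dict[str, int] = {
    "1": 248_956_422, "2": 242_193_529, "3": 198_295_559, "4": 190_214_555,
    "5": 181_538_259, "6": 170_805_979, "7": 159_345_973, "8": 145_138_636,
    "9": 138_394_717, "10": 133_797_422, "11": 135_086_622, "12": 133_275_309,
    "13": 114_364_328, "14": 107_043_718, "15": 101_991_189, "16": 90_338_345,
    "17": 83_257_441, "18": 80_373_285, "19": 58_617_616, "20": 64_444_167,
    "21": 46_709_983, "22": 50_818_468, "X": 156_040_895, "Y": 57_227_415,
}

#: Coarse GRCh38 centromere intervals (1-based inclusive, bp).  Acrocentric
#: short arms (13-15, 21, 22) are treated as telomere-bearing stalks.
GRCH38_CENTROMERES: dict[str, tuple[int, int]] = {
    "1": (121_700_000, 125_100_000), "2": (91_800_000, 96_000_000),
    "3": (87_800_000, 94_000_000), "4": (48_200_000, 51_800_000),
    "5": (46_100_000, 48_800_000), "6": (58_500_000, 62_600_000),
    "7": (58_100_000, 61_100_000), "8": (43_200_000, 45_800_000),
    "9": (42_200_000, 45_500_000), "10": (38_000_000, 41_600_000),
    "11": (51_000_000, 54_400_000), "12": (34_800_000, 38_200_000),
    "13": (16_000_000, 18_900_000), "14": (16_100_000, 18_200_000),
    "15": (17_500_000, 20_500_000), "16": (36_300_000, 38_400_000),
    "17": (22_700_000, 27_400_000), "18": (15_400_000, 21_500_000),
    "19": (24_200_000, 28_100_000), "20": (25_700_000, 30_400_000),
    "21": (10_900_000, 13_000_000), "22": (13_700_000, 17_400_000),
    "X": (58_100_000, 63_800_000), "Y": (10_300_000, 10_600_000),
}


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome lengths, centromere intervals and a subtelomere window.

    Parameters
    ----------
    lengths
        chromosome name -> length in bp.
    centromeres
        chromosome name -> (start, end) centromere interval, 1-based inclusive,
        strictly inside (0, length).
    subtelomere
        Width in bp of the window at each chromosome end inside which a
        segment boundary is taken as evidence of a (sub)telomere.
    bands
        Optional coarse band map: chromosome -> band name -> (start, end).
    """

    lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]]
    subtelomere: int = 500_000
    bands: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, (cs, ce) in self.centromeres.items():
            n = self.lengths[chrom]
            if not (0 < cs <= ce < n):
                raise CoordinateError(
                    f"centromere {cs}-{ce} not strictly inside chromosome {chrom} (1-{n})"
                )
            if self.subtelomere >= n / 2:
                raise CoordinateError(f"subtelomere window too wide for chromosome {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def centromere(self, chrom: str) -> tuple[int, int]:
        self.length(chrom)
        return self.centromeres[chrom]

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        n = self.length(chrom)
        if not (1 <= start <= end <= n):
            raise CoordinateError(f"{chrom}:{start}-{end} outside chromosome (1-{n})")

    def overlaps_centromere(self, chrom: str, start: int, end: int) -> bool:
        cs, ce = self.centromere(chrom)
        return start <= ce and end >= cs

    def in_subtelomere(self, chrom: str, pos: int, arm: str) -> bool:
        """Is ``pos`` inside the subtelomere window of the ``"p"`` or ``"q"`` end?"""
        n = self.length(chrom)
        if arm == "p":
            return pos <= self.subtelomere
        if arm == "q":
            return pos >= n - self.subtelomere
        raise ValueError(f"arm must be 'p' or 'q', got {arm!r}")

    def subset(self, chromosomes: list[str]) -> "GenomeMap":
        return GenomeMap(
            lengths={c: self.lengths[c] for c in chromosomes},
            centromeres={c: self.centromeres[c] for c in chromosomes},
            subtelomere=self.subtelomere,
            bands={c: self.bands[c] for c in chromosomes if c in self.bands},
        )


def grch38_map(subtelomere: int = 500_000) -> GenomeMap:
    """The bundled 24-chromosome GRCh38 map."""
    return GenomeMap(
        lengths=dict(GRCH38_LENGTHS),
        centromeres=dict(GRCH38_CENTROMERES),
        subtelomere=subtelomere,
    )
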