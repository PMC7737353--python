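"""Metaphase and interphase FISH simulation against a karyotype model.

Locus probes (BAC-sized targets) report per-derivative signal as integer
copy-equivalents: each "+" is a signal intensity equivalent to one copy on
the normal chromosome, "(+)" is a reduced signal from a copy that only
partially covers the probe (breakpoint inside the clone), and "–" is absent.
Centromere probes count centromeric segments irrespective of activity;
activity is reported separately (a pseudodicentric shows a signal but no
constriction).  Interphase FISH scores presence/absence of the target in
single cells drawn from the clone/sub-mosaic mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import CoordinateError, GenomeMap, grch38_map
from .karyotype import CellPopulation, DerivativeChromosome, Karyotype

#: Partial-overlap fraction below which a signal is called absent rather
#: than reduced.
REDUCED_SIGNAL_MIN_OVERLAP = 0.10

#: Tandem copies closer than this on one derivative merge into a single
#: multi-copy signal (a "++++" block rather than four resolvable spots).
SIGNAL_MERGE_DISTANCE = 2_000_000


@dataclass(frozen=True)
class FishProbe:
    """A locus (interval) or centromere (whole-chromosome) probe."""

    name: str
    kind: str  # "locus" | "centromere"
    chrom: str
    start: int | None = None
    end: int | None = None
    band: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("locus", "centromere"):
            raise ValueError(f"probe kind must be locus or centromere, got {self.kind!r}")
        if self.kind == "locus" and (self.start is None or self.end is None):
            raise ValueError("locus probe needs start/end")


def probe_from_dict(d: dict) -> FishProbe:
    return FishProbe(d["name"], d["kind"], d["chrom"],
                     d.get("start"), d.get("end"), d.get("band", ""))


@dataclass(frozen=True)
class IntensityClass:
    """Signal of one probe on one derivative: k copy-equivalents, optionally
    with an additional reduced (partial-coverage) component."""

    member: str
    copies: int
    reduced: bool
    signals: tuple[int, ...] = ()  # resolvable signal blocks after merging

    @property
    def symbol(self) -> str:
        if self.copies > 0:
            return "+" * self.copies
        return "(+)" if self.reduced else "–"


def _member_offsets(der: DerivativeChromosome) -> list[int]:
    """Cumulative bp offset of each segment within the derivative."""
    offsets, at = [], 0
    for seg in der.segments:
        offsets.append(at)
        at += seg.length
    return offsets


def simulate_locus_fish(probe: FishProbe, karyotype: Karyotype,
                        genome: GenomeMap | None = None) -> dict[str, IntensityClass]:
    """Per-member signal classes for a locus probe.

    A segment fully containing the probe interval contributes one
    copy-equivalent; a segment covering at least 10% but not all of it sets
    the reduced flag; smaller overlaps are invisible.  Copies closer than
    2 Mb along the derivative merge into one multi-copy signal block.
    """
    genome = genome or grch38_map()
    if probe.kind != "locus":
        raise ValueError("simulate_locus_fish needs a locus probe")
    genome.check_interval(probe.chrom, probe.start, probe.end)
    width = probe.end - probe.start + 1
    out: dict[str, IntensityClass] = {}
    for member in karyotype.members:
        hits: list[tuple[int, bool]] = []  # (offset within derivative, full?)
        offsets = _member_offsets(member)
        for seg, off in zip(member.segments, offsets):
            if seg.chrom != probe.chrom:
                continue
            ov = seg.overlap(probe.start, probe.end)
            if ov == width:
                hits.append((off, True))
            elif ov / width >= REDUCED_SIGNAL_MIN_OVERLAP:
                hits.append((off, False))
        copies = sum(1 for _, full in hits if full)
        reduced = any(not full for _, full in hits)
        signals: list[int] = []
        prev_off: int | None = None
        for off, full in sorted(hits):
            if not full:
                continue
            if prev_off is not None and off - prev_off <= SIGNAL_MERGE_DISTANCE:
                signals[-1] += 1
            else:
                signals.append(1)
            prev_off = off
        out[member.name] = IntensityClass(member.name, copies, reduced, tuple(signals))
    return out


def simulate_centromere_fish(chrom: str, karyotype: Karyotype,
                             genome: GenomeMap | None = None
                             ) -> dict[str, tuple[int, int]]:
    """Per-member (centromeric segments, active centromeres) for one
    chromosome's centromere probe."""
    genome = genome or grch38_map()
    cs, ce = genome.centromere(chrom)
    out: dict[str, tuple[int, int]] = {}
    for member in karyotype.members:
        total = active = 0
        for i, seg in enumerate(member.segments):
            if seg.chrom == chrom and seg.overlap(cs, ce) > 0:
                total += 1
                if i not in member.inactive_centromeres:
                    active += 1
        out[member.name] = (total, active)
    return out


def _cell_has_target(kt: Karyotype, probe: FishProbe, genome: GenomeMap,
                     member: str | None) -> bool:
    members = [m for m in kt.members if member is None or m.name == member]
    if probe.kind == "locus":
        lo, hi = probe.start, probe.end
    else:
        lo, hi = genome.centromere(probe.chrom)
    return any(seg.chrom == probe.chrom and seg.overlap(lo, hi) > 0
               for m in members for seg in m.segments)


def true_present_fraction(probe: FishProbe, pop: CellPopulation,
                          genome: GenomeMap | None = None,
                          member: str | None = None) -> float:
    """Exact fraction of cells carrying >= 1 copy of the probe target,
    optionally restricted to one named derivative (signal scored on a
    specific chromosome, as in metaphase-anchored interphase counting)."""
    genome = genome or grch38_map()
    return sum(f for f, kt in pop.cell_states()
               if _cell_has_target(kt, probe, genome, member))


def simulate_interphase_fish(probe: FishProbe, pop: CellPopulation,
                             n_cells: int, seed: int = 0,
                             genome: GenomeMap | None = None,
                             member: str | None = None) -> tuple[int, int]:
    """Count interphase nuclei with >= 1 copy of the probe target.

    By default presence means >= 1 copy anywhere in the cell's karyotype;
    ``member`` restricts scoring to one derivative (the extra-signal reading
    used when other chromosomes also carry the region).  Cells are drawn from
    the clone/sub-mosaic mixture; counts are binomial and seed-reproducible.
    Returns (n_present, n_absent).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    genome = genome or grch38_map()
    fraction = true_present_fraction(probe, pop, genome, member)
    rng = np.random.default_rng(seed)
    n_present = int(rng.binomial(n_cells, min(1.0, fraction)))
    return n_present, n_cells - n_present
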