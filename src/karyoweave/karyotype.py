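"""Homologue-tagged karyotype model: segments, derivatives, clones, events.

The unit of structure is the :class:`SegmentInterval` — an oriented piece of a
reference chromosome tagged with the parental homologue it descends from and a
founder-copy identifier.  A :class:`DerivativeChromosome` is an ordered list of
such segments; normal chromosomes are single-segment derivatives.  A
:class:`Karyotype` is a multiset of derivatives, a :class:`Clone` a karyotype
with a cell fraction, and a :class:`CellPopulation` a mixture of clones plus
optional cross-cutting sub-mosaic events (an aberration present in a stated
fraction of cells independent of the clone structure).

Rearrangement events (deletion, duplication, amplification, translocation,
whole-genome duplication) are applied functionally: :func:`apply_event` returns
a new karyotype and conserves base content exactly where the event demands it.

Viability follows the cytogenetic rule that a transmissible chromosome needs
two telomeres and at least one active centromere; pseudodicentrics (two
centromeres, one inactivated) are accepted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .genome import CoordinateError, GenomeMap, grch38_map


class ReferenceError_(KeyError):
    """A named chromosome or karyotype member does not exist."""


# ---------------------------------------------------------------------------
# segments and derivatives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentInterval:
    """An oriented, homologue-tagged interval of a reference chromosome.

    ``start``/``end`` are 1-based inclusive.  ``orientation`` is ``"+"`` when
    genomic coordinate increases left-to-right within the derivative.
    ``founder`` identifies the physical founder copy the material descends
    from; founder copies created by whole-genome duplication carry distinct
    identifiers but resolve to the same genotype source (chromosome +
    homologue), making them genotype-identical.
    """

    chrom: str
    start: int
    end: int
    homologue: str = "h1"
    orientation: str = "+"
    founder: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(f"bad segment {self.chrom}:{self.start}-{self.end}")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, start: int, end: int) -> int:
        """Overlap length in bp with ``start``-``end`` (same chromosome assumed)."""
        return max(0, min(self.end, end) - max(self.start, start) + 1)

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom, "start": self.start, "end": self.end,
            "homologue": self.homologue, "orientation": self.orientation,
            "founder": self.founder,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentInterval":
        return cls(**d)


@dataclass(frozen=True)
class DerivativeChromosome:
    """An ordered sequence of segments forming one (possibly abnormal) chromosome.

    ``inactive_centromeres`` holds indices of segments whose centromere is
    present but inactive (pseudodicentric bookkeeping).  ``telomere_assumed``
    marks ends believed capped despite the terminal segment not reaching an
    array-visible subtelomere (p end, q end).
    """

    name: str
    segments: tuple[SegmentInterval, ...]
    inactive_centromeres: frozenset = frozenset()
    telomere_assumed: tuple[bool, bool] = (False, False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"derivative {self.name!r} has no segments")

    @property
    def total_bp(self) -> int:
        return sum(s.length for s in self.segments)

    def chromosomes(self) -> set[str]:
        return {s.chrom for s in self.segments}

    def content_length(self, chrom: str) -> int:
        return sum(s.length for s in self.segments if s.chrom == chrom)

    def copies(self, chrom: str, start: int, end: int,
               homologue: Optional[str] = None) -> float:
        """Fractional copy count of an interval, partial overlaps pro-rated."""
        width = end - start + 1
        total = 0.0
        for s in self.segments:
            if s.chrom != chrom:
                continue
            if homologue is not None and s.homologue != homologue:
                continue
            total += s.overlap(start, end) / width
        return total

    def renamed(self, name: str) -> "DerivativeChromosome":
        return replace(self, name=name)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "segments": [s.to_dict() for s in self.segments],
            "inactive_centromeres": sorted(self.inactive_centromeres),
            "telomere_assumed": list(self.telomere_assumed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DerivativeChromosome":
        return cls(
            name=d["name"],
            segments=tuple(SegmentInterval.from_dict(s) for s in d["segments"]),
            inactive_centromeres=frozenset(d.get("inactive_centromeres", ())),
            telomere_assumed=tuple(d.get("telomere_assumed", (False, False))),
        )


def normal_chromosome(chrom: str, genome: GenomeMap, homologue: str,
                      founder: str = "", name: Optional[str] = None) -> DerivativeChromosome:
    """A single-segment derivative spanning the whole reference chromosome."""
    seg = SegmentInterval(chrom, 1, genome.length(chrom), homologue,
                          "+", founder or f"{chrom}.{homologue}.1")
    return DerivativeChromosome(name or chrom, (seg,))


# ---------------------------------------------------------------------------
# viability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViabilityReport:
    """Centromere/telomere audit of one derivative chromosome."""

    active_centromeres: int
    total_centromeres: int
    p_telomere: bool
    q_telomere: bool
    verdict: str  # viable | acentric | unterminated | dicentric-viable

    @property
    def is_viable(self) -> bool:
        return self.verdict in ("viable", "dicentric-viable")


def _end_is_telomeric(seg: SegmentInterval, genome: GenomeMap, end: str) -> bool:
    """Does the outward-facing genomic end of a terminal segment reach a subtelomere?"""
    if end == "p":
        outward = seg.start if seg.orientation == "+" else seg.end
        arm = "p" if seg.orientation == "+" else "q"
    else:
        outward = seg.end if seg.orientation == "+" else seg.start
        arm = "q" if seg.orientation == "+" else "p"
    return genome.in_subtelomere(seg.chrom, outward, arm)


def validate_chromosome(der: DerivativeChromosome,
                        genome: Optional[GenomeMap] = None) -> ViabilityReport:
    """Count centromeres and telomere-bearing ends; classify viability.

    A derivative is ``viable`` with one active centromere and two
    telomere-bearing ends, ``acentric`` with no active centromere,
    ``unterminated`` when an end lacks a telomere, and ``dicentric-viable``
    when two or more centromeres are physically present with at least one
    active (pseudodicentrics and true dicentrics are flagged, not rejected).
    """
    genome = genome or grch38_map()
    total = active = 0
    for i, seg in enumerate(der.segments):
        if genome.overlaps_centromere(seg.chrom, seg.start, seg.end):
            total += 1
            if i not in der.inactive_centromeres:
                active += 1
    p_tel = der.telomere_assumed[0] or _end_is_telomeric(der.segments[0], genome, "p")
    q_tel = der.telomere_assumed[1] or _end_is_telomeric(der.segments[-1], genome, "q")
    if active == 0:
        verdict = "acentric"
    elif not (p_tel and q_tel):
        verdict = "unterminated"
    elif total >= 2:
        verdict = "dicentric-viable"
    else:
        verdict = "viable"
    return ViabilityReport(active, total, p_tel, q_tel, verdict)


# ---------------------------------------------------------------------------
# karyotypes, clones, populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Karyotype:
    """A named multiset of derivative chromosomes."""

    name: str
    members: tuple[DerivativeChromosome, ...]

    @property
    def total_bp(self) -> int:
        return sum(m.total_bp for m in self.members)

    def member(self, name: str) -> DerivativeChromosome:
        for m in self.members:
            if m.name == name:
                return m
        raise ReferenceError_(f"no member named {name!r} in karyotype {self.name!r}")

    def has_member(self, name: str) -> bool:
        return any(m.name == name for m in self.members)

    def replace_member(self, name: str, new: Optional[DerivativeChromosome]) -> "Karyotype":
        if not self.has_member(name):
            raise ReferenceError_(f"no member named {name!r}")
        members = []
        for m in self.members:
            if m.name == name:
                if new is not None:
                    members.append(new)
            else:
                members.append(m)
        return Karyotype(self.name, tuple(members))

    def add_member(self, new: DerivativeChromosome) -> "Karyotype":
        return Karyotype(self.name, self.members + (new,))

    def homologues(self, chrom: str) -> set[str]:
        return {s.homologue for m in self.members for s in m.segments if s.chrom == chrom}

    def copies(self, chrom: str, start: int, end: int,
               homologue: Optional[str] = None) -> float:
        return sum(m.copies(chrom, start, end, homologue) for m in self.members)

    def to_dict(self) -> dict:
        return {"name": self.name, "members": [m.to_dict() for m in self.members]}

    @classmethod
    def from_dict(cls, d: dict) -> "Karyotype":
        return cls(d["name"], tuple(DerivativeChromosome.from_dict(m) for m in d["members"]))


def count_chromosomes(karyotype: Karyotype) -> int:
    """Number of chromosomes (multiset cardinality)."""
    return len(karyotype.members)


@dataclass(frozen=True)
class Clone:
    """A karyotype present in a stated fraction of cells."""

    karyotype: Karyotype
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"clone fraction {self.fraction} outside [0, 1]")


@dataclass(frozen=True)
class SubMosaic:
    """A cross-cutting aberration present in ``fraction`` of cells of every clone.

    In affected cells the member named ``member`` (where present) is replaced
    by ``variant`` (or removed when ``variant`` is None).
    """

    name: str
    fraction: float
    member: str
    variant: Optional[DerivativeChromosome] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"sub-mosaic fraction {self.fraction} outside [0, 1]")


@dataclass(frozen=True)
class CellPopulation:
    """Mixture of clones plus optional cross-cutting sub-mosaic events."""

    name: str
    clones: tuple[Clone, ...]
    sub_mosaics: tuple[SubMosaic, ...] = ()

    def __post_init__(self) -> None:
        total = sum(c.fraction for c in self.clones)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone fractions sum to {total}, not 1")

    def cell_states(self) -> list[tuple[float, Karyotype]]:
        """Expand clones x sub-mosaic on/off combinations into weighted karyotypes."""
        states: list[tuple[float, Karyotype]] = []
        for clone in self.clones:
            variants: list[tuple[float, Karyotype]] = [(clone.fraction, clone.karyotype)]
            for sm in self.sub_mosaics:
                nxt: list[tuple[float, Karyotype]] = []
                for f, kt in variants:
                    if kt.has_member(sm.member):
                        if sm.fraction > 0:
                            nxt.append((f * sm.fraction, kt.replace_member(sm.member, sm.variant)))
                        if sm.fraction < 1:
                            nxt.append((f * (1 - sm.fraction), kt))
                    else:
                        nxt.append((f, kt))
                variants = nxt
            states.extend(variants)
        return [(f, kt) for f, kt in states if f > 0]

    def all_homologues(self, chrom: str) -> set[str]:
        labels: set[str] = set()
        for _, kt in self.cell_states():
            labels |= kt.homologues(chrom)
        return labels


def copy_number_profile(pop: CellPopulation, chrom: str, start: int, end: int,
                        genome: Optional[GenomeMap] = None) -> float:
    """Population-average copy number of an interval (partial overlaps pro-rated)."""
    if genome is not None:
        genome.check_interval(chrom, start, end)
    return sum(f * kt.copies(chrom, start, end) for f, kt in pop.cell_states())


def homologue_dosage_profile(pop: CellPopulation, chrom: str, start: int, end: int,
                             genome: Optional[GenomeMap] = None) -> dict[str, float]:
    """Population-average copies of the interval split by homologue label."""
    if genome is not None:
        genome.check_interval(chrom, start, end)
    labels = pop.all_homologues(chrom)
    return {
        lab: sum(f * kt.copies(chrom, start, end, lab) for f, kt in pop.cell_states())
        for lab in sorted(labels)
    }


def major_minor(dosage: dict[str, float]) -> tuple[float, float]:
    """Collapse a homologue-dosage dict to (major, minor) averages."""
    vals = sorted(dosage.values(), reverse=True)
    vals += [0.0] * (2 - len(vals))
    return vals[0], vals[1]


# ---------------------------------------------------------------------------
# rearrangement events
# ---------------------------------------------------------------------------

_EVENT_KINDS = (
    "deletion", "tandem-duplication", "inverted-duplication", "amplification",
    "balanced-translocation", "unbalanced-translocation", "whole-genome-duplication",
)


@dataclass(frozen=True)
class RearrangementEvent:
    """One structural event.  Fields not relevant to ``kind`` stay None.

    Interval kinds (deletion/duplication/amplification) act on ``member`` over
    ``chrom:start-end``; translocations join ``member`` broken after
    ``pos`` (on ``chrom``) to ``member2`` broken after ``pos2`` (on ``chrom2``);
    whole-genome duplication copies every member named in ``complement``.
    """

    kind: str
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    member: Optional[str] = None
    homologue: Optional[str] = None
    count: int = 2
    chrom2: Optional[str] = None
    pos: Optional[int] = None
    pos2: Optional[int] = None
    member2: Optional[str] = None
    complement: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "amplification" and self.count < 2:
            raise ValueError("amplification count must be >= 2")


def _match(seg: SegmentInterval, chrom: str, homologue: Optional[str]) -> bool:
    return seg.chrom == chrom and (homologue is None or seg.homologue == homologue)


def _delete_interval(der: DerivativeChromosome, chrom: str, start: int, end: int,
                     homologue: Optional[str]) -> DerivativeChromosome:
    out: list[SegmentInterval] = []
    hit = False
    for seg in der.segments:
        if not _match(seg, chrom, homologue) or seg.overlap(start, end) == 0:
            out.append(seg)
            continue
        hit = True
        left = (seg.start, min(seg.end, start - 1))
        right = (max(seg.start, end + 1), seg.end)
        pieces = [p for p in (left, right) if p[0] <= p[1]]
        if seg.orientation == "-":
            pieces = pieces[::-1]
        out.extend(replace(seg, start=a, end=b) for a, b in pieces)
    if not hit:
        raise CoordinateError(
            f"deletion {chrom}:{start}-{end} hits nothing in member {der.name!r}")
    if not out:
        raise CoordinateError(f"deletion removes all of member {der.name!r}")
    return replace(der, segments=tuple(out), inactive_centromeres=frozenset())


def _duplicate_interval(der: DerivativeChromosome, chrom: str, start: int, end: int,
                        homologue: Optional[str], extra_copies: int,
                        invert_extras: bool) -> DerivativeChromosome:
    out: list[SegmentInterval] = []
    hit = False
    for seg in der.segments:
        if hit or not _match(seg, chrom, homologue) or not (
                seg.start <= start and end <= seg.end):
            out.append(seg)
            continue
        hit = True
        core = replace(seg, start=start, end=end)
        extras = [
            replace(core, orientation=("-" if core.orientation == "+" else "+"))
            if invert_extras else core
            for _ in range(extra_copies)
        ]
        if seg.orientation == "+":
            parts = ([replace(seg, end=start - 1)] if start > seg.start else []) \
                + [core] + extras \
                + ([replace(seg, start=end + 1)] if end < seg.end else [])
        else:
            parts = ([replace(seg, start=end + 1)] if end < seg.end else []) \
                + [core] + extras \
                + ([replace(seg, end=start - 1)] if start > seg.start else [])
        out.extend(parts)
    if not hit:
        raise CoordinateError(
            f"duplication target {chrom}:{start}-{end} not inside a single segment "
            f"of member {der.name!r}")
    return replace(der, segments=tuple(out), inactive_centromeres=frozenset())


def _split_member(der: DerivativeChromosome, chrom: str, pos: int,
                  homologue: Optional[str]
                  ) -> tuple[tuple[SegmentInterval, ...], tuple[SegmentInterval, ...]]:
    """Split a derivative between genomic ``pos`` and ``pos + 1`` of ``chrom``.

    The first matching segment (walking the derivative left to right) is cut.
    Returns (left part, right part) in derivative order.
    """
    for i, seg in enumerate(der.segments):
        if _match(seg, chrom, homologue) and seg.start <= pos <= seg.end:
            if seg.orientation == "+":
                a = [replace(seg, end=pos)] if pos >= seg.start else []
                b = [replace(seg, start=pos + 1)] if pos + 1 <= seg.end else []
            else:
                a = [replace(seg, start=pos + 1)] if pos + 1 <= seg.end else []
                b = [replace(seg, end=pos)] if pos >= seg.start else []
            return der.segments[:i] + tuple(a), tuple(b) + der.segments[i + 1:]
    raise CoordinateError(f"no segment of {chrom} covering {pos} in member {der.name!r}")


def _flip(segments: tuple[SegmentInterval, ...]) -> tuple[SegmentInterval, ...]:
    """Reverse a run of segments, flipping each orientation."""
    return tuple(
        replace(s, orientation="-" if s.orientation == "+" else "+")
        for s in reversed(segments))


def _count_centromeres(segments, genome: GenomeMap) -> int:
    return sum(1 for s in segments
               if genome.overlaps_centromere(s.chrom, s.start, s.end))


def apply_event(karyotype: Karyotype, event: RearrangementEvent,
                genome: Optional[GenomeMap] = None) -> Karyotype:
    """Apply one rearrangement event, returning a new karyotype.

    Balanced translocation conserves total base content exactly; deletion
    removes exactly the stated interval; duplication/amplification insert the
    stated number of extra copies (inverted where requested); whole-genome
    duplication adds one genotype-identical copy of each member of the
    designated complement.
    """
    genome = genome or grch38_map()
    kind = event.kind

    if kind == "whole-genome-duplication":
        kt = karyotype
        for name in event.complement:
            src = kt.member(name)
            kt = kt.add_member(src.renamed(name + "~2"))
        return kt

    if kind in ("deletion", "tandem-duplication", "inverted-duplication", "amplification"):
        if event.chrom is None or event.start is None or event.end is None:
            raise ValueError(f"{kind} needs chrom/start/end")
        genome.check_interval(event.chrom, event.start, event.end)
        target = event.member
        if target is None:
            hits = [m.name for m in karyotype.members
                    if any(_match(s, event.chrom, event.homologue)
                           and s.overlap(event.start, event.end) > 0
                           for s in m.segments)]
            if len(hits) != 1:
                raise ReferenceError_(
                    f"{kind} target ambiguous or absent (candidates {hits})")
            target = hits[0]
        der = karyotype.member(target)
        if kind == "deletion":
            new = _delete_interval(der, event.chrom, event.start, event.end, event.homologue)
        elif kind == "tandem-duplication":
            new = _duplicate_interval(der, event.chrom, event.start, event.end,
                                      event.homologue, 1, False)
        elif kind == "inverted-duplication":
            new = _duplicate_interval(der, event.chrom, event.start, event.end,
                                      event.homologue, 1, True)
        else:  # amplification: count total copies of the interval
            new = _duplicate_interval(der, event.chrom, event.start, event.end,
                                      event.homologue, event.count - 1, False)
        return karyotype.replace_member(target, new)

    if kind in ("balanced-translocation", "unbalanced-translocation"):
        if None in (event.chrom, event.pos, event.chrom2, event.pos2) or \
                event.member is None or event.member2 is None:
            raise ValueError(f"{kind} needs member/chrom/pos for both partners")
        genome.check_interval(event.chrom, event.pos, event.pos)
        genome.check_interval(event.chrom2, event.pos2, event.pos2)
        der_a = karyotype.member(event.member)
        der_b = karyotype.member(event.member2)
        left_a, right_a = _split_member(der_a, event.chrom, event.pos, event.homologue)
        left_b, right_b = _split_member(der_b, event.chrom2, event.pos2, None)
        if kind == "balanced-translocation":
            if not left_a or not right_b or not left_b or not right_a:
                raise CoordinateError("translocation breakpoint at a member end")
            # two reciprocal pairings exist (the second inverts one piece, as
            # when a p-arm break exchanges with a q-arm break); prefer the one
            # giving each product exactly one centromere
            options = (
                (left_a + right_b, left_b + right_a),
                (left_a + _flip(left_b), _flip(right_a) + right_b),
            )

            def badness(products):
                return sum(abs(_count_centromeres(segs, genome) - 1)
                           for segs in products)

            segs_a, segs_b = min(options, key=badness)
            new_a = replace(der_a, segments=segs_a,
                            inactive_centromeres=frozenset(),
                            name=f"der({der_a.name})t({der_a.name};{der_b.name})")
            new_b = replace(der_b, segments=segs_b,
                            inactive_centromeres=frozenset(),
                            name=f"der({der_b.name})t({der_b.name};{der_a.name})")
            return karyotype.replace_member(event.member, new_a) \
                            .replace_member(event.member2, new_b)
        # unbalanced: recipient keeps its left part plus a *copy* of the donor's
        # right part; the donor chromosome itself is unchanged.
        if not left_a or not right_b:
            raise CoordinateError("unbalanced translocation would produce an empty product")
        new_a = replace(der_a, segments=left_a + right_b,
                        inactive_centromeres=frozenset(),
                        name=f"der({der_a.name})t({der_a.name};{der_b.name})")
        return karyotype.replace_member(event.member, new_a)

    raise ValueError(f"unhandled event kind {kind!r}")  # pragma: no cover


def iscn_like(der: DerivativeChromosome) -> str:
    """A write-only ISCN-flavoured summary of a derivative's segment list."""
    parts = []
    for s in der.segments:
        a, b = (s.start, s.end) if s.orientation == "+" else (s.end, s.start)
        parts.append(f"{s.chrom}:{a}->{b}")
    return f"{der.name}({'::'.join(parts)})"
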