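"""Integration of per-segment calls with FISH membership evidence:
derivative composition, homologue assignment, and centromere/telomere
capture detection.

Composition is multiset-level: array plus locus FISH say *what* a derivative
contains and in how many copies, not the internal order, so segment order is
only used when it is actually known (truth-derived compositions).  Inferred
segment copies are distributed across derivatives proportionally to FISH
copy-equivalents; copies no probe accounts for go to an explicit "unplaced"
bucket rather than being dropped, and FISH/array disagreements produce
structured conflict reports instead of exceptions.

Capture detection follows the viability logic: a derivative whose only
centromere comes from a chromosome contributing a small minority of its
length — while the majority content's own centromere is absent — is a
centromere capture; a short foreign subtelomeric segment capping a
derivative whose centromere lies elsewhere is a telomere capture (on the
array, the subtelomeric segment acts as a proxy for the telomere).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .fish import FishProbe, simulate_centromere_fish, simulate_locus_fish
from .genome import GenomeMap, grch38_map
from .inference import SegmentCall
from .karyotype import DerivativeChromosome, Karyotype

#: A chromosome contributing less than this share of a derivative's length is
#: a "minority" donor for centromere capture.
CENTROMERE_MINORITY_SHARE = 0.25
#: A telomere-capturing cap must be shorter than this share of the derivative.
TELOMERE_MINORITY_SHARE = 0.15
#: Window around a centromere interval counted as "spanning the centromere".
PERICENTROMERIC_WINDOW = 3_000_000

UNPLACED = "unplaced"


@dataclass(frozen=True)
class Placement:
    """A copy-weighted interval of one chromosome on one derivative."""

    derivative: str
    chrom: str
    start: int
    end: int
    copies: float = 1.0
    homologue: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DerivativeComposition:
    """Inferred (or truth-derived) content of one abnormal chromosome."""

    name: str
    segments: list[Placement]
    centromeres: dict[str, int] = field(default_factory=dict)  # chrom -> count
    ordered: bool = False  # True when `segments` reflects physical order

    def total_weighted_length(self) -> float:
        return sum(s.length * max(s.copies, 0.0) for s in self.segments)

    def content_share(self, chrom: str) -> float:
        total = self.total_weighted_length()
        if total <= 0:
            return 0.0
        own = sum(s.length * max(s.copies, 0.0)
                  for s in self.segments if s.chrom == chrom)
        return own / total

    def majority_chromosome(self) -> Optional[str]:
        chroms = {s.chrom for s in self.segments}
        if not chroms:
            return None
        return max(chroms, key=self.content_share)


@dataclass(frozen=True)
class CaptureCall:
    derivative: str
    kind: str               # "centromere" | "telomere"
    donor: str              # chromosome supplying the centromere/telomere
    donor_start: int
    donor_end: int
    donor_length: int
    rationale: str


@dataclass(frozen=True)
class Conflict:
    """FISH copy-equivalents exceed the array-inferred copies for a segment."""

    chrom: str
    start: int
    end: int
    fish_copies: float
    inferred_copies: float
    detail: str


@dataclass
class MembershipEvidence:
    """FISH observations keyed by probe: per-derivative copy-equivalents and
    per-chromosome centromere counts."""

    probes: dict[str, FishProbe]
    locus_copies: dict[str, dict[str, int]]          # probe -> derivative -> k
    centromere_counts: dict[str, dict[str, int]]     # chrom -> derivative -> n

    def derivatives(self) -> list[str]:
        names: set[str] = set()
        for table in self.locus_copies.values():
            names |= set(table)
        for table in self.centromere_counts.values():
            names |= set(table)
        return sorted(names)


def evidence_from_fish(probes: list[FishProbe], karyotype: Karyotype,
                       derivatives: Optional[list[str]] = None,
                       genome: Optional[GenomeMap] = None) -> MembershipEvidence:
    """Simulate the targeted-FISH evidence table for the named derivatives."""
    genome = genome or grch38_map()
    derivatives = derivatives or [m.name for m in karyotype.members]
    locus: dict[str, dict[str, int]] = {}
    cen: dict[str, dict[str, int]] = {}
    for probe in probes:
        if probe.kind == "locus":
            table = simulate_locus_fish(probe, karyotype, genome)
            locus[probe.name] = {d: table[d].copies for d in derivatives if d in table}
        else:
            table = simulate_centromere_fish(probe.chrom, karyotype, genome)
            cen.setdefault(probe.chrom, {}).update(
                {d: table[d][0] for d in derivatives if d in table})
    return MembershipEvidence({p.name: p for p in probes}, locus, cen)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def composition_from_derivative(der: DerivativeChromosome,
                                genome: Optional[GenomeMap] = None
                                ) -> DerivativeComposition:
    """Ground-truth composition of a known derivative (ordered)."""
    genome = genome or grch38_map()
    segs = [Placement(der.name, s.chrom, s.start, s.end, 1.0, s.homologue)
            for s in der.segments]
    cen: dict[str, int] = {}
    for s in der.segments:
        if genome.overlaps_centromere(s.chrom, s.start, s.end):
            cen[s.chrom] = cen.get(s.chrom, 0) + 1
    return DerivativeComposition(der.name, segs, cen, ordered=True)


def compose_derivatives(calls: list[SegmentCall], evidence: MembershipEvidence,
                        genome: Optional[GenomeMap] = None,
                        tolerance: float = 0.75
                        ) -> tuple[list[DerivativeComposition], list[Conflict]]:
    """Distribute inferred segment copies across derivatives per FISH evidence.

    For each called segment, locus probes inside it vote with their
    copy-equivalents; copies are placed proportionally (capped by the
    inferred total) and the remainder is booked under an "unplaced"
    pseudo-derivative.  Total copies are conserved exactly.
    """
    genome = genome or grch38_map()
    names = evidence.derivatives()
    comps = {n: DerivativeComposition(n, []) for n in names}
    comps[UNPLACED] = DerivativeComposition(UNPLACED, [])
    conflicts: list[Conflict] = []

    for call in calls:
        if call.selected is None:
            comps[UNPLACED].segments.append(
                Placement(UNPLACED, call.chrom, call.start, call.end, 0.0))
            continue
        total = call.cn_total
        inside = []
        for pname, table in evidence.locus_copies.items():
            probe = evidence.probes[pname]
            if probe.chrom != call.chrom or probe.start is None:
                continue
            if probe.start < call.start or probe.end > call.end:
                continue
            inside.append((probe, table))
        if not inside:
            comps[UNPLACED].segments.append(
                Placement(UNPLACED, call.chrom, call.start, call.end, total))
            continue
        # each probe localises the stretch of the call nearest to it: split
        # the call at midpoints between consecutive probes so an
        # array-invisible junction (e.g. a balanced-translocation breakpoint)
        # does not credit a whole call to one derivative
        inside.sort(key=lambda pt: pt[0].start)
        cuts = [call.start]
        for (p1, _), (p2, _) in zip(inside[:-1], inside[1:]):
            cuts.append((p1.end + p2.start) // 2)
        cuts.append(call.end)
        # placements are length-weighted downstream; keep them in
        # array-visible space (the probe-free centromere interval carries no
        # placement evidence — centromere FISH tracks it separately)
        cs, ce = genome.centromere(call.chrom)
        pieces = []
        for (probe, table), a, b in zip(inside, cuts[:-1], cuts[1:]):
            if a < cs and b > ce:
                pieces.append((probe, table, a, cs - 1))
                pieces.append((probe, table, ce + 1, b))
            elif cs <= a <= ce:
                pieces.append((probe, table, min(ce + 1, b), b))
            elif cs <= b <= ce:
                pieces.append((probe, table, a, max(cs - 1, a)))
            else:
                pieces.append((probe, table, a, b))
        for probe, table, a, b in pieces:
            votes = {d: float(k) for d, k in table.items() if k > 0}
            fish_total = sum(votes.values())
            if fish_total <= 0:
                comps[UNPLACED].segments.append(
                    Placement(UNPLACED, call.chrom, a, b, total))
                continue
            if fish_total > total + tolerance:
                conflicts.append(Conflict(
                    call.chrom, a, b, fish_total, total,
                    f"FISH copy-equivalents at {probe.name} exceed "
                    f"array-inferred copies"))
            scale = min(1.0, total / fish_total)
            placed = 0.0
            for der, v in sorted(votes.items()):
                c = v * scale
                comps[der].segments.append(Placement(der, call.chrom, a, b, c))
                placed += c
            residual = total - placed
            if residual > 1e-9:
                comps[UNPLACED].segments.append(
                    Placement(UNPLACED, call.chrom, a, b, residual))

    for chrom, table in evidence.centromere_counts.items():
        for der, n in table.items():
            if n > 0:
                comps[der].centromeres[chrom] = \
                    comps[der].centromeres.get(chrom, 0) + n
    return list(comps.values()), conflicts


# ---------------------------------------------------------------------------
# capture detection
# ---------------------------------------------------------------------------

def detect_centromere_capture(comp: DerivativeComposition,
                              genome: Optional[GenomeMap] = None,
                              minority_share: float = CENTROMERE_MINORITY_SHARE
                              ) -> list[CaptureCall]:
    """Flag a derivative whose every centromere comes from a minority donor.

    All centromeres present must originate from chromosomes each contributing
    less than ``minority_share`` of the derivative's (copy-weighted) length,
    while the majority content's own centromere is absent.
    """
    genome = genome or grch38_map()
    if not comp.segments:
        raise ValueError(f"empty composition for {comp.name!r}")
    cen_chroms = [c for c, n in comp.centromeres.items() if n > 0]
    if not cen_chroms:
        return []
    majority = comp.majority_chromosome()
    if majority in cen_chroms:
        return []
    if any(comp.content_share(c) >= minority_share for c in cen_chroms):
        return []
    calls = []
    for donor in cen_chroms:
        cs, ce = genome.centromere(donor)
        lo, hi = cs - PERICENTROMERIC_WINDOW, ce + PERICENTROMERIC_WINDOW
        near = [s for s in comp.segments
                if s.chrom == donor and s.start <= hi and s.end >= lo]
        if near:
            dstart = min(s.start for s in near)
            dend = max(s.end for s in near)
        else:
            dstart, dend = cs, ce
        calls.append(CaptureCall(
            comp.name, "centromere", donor, dstart, dend, dend - dstart + 1,
            f"all centromeres from minority donors ({donor}: "
            f"{comp.content_share(donor):.0%} of length); "
            f"majority content ({majority}) centromere absent"))
    return calls


def detect_telomere_capture(comp: DerivativeComposition,
                            genome: Optional[GenomeMap] = None,
                            minority_share: float = TELOMERE_MINORITY_SHARE
                            ) -> list[CaptureCall]:
    """Flag short foreign subtelomeric segments capping a derivative.

    A content segment reaching a subtelomere of its source chromosome is a
    capture cap when that chromosome (i) contributes less than
    ``minority_share`` of the derivative, (ii) is not the majority content,
    (iii) supplies no centromere to the derivative, (iv) forms the
    chromosome's only contiguous content block on the derivative (a cap, not
    a piece of a larger native run), and (v) — when segment order is known —
    sits terminally next to content of a different chromosome.
    """
    genome = genome or grch38_map()
    majority = comp.majority_chromosome()
    cen_chroms = {c for c, n in comp.centromeres.items() if n > 0}
    calls = []
    for i, seg in enumerate(comp.segments):
        p_tel = genome.in_subtelomere(seg.chrom, seg.start, "p")
        q_tel = genome.in_subtelomere(seg.chrom, seg.end, "q")
        if not (p_tel or q_tel):
            continue
        if seg.chrom == majority or seg.chrom in cen_chroms:
            continue
        if comp.content_share(seg.chrom) >= minority_share:
            continue
        if len(_chrom_blocks(comp, seg.chrom)) != 1:
            continue
        if comp.ordered:
            terminal = i in (0, len(comp.segments) - 1)
            if not terminal:
                continue
            neighbour = comp.segments[1] if i == 0 else comp.segments[-2]
            if neighbour.chrom == seg.chrom:
                continue
        calls.append(CaptureCall(
            comp.name, "telomere", seg.chrom, seg.start, seg.end, seg.length,
            f"foreign subtelomeric segment of {seg.chrom} "
            f"({comp.content_share(seg.chrom):.0%} of length) capping "
            f"{majority} content"))
    return calls


def _chrom_blocks(comp: DerivativeComposition, chrom: str,
                  gap: int = 3_000_000) -> list[tuple[int, int]]:
    """Contiguous genomic content blocks of one chromosome (gaps <= ``gap``
    merged, bridging probe-free regions and adjacent call boundaries)."""
    ivs = sorted((s.start, s.end) for s in comp.segments if s.chrom == chrom)
    blocks: list[tuple[int, int]] = []
    for a, b in ivs:
        if blocks and a - blocks[-1][1] <= gap:
            blocks[-1] = (blocks[-1][0], max(blocks[-1][1], b))
        else:
            blocks.append((a, b))
    return blocks


# ---------------------------------------------------------------------------
# homologue assignment
# ---------------------------------------------------------------------------

@dataclass
class AssignmentResult:
    chromosome: str
    placements: list[Placement]
    assignments: list[tuple[str, ...]]   # label per placement, canonical
    unique: bool
    violated: list[str] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return bool(self.assignments)


def _dosage_for(placements: list[Placement], labels: tuple[str, ...],
                label: str, start: int, end: int) -> float:
    width = end - start + 1
    dose = 0.0
    for p, lab in zip(placements, labels):
        if lab != label:
            continue
        ov = max(0, min(p.end, end) - max(p.start, start) + 1)
        dose += p.copies * ov / width
    return dose


def solve_homologue_assignment(chromosome: str, calls: list[SegmentCall],
                               placements: list[Placement],
                               tol: float = 0.3) -> AssignmentResult:
    """Exhaustively label placements with the two homologues.

    An assignment is kept when, for every segment call on the chromosome, the
    two per-label dosage sums match the call's (n_major, n_minor) within
    ``tol``.  The first placement's label is fixed to break the global swap
    symmetry.  No valid assignment yields an inconsistency report listing the
    violated segments.
    """
    placements = [p for p in placements if p.chrom == chromosome]
    calls = [c for c in calls if c.chrom == chromosome and c.selected is not None]
    if not placements:
        raise ValueError(f"no placements of chromosome {chromosome}")
    n = len(placements)
    valid: list[tuple[str, ...]] = []
    violations: dict[str, int] = {}
    for mask in range(2 ** (n - 1)):
        labels = ("h1",) + tuple(
            "h1" if (mask >> i) & 1 == 0 else "h2" for i in range(n - 1))
        ok = True
        for call in calls:
            d1 = _dosage_for(placements, labels, "h1", call.start, call.end)
            d2 = _dosage_for(placements, labels, "h2", call.start, call.end)
            want = sorted((call.n_major, call.n_minor), reverse=True)
            got = sorted((d1, d2), reverse=True)
            if abs(want[0] - got[0]) > tol or abs(want[1] - got[1]) > tol:
                ok = False
                key = f"{call.chrom}:{call.start}-{call.end}"
                violations[key] = violations.get(key, 0) + 1
        if ok:
            valid.append(labels)
    return AssignmentResult(chromosome, placements, valid, len(valid) == 1,
                            violated=sorted(violations) if not valid else [])


def classify_rearrangement_homologues(name_a: str, name_b: str, chromosome: str,
                                      calls: list[SegmentCall],
                                      placements: list[Placement],
                                      tol: float = 0.3) -> str:
    """Verdict whether two derivatives carry the same chromosome homologue.

    Returns ``"same"``, ``"different"`` or ``"ambiguous"`` from the
    projections of every optimal homologue assignment.
    """
    chrom_placements = [p for p in placements if p.chrom == chromosome]
    idx_a = [i for i, p in enumerate(chrom_placements) if p.derivative == name_a]
    idx_b = [i for i, p in enumerate(chrom_placements) if p.derivative == name_b]
    if not idx_a or not idx_b:
        raise ValueError(
            f"chromosome {chromosome} absent from {name_a!r} or {name_b!r}")
    if name_a == name_b:
        return "same"
    result = solve_homologue_assignment(chromosome, calls, chrom_placements, tol)
    if not result.assignments:
        return "ambiguous"
    verdicts = set()
    for labels in result.assignments:
        la = {labels[i] for i in idx_a}
        lb = {labels[i] for i in idx_b}
        if len(la) == 1 and len(lb) == 1:
            verdicts.add("same" if la == lb else "different")
        else:
            verdicts.add("ambiguous")
    return verdicts.pop() if len(verdicts) == 1 else "ambiguous"
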