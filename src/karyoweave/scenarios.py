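"""Scenario generator: random rearranged cell populations with known truth,
plus the end-to-end U937 scenario, for parameter-recovery testing.

A scenario starts from a diploid complement, duplicates one designated
haploid complement (triploidisation, genotype-identical copies), applies
seeded random structural events, optionally adds clone-private deletions
(mosaicism) and one constructed centromere- or telomere-capture derivative,
then simulates the SNP-array track and the targeted-FISH evidence.  The full
truth — population, event log, per-region dosages and capture calls — is
returned alongside, so every inference stage can be scored against it.

Random events avoid centromere intervals (breakpoints and deleted material),
keeping every member viable; event sizes are log-uniform between 0.5 and
50 Mb.  Infeasible draws (or draws that would create an unintended
capture-like topology or a zero-copy region) are rejected and redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional

import numpy as np
import pandas as pd

from .arrays import assign_genotypes, make_probe_panel, simulate_array
from .assembly import (
    CaptureCall, MembershipEvidence, composition_from_derivative,
    detect_centromere_capture, detect_telomere_capture, evidence_from_fish,
)
from .fish import FishProbe
from .genome import GenomeMap, grch38_map
from .inference import SegmentCall
from .karyotype import (
    CellPopulation, Clone, DerivativeChromosome, Karyotype, RearrangementEvent,
    SegmentInterval, apply_event, normal_chromosome, validate_chromosome,
)

DEFAULT_CHROMOSOMES = ("19", "20", "21")


def spec_to_yaml(spec: "ScenarioSpec", path) -> None:
    """Write a scenario spec as YAML (round-trips via spec_from_yaml)."""
    import yaml

    payload = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in spec.__dict__.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def spec_from_yaml(path) -> "ScenarioSpec":
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    for key in ("chromosomes", "clone_fractions", "size_range_mb"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return ScenarioSpec(**payload)


@dataclass(frozen=True)
class ScenarioSpec:
    """Reproducible recipe for one synthetic rearranged population."""

    seed: int = 0
    chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES
    triploid: bool = True
    n_events: int = 6
    n_private_deletions: int = 2          # clone-2-only deletions (mosaicism)
    clone_fractions: tuple[float, ...] = (0.65, 0.35)
    event_weights: dict = field(default_factory=lambda: {
        "deletion": 0.4, "tandem-duplication": 0.25, "inverted-duplication": 0.1,
        "amplification": 0.1, "balanced-translocation": 0.15,
    })
    size_range_mb: tuple[float, float] = (0.5, 50.0)
    density_per_mb: float = 30.0
    sigma_baf: float = 0.03
    sigma_lrr: float = 0.15
    capture: Optional[str] = None         # None | "centromere" | "telomere"
    max_region_total: float = 8.0


@dataclass
class ScenarioTruth:
    population: CellPopulation
    events: list[RearrangementEvent]
    regions: pd.DataFrame
    captures: list[CaptureCall]


@dataclass
class Scenario:
    spec: ScenarioSpec
    genome: GenomeMap
    population: CellPopulation
    panel: pd.DataFrame
    track: pd.DataFrame
    probes: list[FishProbe]
    evidence: MembershipEvidence
    truth: ScenarioTruth


# ---------------------------------------------------------------------------
# event drawing
# ---------------------------------------------------------------------------

def _draw_interval(rng, genome: GenomeMap, seg: SegmentInterval,
                   size_range_mb) -> Optional[tuple[int, int]]:
    """An interval inside ``seg`` avoiding the centromere, or None."""
    lo_mb, hi_mb = size_range_mb
    size = int(np.exp(rng.uniform(np.log(lo_mb * 1e6), np.log(hi_mb * 1e6))))
    cs, ce = genome.centromere(seg.chrom)
    windows = []
    sub = genome.subtelomere
    a = max(seg.start, sub + 1)
    b = min(seg.end, cs - 1)
    if b - a + 1 > size:
        windows.append((a, b))
    a = max(seg.start, ce + 1)
    b = min(seg.end, genome.length(seg.chrom) - sub - 1)
    if b - a + 1 > size:
        windows.append((a, b))
    if not windows:
        return None
    a, b = windows[rng.integers(0, len(windows))]
    start = int(rng.integers(a, b - size + 1))
    return start, start + size - 1


def _draw_event(rng, genome: GenomeMap, kt: Karyotype, weights: dict,
                size_range=(0.5, 50.0)
                ) -> Optional[tuple[RearrangementEvent, Karyotype]]:
    kinds = sorted(weights)  # stable order regardless of dict construction
    probs = np.array([weights[k] for k in kinds], float)
    kind = kinds[rng.choice(len(kinds), p=probs / probs.sum())]

    if kind == "balanced-translocation":
        if len(kt.members) < 2:
            return None
        i, j = rng.choice(len(kt.members), size=2, replace=False)
        ma, mb = kt.members[i], kt.members[j]
        sa = ma.segments[rng.integers(0, len(ma.segments))]
        sb = mb.segments[rng.integers(0, len(mb.segments))]
        if sa.chrom == sb.chrom:
            return None
        iva = _draw_interval(rng, genome, sa, (1.0, 2.0))
        ivb = _draw_interval(rng, genome, sb, (1.0, 2.0))
        if iva is None or ivb is None:
            return None
        ev = RearrangementEvent("balanced-translocation",
                                chrom=sa.chrom, pos=iva[0], member=ma.name,
                                chrom2=sb.chrom, pos2=ivb[0], member2=mb.name)
        try:
            return ev, apply_event(kt, ev, genome)
        except Exception:
            return None

    member = kt.members[rng.integers(0, len(kt.members))]
    lengths = np.array([s.length for s in member.segments], float)
    seg = member.segments[rng.choice(len(member.segments), p=lengths / lengths.sum())]
    iv = _draw_interval(rng, genome, seg, size_range)
    if iv is None:
        return None
    count = int(rng.integers(2, 5)) if kind == "amplification" else 2
    ev = RearrangementEvent(kind, chrom=seg.chrom, start=iv[0], end=iv[1],
                            member=member.name, homologue=seg.homologue,
                            count=count)
    try:
        return ev, apply_event(kt, ev, genome)
    except Exception:
        return None


def _draw_private_deletion(rng, genome: GenomeMap, kt: Karyotype, size_range
                           ) -> Optional[tuple[RearrangementEvent, Karyotype]]:
    """A clone-private deletion removing exactly one copy of its interval.

    The interval must lie within a single segment of the target member with
    no other segment of that member overlapping it, so the resulting mosaic
    region differs from the shared state by exactly one copy (the simple
    subclonal-deletion structure the estimator targets)."""
    member = kt.members[rng.integers(0, len(kt.members))]
    lengths = np.array([s.length for s in member.segments], float)
    seg = member.segments[rng.choice(len(member.segments), p=lengths / lengths.sum())]
    iv = _draw_interval(rng, genome, seg, size_range)
    if iv is None:
        return None
    overlapping = [s for s in member.segments if s.chrom == seg.chrom
                   and s.overlap(iv[0], iv[1]) > 0]
    if len(overlapping) != 1:
        return None
    ev = RearrangementEvent("deletion", chrom=seg.chrom, start=iv[0], end=iv[1],
                            member=member.name, homologue=seg.homologue)
    try:
        return ev, apply_event(kt, ev, genome)
    except Exception:
        return None


def _capture_member(rng, genome: GenomeMap, kind: str,
                    chromosomes: tuple[str, ...]) -> DerivativeChromosome:
    """Construct one capture derivative with a detectable donor segment."""
    host, donor = rng.choice(len(chromosomes), size=2, replace=False)
    host, donor = chromosomes[host], chromosomes[donor]
    hcs, hce = genome.centromere(host)
    if kind == "centromere":
        # acentric host q-arm fragment rescued by a donor pericentromeric piece
        frag_start = hce + int(rng.integers(2_000_000, 5_000_000))
        frag = SegmentInterval(host, frag_start, genome.length(host), "h2", "+")
        dcs, dce = genome.centromere(donor)
        f1 = int(rng.integers(1_500_000, 2_500_000))
        f2 = int(rng.integers(1_500_000, 2_500_000))
        peri = SegmentInterval(donor, dcs - f1, dce + f2, "h2", "+")
        return DerivativeChromosome("mar(capture)", (peri, frag),
                                    telomere_assumed=(True, False))
    # telomere capture: broken host arm capped by a donor subtelomeric piece
    break_at = hce + int(rng.integers(14_000_000, 18_000_000))
    body = SegmentInterval(host, 1, break_at, "h2", "+")
    cap_len = int(rng.integers(1_500_000, 2_500_000))
    cap = SegmentInterval(donor, genome.length(donor) - cap_len + 1,
                          genome.length(donor), "h2", "+")
    return DerivativeChromosome("mar(capture)", (body, cap))


# ---------------------------------------------------------------------------
# truth computation
# ---------------------------------------------------------------------------

def truth_regions(pop: CellPopulation, genome: GenomeMap,
                  panel: Optional[pd.DataFrame] = None,
                  chromosomes: Optional[list[str]] = None) -> pd.DataFrame:
    """Exact per-region dosage truth from the population structure.

    Regions are delimited by every segment boundary in any cell state;
    consecutive regions with identical per-state dosage are merged.  Columns:
    ``chrom, start, end, cn_avg, n_major, n_minor, mosaic_fraction, states,
    n_probes``; ``states`` holds ((n1, n2), fraction) tuples and
    ``mosaic_fraction`` the fraction of the most frequent state when exactly
    two distinct states coexist.
    """
    states = pop.cell_states()
    chroms = chromosomes or sorted(
        {s.chrom for _, kt in states for m in kt.members for s in m.segments})
    rows = []
    for chrom in chroms:
        bounds: set[int] = set()
        for _, kt in states:
            for m in kt.members:
                for s in m.segments:
                    if s.chrom == chrom:
                        bounds.add(s.start)
                        bounds.add(s.end + 1)
        cuts = sorted(bounds)
        regions = []
        for a, b in zip(cuts[:-1], cuts[1:]):
            start, end = a, b - 1
            labels = sorted({s.homologue for _, kt in states for m in kt.members
                             for s in m.segments if s.chrom == chrom})
            per_state = []
            for f, kt in states:
                dose = tuple(int(round(kt.copies(chrom, start, end, lab)))
                             for lab in labels)
                per_state.append((dose, f))
            merged: dict[tuple, float] = {}
            for dose, f in per_state:
                merged[dose] = merged.get(dose, 0.0) + f
            state_t = tuple(sorted(merged.items(), key=lambda kv: -kv[1]))
            regions.append((start, end, state_t, labels))
        # merge equal-state neighbours
        out = []
        for start, end, state_t, labels in regions:
            if out and out[-1][2] == state_t and out[-1][1] + 1 == start:
                out[-1] = (out[-1][0], end, state_t, labels)
            else:
                out.append((start, end, state_t, labels))
        for start, end, state_t, labels in out:
            cn = sum(f * sum(d) for d, f in state_t)
            per_label = [sum(f * d[i] for d, f in state_t)
                         for i in range(len(labels))]
            per_label += [0.0] * (2 - len(per_label))
            per_label.sort(reverse=True)
            mosaic = state_t[0][1] if len(state_t) == 2 else float("nan")
            n_probes = 0
            if panel is not None:
                sel = (panel["chrom"] == chrom) & (panel["pos"] >= start) & \
                      (panel["pos"] <= end)
                n_probes = int(sel.sum())
            rows.append({
                "chrom": chrom, "start": start, "end": end, "cn_avg": cn,
                "n_major": per_label[0], "n_minor": per_label[1],
                "mosaic_fraction": mosaic, "states": state_t,
                "n_probes": n_probes,
            })
    return pd.DataFrame(rows)


def truth_captures(pop: CellPopulation,
                   genome: GenomeMap) -> list[CaptureCall]:
    """Capture calls implied by the population's own structure."""
    seen: dict[str, DerivativeChromosome] = {}
    for _, kt in pop.cell_states():
        for m in kt.members:
            seen.setdefault(m.name, m)
    calls: list[CaptureCall] = []
    for m in seen.values():
        comp = composition_from_derivative(m, genome)
        calls.extend(detect_centromere_capture(comp, genome))
        calls.extend(detect_telomere_capture(comp, genome))
    return calls


def _array_visible_composition(member: DerivativeChromosome,
                               genome: GenomeMap):
    """Unordered composition restricted to array-visible content (centromere
    intervals carry no probes), mirroring what the pipeline reconstructs."""
    from .assembly import DerivativeComposition, Placement

    segs = []
    cen: dict[str, int] = {}
    for s in member.segments:
        cs, ce = genome.centromere(s.chrom)
        if s.overlap(cs, ce) > 0:
            cen[s.chrom] = cen.get(s.chrom, 0) + 1
        for a, b in ((s.start, min(s.end, cs - 1)),
                     (max(s.start, ce + 1), s.end)):
            a2, b2 = max(a, s.start), min(b, s.end)
            if a2 <= b2 and not (a2 >= cs and b2 <= ce):
                segs.append(Placement(member.name, s.chrom, a2, b2, 1.0))
    return DerivativeComposition(member.name, segs, cen, ordered=False)


#: (strict, loose) detector thresholds used to reject borderline scenario
#: topologies: a member's capture status must be identical at both, so the
#: pipeline's share estimates (accurate to several percent, limited by FISH
#: probe spacing across array-invisible junctions) cannot flip it.
_MARGIN_THRESHOLDS = ((0.19, 0.10), (0.33, 0.22))


def _classification_unambiguous(pop: CellPopulation, genome: GenomeMap,
                                intended: Optional[tuple[str, str]]) -> bool:
    """True when every member's array-visible capture classification matches
    the intended truth at both strict and loose thresholds."""
    seen: dict[str, DerivativeChromosome] = {}
    for _, kt in pop.cell_states():
        for m in kt.members:
            seen.setdefault(m.name, m)
    for m in seen.values():
        comp = _array_visible_composition(m, genome)
        if not comp.segments:
            return False
        expected = {intended} if intended and intended[0] == m.name else set()
        for cen_share, telo_share in _MARGIN_THRESHOLDS:
            flags = {(m.name, c.kind) for c in
                     detect_centromere_capture(comp, genome,
                                               minority_share=cen_share)
                     + detect_telomere_capture(comp, genome,
                                               minority_share=telo_share)}
            if flags != expected:
                return False
    return True


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _base_karyotype(genome: GenomeMap, chromosomes, triploid: bool) -> Karyotype:
    members = []
    for chrom in chromosomes:
        members.append(normal_chromosome(chrom, genome, "h1", f"{chrom}.h1.1"))
        members.append(
            normal_chromosome(chrom, genome, "h2", f"{chrom}.h2.1", f"{chrom}~b"))
    kt = Karyotype("founder", tuple(members))
    if triploid:
        ev = RearrangementEvent("whole-genome-duplication",
                                complement=tuple(f"{c}~b" for c in chromosomes))
        kt = apply_event(kt, ev, genome)
    return kt


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Build a full scenario (population, array track, FISH evidence, truth)."""
    genome = grch38_map().subset(list(spec.chromosomes))
    for attempt in range(30):
        rng = np.random.default_rng((spec.seed, attempt))
        scenario = _generate_once(spec, genome, rng)
        if scenario is not None:
            return scenario
    raise RuntimeError(f"could not generate a valid scenario for seed {spec.seed}")


def _generate_once(spec: ScenarioSpec, genome: GenomeMap, rng) -> Optional[Scenario]:
    kt = _base_karyotype(genome, spec.chromosomes, spec.triploid)
    events: list[RearrangementEvent] = []
    guard = 0
    while len(events) < spec.n_events and guard < 200:
        guard += 1
        drawn = _draw_event(rng, genome, kt, spec.event_weights,
                            spec.size_range_mb)
        if drawn is None:
            continue
        ev, new_kt = drawn
        events.append(ev)
        kt = new_kt

    if spec.capture in ("centromere", "telomere"):
        kt = kt.add_member(_capture_member(rng, genome, spec.capture,
                                           spec.chromosomes))

    clones = [Karyotype("clone1", kt.members)]
    for ci, frac in enumerate(spec.clone_fractions[1:], start=2):
        ck = Karyotype(f"clone{ci}", kt.members)
        made = 0
        guard = 0
        while made < spec.n_private_deletions and guard < 100:
            guard += 1
            drawn = _draw_private_deletion(rng, genome, ck, spec.size_range_mb)
            if drawn is None:
                continue
            ev, ck = drawn
            events.append(dc_replace(ev, name=f"private:clone{ci}"))
            made += 1
        clones.append(ck)

    pop = CellPopulation(
        f"scenario seed={spec.seed}",
        tuple(Clone(k, f) for k, f in zip(clones, spec.clone_fractions)))

    # viability and copy-range checks; reject degenerate draws
    for member in kt.members:
        if not validate_chromosome(member, genome).is_viable:
            return None
    regions = truth_regions(pop, genome)
    if (regions["cn_avg"] < 0.999).any() or \
            (regions["cn_avg"] > spec.max_region_total).any():
        return None
    for _, r in regions.iterrows():
        if any(sum(d) == 0 for d, _ in r["states"]):
            return None

    captures = truth_captures(pop, genome)
    if spec.capture is None and captures:
        return None
    if spec.capture is not None:
        ours = [c for c in captures if c.derivative == "mar(capture)"
                and c.kind == spec.capture]
        if len(ours) != 1 or len(captures) != 1:
            return None
    intended = ("mar(capture)", spec.capture) if spec.capture else None
    if not _classification_unambiguous(pop, genome, intended):
        return None

    panel = make_probe_panel(genome, spec.density_per_mb, int(rng.integers(2**31)),
                             list(spec.chromosomes))
    genotypes = assign_genotypes(panel, pop, int(rng.integers(2**31)))
    track = simulate_array(pop, panel, genotypes, spec.sigma_baf, spec.sigma_lrr,
                           int(rng.integers(2**31)))
    regions = truth_regions(pop, genome, panel)

    probes = _region_probes(regions, genome)
    evidence = evidence_from_fish(probes, clones[0], genome=genome)
    truth = ScenarioTruth(pop, events, regions, captures)
    return Scenario(spec, genome, pop, panel, track, probes, evidence, truth)


_PROBE_SPACING = 3_000_000


def _region_probes(regions: pd.DataFrame, genome: GenomeMap) -> list[FishProbe]:
    """BAC-sized locus probes tiled ~3 Mb apart across every truth region
    (array segments alone cannot place material, and a single probe per
    region cannot resolve array-invisible junctions), plus centromere probes."""
    probes: list[FishProbe] = []
    for _, r in regions.iterrows():
        width = r["end"] - r["start"]
        if width < 2_000:
            continue
        n = max(1, int(width // _PROBE_SPACING))
        step = width / n
        for k in range(n):
            mid = int(r["start"] + (k + 0.5) * step)
            half = min(75_000, width // 2)
            probes.append(FishProbe(f"P{r['chrom']}:{mid}", "locus",
                                    r["chrom"], mid - half, mid + half))
    for chrom in genome.chromosomes:
        probes.append(FishProbe(f"CEN{chrom}", "centromere", chrom))
    return probes


# ---------------------------------------------------------------------------
# scoring against truth
# ---------------------------------------------------------------------------

def score_calls_against_truth(regions: pd.DataFrame, calls: list[SegmentCall],
                              min_probes: int = 20, cn_tol: float = 0.3,
                              dosage_tol: float = 0.3) -> pd.DataFrame:
    """Per-region recovery scores for a set of segment calls.

    For each truth region with at least ``min_probes`` probes the overlapping
    call with the largest overlap is compared: total copy number within
    ``cn_tol``, homologue dosage within ``dosage_tol``, and — for two-state
    (mosaic) regions — the absolute error of the recovered fraction of the
    majority state (a one-clone call counts as fraction 0 or 1).
    """
    rows = []
    for _, r in regions.iterrows():
        if r["n_probes"] < min_probes:
            continue
        best, best_ov = None, 0
        for call in calls:
            if call.chrom != r["chrom"] or call.selected is None:
                continue
            ov = min(call.end, r["end"]) - max(call.start, r["start"]) + 1
            if ov > best_ov:
                best, best_ov = call, ov
        if best is None:
            rows.append({"chrom": r["chrom"], "start": r["start"], "end": r["end"],
                         "covered": False, "cn_ok": False, "dosage_ok": False,
                         "mosaic_error": np.nan})
            continue
        cn_ok = abs(best.cn_total - r["cn_avg"]) <= cn_tol
        dosage_ok = (abs(best.n_major - r["n_major"]) <= dosage_tol and
                     abs(best.n_minor - r["n_minor"]) <= dosage_tol)
        mosaic_err = np.nan
        if len(r["states"]) == 2:
            mosaic_err = _mosaic_error(r["states"], best)
        rows.append({"chrom": r["chrom"], "start": r["start"], "end": r["end"],
                     "covered": True, "cn_ok": cn_ok, "dosage_ok": dosage_ok,
                     "mosaic_error": mosaic_err})
    return pd.DataFrame(rows)


def _mosaic_error(truth_states, call: SegmentCall) -> float:
    (t1, g1), (t2, _) = truth_states
    cfg = call.selected
    f_hat = call.mosaic.fraction if call.mosaic is not None else None
    est = [((a, b), f) for a, b, f in cfg.clones]
    for flip in (False, True):
        def norm(s):
            return (s[1], s[0]) if flip else s
        est_states = {norm(s): f for s, f in est}
        if set(est_states) == {tuple(t1), tuple(t2)} and f_hat is not None:
            # mosaic estimator profiles the first listed clone's fraction
            first = norm(est[0][0])
            return abs((f_hat if first == tuple(t1) else 1.0 - f_hat) - g1)
        if cfg.n_clones == 1 and set(est_states) <= {tuple(t1), tuple(t2)}:
            only = next(iter(est_states))
            return abs((1.0 if only == tuple(t1) else 0.0) - g1)
    return 0.5  # state mismatch: maximally uninformative recovery


def u937_scenario(mode: str = "nominal", sigma_baf: float = 0.03,
                  sigma_lrr: float = 0.15, seed: int = 0,
                  density_per_mb: float = 30.0,
                  chromosomes: Optional[list[str]] = None
                  ) -> Scenario:
    """End-to-end U937 scenario: fixture population, simulated array track,
    the published targeted-FISH probe panel, and full truth."""
    from .u937 import U937_FISH_PROBES, u937_fixture

    genome = grch38_map()
    pop = u937_fixture(mode, genome)
    rng = np.random.default_rng(seed)
    panel = make_probe_panel(genome, density_per_mb, int(rng.integers(2**31)),
                             chromosomes)
    genotypes = assign_genotypes(panel, pop, int(rng.integers(2**31)))
    track = simulate_array(pop, panel, genotypes, sigma_baf, sigma_lrr,
                           int(rng.integers(2**31)))
    from .fish import probe_from_dict

    probes = [probe_from_dict(d) for d in U937_FISH_PROBES]
    stem = pop.clones[0].karyotype
    evidence = evidence_from_fish(probes, stem, genome=genome)
    regions = truth_regions(pop, genome, panel,
                            chromosomes=chromosomes)
    captures = truth_captures(pop, genome)
    spec = ScenarioSpec(seed=seed, chromosomes=tuple(chromosomes or genome.chromosomes),
                        density_per_mb=density_per_mb, sigma_baf=sigma_baf,
                        sigma_lrr=sigma_lrr)
    truth = ScenarioTruth(pop, [], regions, captures)
    return Scenario(spec, genome, pop, panel, track, probes, evidence, truth)
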