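"""SNP-array synthesis: probe panels, founder genotypes, expected BAF/LRR,
and noisy track simulation for clone mixtures.

The B allele frequency (BAF) of a probe in a mixed cell population is the
intensity-pooled ratio

    BAF = (sum_c f_c * nB_c) / (sum_c f_c * (nA_c + nB_c))

over clones ``c`` with fractions ``f_c`` and allele copy counts
``(nA_c, nB_c)`` — copies are pooled across cells before the ratio is taken,
which is what the hybridisation assay measures.  The log R ratio (LRR) is
``log2(total copy number / baseline ploidy)`` with baseline 2: the array is
normalised against a diploid reference even for near-triploid genomes, which
is also how such karyotypes are conventionally written (gain/loss from
diploidy).

An :class:`ArrayTrack` is a plain pandas DataFrame with columns
``probe, chrom, pos, lrr, baf``; a probe panel is a DataFrame with columns
``probe, chrom, pos, popfreq``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import CoordinateError, GenomeMap, grch38_map
from .karyotype import CellPopulation

TRACK_COLUMNS = ["probe", "chrom", "pos", "lrr", "baf"]
PANEL_COLUMNS = ["probe", "chrom", "pos", "popfreq"]

#: Floor for the copy-number ratio inside the LRR logarithm (homozygous
#: deletions would otherwise be -inf).
LRR_EPS = 0.05


class UndefinedBAFError(ValueError):
    """BAF requested for a locus with zero total copy number."""


# ---------------------------------------------------------------------------
# allele-configuration arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleConfig:
    """Per-clone (nA, nB, fraction) hypotheses for one segment."""

    clones: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        total_f = sum(f for _, _, f in self.clones)
        if abs(total_f - 1.0) > 1e-9:
            raise ValueError(f"clone fractions sum to {total_f}, not 1")
        if any(a < 0 or b < 0 for a, b, _ in self.clones):
            raise ValueError("allele copy numbers must be >= 0")

    @property
    def mean_total(self) -> float:
        return sum(f * (a + b) for a, b, f in self.clones)


def expected_baf(config: AlleleConfig) -> float:
    """Intensity-pooled expected B allele frequency of a clone mixture."""
    num = sum(f * b for _, b, f in config.clones)
    den = sum(f * (a + b) for a, b, f in config.clones)
    if den <= 0:
        raise UndefinedBAFError("total copy number of the mixture is zero")
    return num / den


def expected_lrr(config: AlleleConfig, baseline_ploidy: int = 2,
                 eps: float = LRR_EPS) -> float:
    """Expected log R ratio: log2 of total copy number over baseline ploidy."""
    return float(np.log2(max(eps, config.mean_total) / baseline_ploidy))


def mixture_baf(n_b: float, n_total: float) -> float:
    if n_total <= 0:
        raise UndefinedBAFError("total copy number of the mixture is zero")
    return n_b / n_total


def baf_band_set(dosages: tuple[tuple[int, int, float], ...],
                 tol: float = 1e-9) -> list[float]:
    """Expected BAF bands for the four genotype classes of a segment state.

    ``dosages`` holds per-clone (copies of homologue 1, copies of homologue 2,
    fraction).  The classes are hom-A (both homologues A), hom-B, het with B
    on homologue 1, and het with B on homologue 2; bands are deduplicated
    within ``tol`` and returned sorted ascending (at most four values).
    """
    den = sum(f * (n1 + n2) for n1, n2, f in dosages)
    if den <= 0:
        raise UndefinedBAFError("total copy number of the mixture is zero")
    b1 = sum(f * n1 for n1, n2, f in dosages) / den
    b2 = sum(f * n2 for n1, n2, f in dosages) / den
    bands: list[float] = []
    for b in sorted((0.0, b1, b2, 1.0)):
        if not bands or b - bands[-1] > tol:
            bands.append(b)
    return bands


# ---------------------------------------------------------------------------
# probe panels and genotypes
# ---------------------------------------------------------------------------

def make_probe_panel(genome: GenomeMap, density_per_mb: float = 30.0,
                     seed: int = 0, chromosomes: list[str] | None = None,
                     exclude_centromeres: bool = True) -> pd.DataFrame:
    """Draw a reproducible SNP probe panel at the given density.

    Probe positions are uniform over each chromosome (centromere intervals
    excluded by default — arrays carry no probes in centromeric repeats) and
    population B-allele frequencies uniform on (0.05, 0.95).
    """
    if density_per_mb <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in (chromosomes or genome.chromosomes):
        n = int(round(density_per_mb * genome.length(chrom) / 1e6))
        pos = np.sort(rng.integers(1, genome.length(chrom) + 1, size=n))
        pos = np.unique(pos)
        if exclude_centromeres:
            cs, ce = genome.centromere(chrom)
            pos = pos[(pos < cs) | (pos > ce)]
        freq = rng.uniform(0.05, 0.95, size=pos.size)
        rows.append(pd.DataFrame({
            "probe": [f"{chrom}:{p}" for p in pos],
            "chrom": chrom, "pos": pos, "popfreq": freq,
        }))
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class FounderGenotypes:
    """B-allele indicators per (chromosome, homologue) genotype source.

    Founder copies created by whole-genome duplication share their homologue
    label and therefore their genotype, making duplicated complements
    genotype-identical by construction.
    """

    is_b: dict[tuple[str, str], np.ndarray]  # aligned to the panel's per-chrom rows

    def labels(self, chrom: str) -> list[str]:
        return sorted(h for c, h in self.is_b if c == chrom)


def assign_genotypes(panel: pd.DataFrame, pop: CellPopulation,
                     seed: int = 0) -> FounderGenotypes:
    """Draw founder genotypes per homologue at each panel probe."""
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], np.ndarray] = {}
    for chrom, sub in panel.groupby("chrom", sort=False):
        labels = sorted(pop.all_homologues(str(chrom)))
        freq = sub["popfreq"].to_numpy()
        for lab in labels:
            out[(str(chrom), lab)] = rng.random(freq.size) < freq
    return FounderGenotypes(out)


# ---------------------------------------------------------------------------
# dosage and track simulation
# ---------------------------------------------------------------------------

def _state_dosage(kt, chrom: str, positions: np.ndarray,
                  labels: list[str]) -> dict[str, np.ndarray]:
    """Copy number per homologue at each position for one karyotype."""
    dose = {lab: np.zeros(positions.size, dtype=np.int32) for lab in labels}
    for member in kt.members:
        for seg in member.segments:
            if seg.chrom != chrom:
                continue
            lo = np.searchsorted(positions, seg.start, side="left")
            hi = np.searchsorted(positions, seg.end, side="right")
            if hi > lo:
                dose[seg.homologue][lo:hi] += 1
    return dose


def population_dosage(pop: CellPopulation, chrom: str,
                      positions: np.ndarray) -> dict[str, np.ndarray]:
    """Population-average copies per homologue at each position."""
    labels = sorted(pop.all_homologues(chrom))
    avg = {lab: np.zeros(positions.size) for lab in labels}
    for f, kt in pop.cell_states():
        dose = _state_dosage(kt, chrom, positions, labels)
        for lab in labels:
            avg[lab] += f * dose[lab]
    return avg


def expected_track(pop: CellPopulation, panel: pd.DataFrame,
                   genotypes: FounderGenotypes, baseline_ploidy: int = 2,
                   eps: float = LRR_EPS) -> pd.DataFrame:
    """Noiseless expected LRR/BAF at every panel probe."""
    pieces = []
    for chrom, sub in panel.groupby("chrom", sort=False):
        chrom = str(chrom)
        positions = sub["pos"].to_numpy()
        avg = population_dosage(pop, chrom, positions)
        num = np.zeros(positions.size)
        den = np.zeros(positions.size)
        for lab, dose in avg.items():
            key = (chrom, lab)
            if key not in genotypes.is_b:
                raise CoordinateError(f"no genotypes for homologue {key}")
            num += dose * genotypes.is_b[key]
            den += dose
        with np.errstate(divide="ignore", invalid="ignore"):
            baf = np.where(den > 0, num / np.maximum(den, 1e-12), 0.5)
        lrr = np.log2(np.maximum(eps, den) / baseline_ploidy)
        pieces.append(pd.DataFrame({
            "probe": sub["probe"].to_numpy(), "chrom": chrom,
            "pos": positions, "lrr": lrr, "baf": baf,
        }))
    return pd.concat(pieces, ignore_index=True)


def simulate_array(pop: CellPopulation, panel: pd.DataFrame,
                   genotypes: FounderGenotypes, sigma_baf: float = 0.03,
                   sigma_lrr: float = 0.15, seed: int = 0,
                   baseline_ploidy: int = 2) -> pd.DataFrame:
    """Simulate a noisy array track: expectations plus independent Gaussian
    noise, BAF truncated to [0, 1].  Zero noise reproduces the expectations
    exactly."""
    if sigma_baf < 0 or sigma_lrr < 0:
        raise ValueError("noise standard deviations must be >= 0")
    track = expected_track(pop, panel, genotypes, baseline_ploidy)
    rng = np.random.default_rng(seed)
    n = len(track)
    if sigma_lrr > 0:
        track["lrr"] = track["lrr"] + rng.normal(0.0, sigma_lrr, n)
    if sigma_baf > 0:
        track["baf"] = np.clip(track["baf"] + rng.normal(0.0, sigma_baf, n), 0.0, 1.0)
    return track


def simulate_u937_track(mode: str = "nominal", density_per_mb: float = 30.0,
                        sigma_baf: float = 0.03, sigma_lrr: float = 0.15,
                        seed: int = 0, chromosomes: list[str] | None = None,
                        genome: GenomeMap | None = None
                        ) -> tuple[CellPopulation, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: fixture population, panel and simulated track."""
    from .u937 import u937_fixture

    g = genome or grch38_map()
    pop = u937_fixture(mode, g)
    panel = make_probe_panel(g, density_per_mb, seed, chromosomes)
    geno = assign_genotypes(panel, pop, seed + 1)
    track = simulate_array(pop, panel, geno, sigma_baf, sigma_lrr, seed + 2)
    return pop, panel, track
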