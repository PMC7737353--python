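"""Allele-configuration enumeration, mosaic-fraction estimation and
homologue-dosage calls per segment.

A segment state is described per clone by homologue copy counts (n1, n2).
Its observable signature is the BAF band set {0, beta, 1 - beta, 1} with

    beta = (sum_c f_c n2_c) / (sum_c f_c (n1_c + n2_c))

plus the mean LRR log2(total / 2).  The solver enumerates every one-clone
configuration up to a copy limit and every two-clone configuration over a
fraction grid, scores each against the observed bands and LRR, and ranks by
score with parsimony tie-breaks (fewer clones, then lower total copies, then
lexicographic).  The paper-style reasoning — "the band pattern trends toward
heterozygosity, so this segment comes from the majority homologue" — falls
out of the fitted per-homologue average dosages.

The score is a weighted symmetric Chamfer distance between observed and
predicted band sets: homozygous bands (near 0/1) carry reduced weight since
they are uninformative about dosage, and predicted bands unsupported by any
observed band are penalised so that a heterozygous configuration cannot
silently explain a loss-of-heterozygosity pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from dataclasses import replace as dc_replace
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd

from .arrays import LRR_EPS
from .segmentation import (
    BandSet, InsufficientDataError, bands_for_interval, extract_baf_bands,
    segment_tracks,
)


class NotApplicableError(ValueError):
    """Mosaic-fraction estimation requested for a one-clone model."""


@dataclass(frozen=True)
class InferenceParams:
    """Tunable limits and weights of the configuration solver."""

    max_total_copies: int = 12
    max_clones: int = 2
    fraction_step: float = 0.01
    lrr_weight: float = 1.0          # lambda on the squared LRR mismatch
    hom_band_weight: float = 0.25    # down-weight of bands near 0/1
    unmatched_weight: float = 0.25   # penalty weight per unsupported predicted band
    extra_clone_penalty: float = 5e-4  # parsimony margin a 2nd clone must beat
    non_nested_penalty: float = 5e-4   # clones should be related by gains/losses
    zero_state_penalty: float = 5e-4   # clone-wide homozygous loss is implausible
    state_distance_penalty: float = 5e-4  # per copy the two clone states differ, beyond 1
    score_tol: float = 1e-6          # tie window for ambiguity flagging
    min_band_separation: float = 0.08
    min_probes_bands: int = 10
    n_bootstrap: int = 200


DEFAULT_PARAMS = InferenceParams()


@dataclass(frozen=True)
class ScoredConfig:
    """One candidate configuration: clones are (n1, n2, fraction) with
    homologue-consistent labelling across clones."""

    clones: tuple[tuple[int, int, float], ...]
    score: float
    expected_bands: tuple[float, ...]
    expected_lrr: float

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def mean_total(self) -> float:
        return sum(f * (a + b) for a, b, f in self.clones)

    @property
    def mean_dosage(self) -> tuple[float, float]:
        return (sum(f * a for a, b, f in self.clones),
                sum(f * b for a, b, f in self.clones))


@dataclass(frozen=True)
class MosaicEstimate:
    fraction: float
    ci_low: float
    ci_high: float
    n_bootstrap: int


@dataclass
class SegmentCall:
    """Per-segment inference result."""

    chrom: str
    start: int
    end: int
    n_probes: int
    mean_lrr: float
    bands: Optional[BandSet]
    candidates: list[ScoredConfig] = field(default_factory=list)
    selected: Optional[ScoredConfig] = None
    ambiguous: bool = False
    n_major: float = float("nan")
    n_minor: float = float("nan")
    dosage_ambiguous: bool = False
    mosaic: Optional[MosaicEstimate] = None

    @property
    def cn_total(self) -> float:
        return self.selected.mean_total if self.selected else float("nan")


# ---------------------------------------------------------------------------
# configuration table (cached) and scoring
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _config_table(max_total: int, fraction_step: float
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All canonical configurations as flat arrays.

    Returns (states, fractions, n_clones, nested) where states has columns
    (a1, b1, a2, b2); single-clone rows repeat the clone with fraction 1.
    Canonical forms remove clone-order and homologue-label-swap duplicates.
    ``nested`` marks two-clone pairs related componentwise (one state
    reachable from the other by pure gains or pure losses, as expected for
    clones related by descent).
    """
    single = [(a, b) for a in range(max_total + 1) for b in range(a + 1)
              if 1 <= a + b <= max_total]
    rows = [(a, b, a, b) for a, b in single]
    fracs = [1.0] * len(rows)
    nclones = [1] * len(rows)

    states = [(a, b) for a in range(max_total + 1) for b in range(max_total + 1)
              if a + b <= max_total]
    fgrid = np.round(np.arange(fraction_step, 1.0 - fraction_step / 2, fraction_step), 10)
    pair_rows = []
    for i, s1 in enumerate(states):
        for s2 in states[:i]:  # s1 > s2 lexicographically
            a1, b1 = s1
            a2, b2 = s2
            # homologue-label swap canonicalisation
            sw = tuple(sorted(((b1, a1), (b2, a2)), reverse=True))
            if ((a1, b1), (a2, b2)) < sw:
                continue
            pair_rows.append((a1, b1, a2, b2))
    nested = [True] * len(rows)
    for a1, b1, a2, b2 in pair_rows:
        is_nested = (a1 >= a2 and b1 >= b2) or (a1 <= a2 and b1 <= b2)
        for f in fgrid:
            rows.append((a1, b1, a2, b2))
            fracs.append(float(f))
            nclones.append(2)
            nested.append(is_nested)
    return (np.array(rows, dtype=np.int16), np.array(fracs),
            np.array(nclones, dtype=np.int8), np.array(nested, dtype=bool))


def _score_arrays(states: np.ndarray, fracs: np.ndarray, obs_centers: np.ndarray,
                  obs_weights: np.ndarray, mean_lrr: float,
                  params: InferenceParams,
                  nclones: np.ndarray | None = None,
                  nested: np.ndarray | None = None) -> np.ndarray:
    a1 = states[:, 0].astype(float)
    b1 = states[:, 1].astype(float)
    a2 = states[:, 2].astype(float)
    b2 = states[:, 3].astype(float)
    f = fracs
    den = f * (a1 + b1) + (1 - f) * (a2 + b2)
    ok = den > 0

    # The band score is bounded by 2, so configurations whose LRR term alone
    # exceeds the minimum LRR term by more than 2 can never rank first; skip
    # their (expensive) band scoring.
    lrr = np.log2(np.maximum(LRR_EPS, den) / 2.0)
    lrr_term = params.lrr_weight * (lrr - mean_lrr) ** 2
    scores = np.full(den.size, np.inf)
    active = ok & (lrr_term <= lrr_term[ok].min() + 2.0 + params.score_tol)
    idx = np.flatnonzero(active)

    beta = (f[idx] * b1[idx] + (1 - f[idx]) * b2[idx]) / den[idx]
    pred = np.stack([np.zeros_like(beta), beta, 1.0 - beta, np.ones_like(beta)], axis=1)
    # observed -> predicted
    w = np.where((obs_centers <= 0.08) | (obs_centers >= 0.92),
                 obs_weights * params.hom_band_weight, obs_weights)
    d = np.abs(pred[:, :, None] - obs_centers[None, None, :])
    band = (w[None, :] * d.min(axis=1) ** 2).sum(axis=1)
    # predicted -> observed (unsupported predicted bands)
    pw = np.where((pred <= 0.08) | (pred >= 0.92),
                  params.unmatched_weight * params.hom_band_weight,
                  params.unmatched_weight)
    band += (pw * d.min(axis=2) ** 2).sum(axis=1)
    scores[idx] = band + lrr_term[idx]
    if nclones is not None:
        # parsimony: an extra clone must improve the fit by more than this
        # margin, generalising the exact-tie "fewer clones" rule to noisy data
        scores = scores + params.extra_clone_penalty * (nclones - 1)
    if nested is not None:
        scores = scores + params.non_nested_penalty * (~nested)
    if nclones is not None:
        # a clone carrying zero copies of a multi-megabase segment would be a
        # clone-wide homozygous deletion; prior against it
        zero2 = (nclones == 2) & (states[:, 2] == 0) & (states[:, 3] == 0)
        scores = scores + params.zero_state_penalty * zero2
        # clones related by descent differ by few copy changes per segment
        l1 = (np.abs(states[:, 0] - states[:, 2])
              + np.abs(states[:, 1] - states[:, 3])).astype(float)
        scores = scores + params.state_distance_penalty * \
            np.where(nclones == 2, np.maximum(l1 - 1.0, 0.0), 0.0)
    return scores


def enumerate_configs(bands: BandSet, mean_lrr: float,
                      params: InferenceParams = DEFAULT_PARAMS) -> list[ScoredConfig]:
    """Rank all allele configurations against observed bands and LRR.

    Returns candidates sorted by (score, clone count, mean total copies,
    lexicographic clones); all configurations scoring within ``score_tol`` of
    the best are returned (more than one distinct signature marks the call
    ambiguous downstream), followed by the next few runners-up for context.
    """
    if params.max_total_copies < 1 or params.max_clones < 1:
        raise ValueError("copy/clone limits must be >= 1")
    if len(bands) == 0:
        raise ValueError("bands must be non-empty")
    states, fracs, nclones, nested = _config_table(params.max_total_copies,
                                                   params.fraction_step)
    if params.max_clones < 2:
        keep = nclones == 1
        states, fracs, nclones, nested = (states[keep], fracs[keep],
                                          nclones[keep], nested[keep])
    obs_c = np.asarray(bands.centers)
    obs_w = np.asarray(bands.weights)
    scores = _score_arrays(states, fracs, obs_c, obs_w, mean_lrr, params,
                           nclones, nested)

    best = float(np.min(scores))
    within = np.flatnonzero(scores <= best + params.score_tol)
    k = min(25, scores.size - 1)
    runners = np.argpartition(scores, k)[: k + 1]
    idx = np.unique(np.concatenate([within, runners]))

    def make(i: int) -> ScoredConfig:
        a1, b1, a2, b2 = (int(x) for x in states[i])
        f = float(fracs[i])
        if nclones[i] == 1:
            clones = ((a1, b1, 1.0),)
        else:
            clones = ((a1, b1, f), (a2, b2, 1.0 - f))
        den = sum(fr * (a + b) for a, b, fr in clones)
        beta = sum(fr * b for a, b, fr in clones) / den
        pred = tuple(sorted({0.0, round(beta, 12), round(1 - beta, 12), 1.0}))
        lrr = float(np.log2(max(LRR_EPS, den) / 2.0))
        return ScoredConfig(clones, float(scores[i]), pred, lrr)

    def sort_key(c: ScoredConfig):
        return (round(c.score, 12), c.n_clones,
                sum(a + b for a, b, _ in c.clones), c.clones)

    cands = sorted({make(int(i)).clones: make(int(i)) for i in idx}.values(), key=sort_key)
    return cands


def select_config(candidates: list[ScoredConfig],
                  params: InferenceParams = DEFAULT_PARAMS
                  ) -> tuple[ScoredConfig, bool]:
    """First candidate plus an ambiguity flag (distinct signatures tied)."""
    best = candidates[0]
    tied = [c for c in candidates[1:] if c.score <= best.score + params.score_tol]
    ambiguous = any(c.expected_bands != best.expected_bands
                    or abs(c.mean_total - best.mean_total) > 1e-9 for c in tied)
    return best, ambiguous


def infer_homologue_dosage(config: ScoredConfig) -> tuple[float, float, bool]:
    """Population-average copies of the more/less represented homologue.

    Returns (n_major, n_minor, ambiguous); ambiguous marks a balanced
    configuration whose homologues cannot be told apart.
    """
    d1, d2 = config.mean_dosage
    major, minor = (d1, d2) if d1 >= d2 else (d2, d1)
    return major, minor, abs(d1 - d2) < 1e-9


# ---------------------------------------------------------------------------
# mosaic-fraction estimation
# ---------------------------------------------------------------------------

def _band_objective(f: np.ndarray, s1: tuple[int, int], s2: tuple[int, int],
                    obs_c: np.ndarray, obs_w: np.ndarray,
                    params: InferenceParams) -> np.ndarray:
    a1, b1 = s1
    a2, b2 = s2
    den = f * (a1 + b1) + (1 - f) * (a2 + b2)
    beta = (f * b1 + (1 - f) * b2) / np.maximum(den, 1e-12)
    pred = np.stack([np.zeros_like(beta), beta, 1 - beta, np.ones_like(beta)], axis=1)
    w = np.where((obs_c <= 0.08) | (obs_c >= 0.92),
                 obs_w * params.hom_band_weight, obs_w)
    d = np.abs(pred[:, :, None] - obs_c[None, None, :])
    score = (w[None, :] * d.min(axis=1) ** 2).sum(axis=1)
    pw = np.where((pred <= 0.08) | (pred >= 0.92),
                  params.unmatched_weight * params.hom_band_weight,
                  params.unmatched_weight)
    score += (pw * d.min(axis=2) ** 2).sum(axis=1)
    return score


def estimate_mosaic_fraction(baf_values: np.ndarray, config: ScoredConfig,
                             params: InferenceParams = DEFAULT_PARAMS,
                             seed: int = 0,
                             lrr_values: Optional[np.ndarray] = None
                             ) -> MosaicEstimate:
    """Profile the first-clone fraction of a two-clone configuration.

    The fraction is scanned on a 0-1 grid (step ``fraction_step``) minimising
    the band score of the re-extracted observed bands plus — when LRR values
    are supplied — the squared mean-LRR mismatch.  The LRR term is essential
    for mosaics of homozygous states (e.g. one vs two copies of the same
    homologue), whose BAF bands are {0, 1} at every fraction; the confidence
    interval is a percentile bootstrap over probes.
    """
    if config.n_clones < 2:
        raise NotApplicableError("mosaic fraction undefined for a one-clone model")
    s1 = config.clones[0][:2]
    s2 = config.clones[1][:2]
    grid = np.round(np.arange(0.0, 1.0 + params.fraction_step / 2,
                              params.fraction_step), 10)
    total = grid * sum(s1) + (1 - grid) * sum(s2)
    pred_lrr = np.log2(np.maximum(LRR_EPS, total) / 2.0)

    def fit(values: np.ndarray, lrr: Optional[np.ndarray]) -> float:
        bands = extract_baf_bands(values,
                                  min_separation=params.min_band_separation)
        obj = _band_objective(grid, s1, s2, np.asarray(bands.centers),
                              np.asarray(bands.weights), params)
        if lrr is not None and lrr.size:
            obj = obj + params.lrr_weight * (pred_lrr - float(np.mean(lrr))) ** 2
        return float(grid[int(np.argmin(obj))])

    v = np.asarray(baf_values, float)
    keep = np.isfinite(v)
    v = v[keep]
    lv = None
    if lrr_values is not None:
        lv = np.asarray(lrr_values, float)[keep]
    f_hat = fit(v, lv)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(params.n_bootstrap):
        idx = rng.integers(0, v.size, v.size)
        boots.append(fit(v[idx], lv[idx] if lv is not None else None))
    boots = np.array(boots) if boots else np.array([f_hat])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return MosaicEstimate(f_hat, float(lo), float(hi), params.n_bootstrap)


# ---------------------------------------------------------------------------
# full per-segment calling
# ---------------------------------------------------------------------------

def call_segments(track: pd.DataFrame, params: InferenceParams = DEFAULT_PARAMS,
                  min_size: int = 20, penalty: float = 30.0,
                  seed: int = 0, bootstrap: bool = True) -> list[SegmentCall]:
    """Segment a track and infer the allele configuration of every segment."""
    segs = segment_tracks(track, min_size=min_size, penalty=penalty)
    calls: list[SegmentCall] = []
    for row in segs.itertuples():
        sub = track.iloc[row.i0:row.i1]
        call = SegmentCall(row.chrom, row.start, row.end, row.n_probes,
                           float(sub["lrr"].mean()), None)
        try:
            call.bands = extract_baf_bands(
                sub["baf"].to_numpy(),
                min_separation=params.min_band_separation)
        except InsufficientDataError:
            calls.append(call)
            continue
        call.candidates = enumerate_configs(call.bands, call.mean_lrr, params)
        call.selected, call.ambiguous = select_config(call.candidates, params)
        call.n_major, call.n_minor, call.dosage_ambiguous = \
            infer_homologue_dosage(call.selected)
        if call.selected.n_clones == 2 and call.selected.clones[0][:2] != \
                call.selected.clones[1][:2]:
            p = params if bootstrap else dc_replace(params, n_bootstrap=0)
            call.mosaic = estimate_mosaic_fraction(
                sub["baf"].to_numpy(), call.selected, p, seed=seed,
                lrr_values=sub["lrr"].to_numpy())
        calls.append(call)
    return calls
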