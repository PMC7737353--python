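# Methods

## Model

A genome is a multiset of derivative chromosomes; each derivative is an
ordered list of oriented reference segments tagged with the parental
homologue (two opaque labels per chromosome, "blue"/"green" in the fixture)
and a founder-copy identifier. Whole-genome duplication ("triploidisation")
copies one designated haploid complement; the copies carry distinct founder
identifiers but resolve to the same genotype source (chromosome +
homologue), so duplicated material is genotype-identical — the property that
makes near-triploid BAF patterns informative about homologue history.

A cell population is a mixture of clones (karyotype + fraction, fractions
summing to 1) plus optional cross-cutting sub-mosaic events: an aberration
present in a stated fraction of cells independent of the clone structure,
modelled as a member replacement. Expectations are computed by expanding
clones × sub-mosaic states into weighted karyotypes.

### Observables

For a locus with per-state homologue dosages `(n1, n2)` the array reports,
pooled over cells before the ratio is taken (which is what hybridisation
intensity does),

    BAF  = Σ f·nB / Σ f·(nA + nB)
    LRR  = log2(max(ε, Σ f·N) / 2),  ε = 0.05

The LRR baseline is diploid even for near-triploid genomes: arrays are
normalised against diploid references, and such karyotypes are conventionally
written as gains/losses from diploidy. The BAF band set of a segment state
is {0, β, 1−β, 1} with β the mixture value for hets carrying B on one
homologue; bands are orientation- and order-insensitive (segments contribute
dosage only). Simulated tracks add independent Gaussian noise (defaults
σ_BAF = 0.03, σ_LRR = 0.15; BAF truncated to [0, 1], truncation rather than
re-draw) to the closed-form expectations at probes drawn uniformly at
30 probes/Mb outside centromere intervals (population B-allele frequencies
uniform on 0.05–0.95). Zero-copy loci report BAF 0.5 by convention.

### Viability and capture

A transmissible chromosome needs two telomeres and at least one active
centromere. An end is telomere-bearing when its terminal segment's
outward-facing genomic end reaches within the subtelomere window (default
500 kb) of its source chromosome, or when an end is explicitly annotated as
assumed-capped (several real derivatives lack array-visible subtelomeres but
are clearly transmitted). Verdicts: `acentric` (no active centromere),
`unterminated` (a bare end), `dicentric-viable` (≥ 2 physical centromeres,
≥ 1 active — pseudodicentrics are flagged, not rejected), else `viable`.

**Centromere capture** is flagged on a composition when every centromere
present originates from chromosomes each contributing less than 25%
(configurable) of the derivative's copy-weighted length, while the majority
content's own centromere is absent. The reported donor segment is the
donor-chromosome content within ±3 Mb of its centromere interval.

**Telomere capture** is flagged for a content segment reaching a subtelomere
of its source chromosome when that chromosome (i) contributes < 15% of the
derivative, (ii) is not the majority content, (iii) supplies no centromere,
(iv) forms its chromosome's only contiguous content block on the derivative
(gap tolerance 3 Mb), and (v), when physical order is known, sits terminally
next to foreign content. Conditions (i)–(iv) were added to the naive
"foreign subtelomeric segment" rule because large native arms and
same-chromosome runs otherwise masquerade as caps; the thresholds separate
the real capture (a 10 Mb 6q cap on an ~87 Mb chromosome-7 body, ~10%) from
ordinary translocation products (arm shares ≥ 20%).

## Inference

1. **Segmentation.** Recursive binary changepoint search on three per-probe
   channels — LRR, folded BAF (|BAF−0.5| of probes in the 0.15–0.85
   heterozygous range) and a heterozygous-probe indicator (carrying the LOH
   signal) — each standardised by a robust noise scale from successive
   differences. A split is accepted when the joint SSE reduction exceeds a
   fixed penalty (30; true copy steps contribute gains ≥ 100 even at 20
   probes, spurious maxima stay well below). Greedy splitting misses short
   interior dips, so converged segments are scanned for paired splits
   (windows from the minimum size upward in ×1.2 steps); finally each
   boundary is re-positioned to its local SSE optimum. Minimum segment size
   20 probes. Integer-copy boundaries localise to probe resolution; a
   boundary separating average copies 3.5 from 3.7 (a 0.08 LRR step) is
   information-limited to tens of probes — a property of the data, not of
   the search.

2. **Band extraction.** 1-D mode clustering of BAF values: a 0.002-bin
   histogram smoothed with a Gaussian kernel (σ = 0.012) seeds modes; values
   are assigned to the nearest mode, centers refined as weighted means, and
   centers closer than 0.08 merged; at most 6 bands, weights = probe shares.
   Requires ≥ 10 probes.

3. **Configuration enumeration.** All one-clone states (n1, n2) with total ≤
   12 (covering the averaged amplicon) and all canonical two-clone state
   pairs over a 0.01 fraction grid are scored against the observed bands and
   mean LRR:

       score = Σ_obs w'·min_pred d² + 0.25·Σ_pred w''·min_obs d²
               + 1.0·(LRR_pred − LRR_obs)² + priors

   Homozygous bands (within 0.08 of 0/1) carry ×0.25 weight (uninformative
   about dosage); the predicted→observed term stops a heterozygous
   configuration from silently explaining an LOH pattern. Four small fixed
   priors (5·10⁻⁴ each, the scale of band-noise SSE) encode clonal descent
   and break otherwise exact observational degeneracies: per extra clone,
   per non-nested state pair, per zero-copy clone state (a clone-wide
   homozygous deletion of a multi-Mb segment is implausible), and per L1
   copy difference between clone states beyond one. Without them, pairs such
   as {(3,0),(0,2)} or {(4,2),(1,0)} reproduce the {0, 0.25, 0.75, 1} /
   CN 2.67 signature of a simple one-copy mosaic deletion exactly. Ties
   within 10⁻⁶ are flagged ambiguous; ranking breaks ties by fewer clones,
   lower totals, then lexicographically.

4. **Mosaic fraction.** For a selected two-clone configuration the
   first-clone fraction is profiled on the 0.01 grid minimising the band
   score of re-extracted bands plus the squared mean-LRR mismatch. The LRR
   term is required: mosaics of homozygous states (e.g. (0,2) vs (0,1)) have
   BAF bands {0, 1} at every fraction, so a band-only objective is flat.
   Confidence intervals are percentile bootstrap over probes (200 resamples,
   seeded).

5. **Homologue dosage.** Population-average copies of the more/less
   represented homologue, directly from the selected configuration (may be
   fractional, e.g. 2 and 1.5); balanced configurations are flagged
   ambiguous.

6. **Composition.** Locus-FISH probes vote with integer copy-equivalents
   (one "+" per copy on the normal chromosome; partial coverage ≥ 10% of the
   probe renders "(+)"; tandem copies within 2 Mb merge into one multi-copy
   signal). Call intervals are split at midpoints between probes — balanced
   junctions are array-invisible, so per-call voting would credit whole
   calls to one derivative — clipped to array-visible space, and copies are
   distributed proportionally, capped by the inferred total; the remainder
   goes to an explicit "unplaced" bucket and FISH/array excesses produce
   structured conflict reports, never exceptions. Composition is
   multiset-level: array + locus FISH cannot order segments, so order is
   used only where known.

7. **Homologue assignment.** Exhaustive labelling of a chromosome's
   placements with the two homologues, keeping assignments whose per-label
   dosage sums match each segment call's (n_major, n_minor) within 0.3; the
   global label swap is fixed by the first placement. A unique survivor
   yields same/different verdicts for derivative pairs; multiple optima
   yield "ambiguous"; none yields an inconsistency report.

## Synthetic scenarios

The generator emulates the study's cell-culture situation: a diploid
complement, triploidisation of one haploid complement, 6 seeded random
events (deletions, tandem/inverted duplications, amplifications ≤ 4 copies,
balanced translocations; sizes log-uniform 0.5–50 Mb; breakpoints avoid
centromeres and subtelomere windows), two clones (0.65/0.35) with two
clone-private one-copy deletions providing mosaicism, and optionally one
constructed capture derivative (pericentromeric donor with 1.5–2.5 Mb
flanks, or a 1.5–2.5 Mb subtelomeric cap on a broken arm — always ≥ 1 Mb
and ≥ 20 probes of array-visible donor material). Default scenarios use a
three-chromosome subset (19, 20, 21; ~170 Mb) — enough structure for every
inference stage while keeping hundred-scenario sweeps cheap. Draws are
rejected and redrawn when an event is infeasible, a region would reach zero
copies in some state, a member would be inviable, or — critically — when a
member's array-visible capture classification is not stable between strict
and loose detector thresholds ((cen, telo) = (0.19, 0.10) and (0.33, 0.22)):
borderline shares that the pipeline's few-percent localisation error could
flip are excluded from both classes, in the same spirit as restricting
scored capture events to detectable donors. FISH evidence tiles BAC-sized
locus probes ~3 Mb apart across truth regions plus one centromere probe per
chromosome, read from the largest clone's metaphases.

Clone-private deletions remove exactly one copy (the interval must lie in a
single member segment): mosaic regions then differ from the shared state by
one copy, matching the simple subclonal-deletion structure the estimator
targets; truth regions are recorded exactly from the population structure
(regions with identical state multisets merged, so balanced exchanges are
correctly invisible).

What the generator does *not* emulate: platform wave/GC artefacts, probe
drop-out, cluster-file miscalibration, signal noise in FISH copy counts
(metaphase-to-metaphase variance is unreported in the source material and is
not guessed), >2-clone segment states, and gene conversion. Passing recovery
tests therefore demonstrate correctness of the inference machinery under the
stated noise model, not robustness to platform artefacts.

## The U937 fixture

Three clones (62, 63 and 60 chromosomes; nominal fractions 0.30/0.50/0.20,
observed-count mode 21/71, 37/71, 13/71) encode the published karyotype with
homologue tags: the duplicated-homologue structure, the
der(11)t(11;16;20) carrying a 6.0 Mb chromosome-11 pericentromeric segment
(centromere capture) and a 1.7–2.0 Mb 11q24 segment whose boundary
uncertainty intervals are encoded verbatim, the der(20)t(15;20) with one- to
four-copy 20p11.21 blocks (one inverted, mirroring the inverted repeat) and
a broken long-arm end, two normal chromosomes 20 of a single homologue (the
20q12 common deleted region at two copies with LOH), the chromosome 6
derivative family (ten-copy amplicon on the 50%-mosaic der(6)del(6)dup(6);
the source material states both "about eight" and "approximately ten" copies
— the encoded ten is the only value consistent with the 2:6 population-
average dosage arithmetic, and both readings are noted here), the
der(7)t(6;7) capped by blue-homologue 6q material (telomere capture), and
the two overlapping 5q11.2 deletions of the der(5)t(5;13) — the larger as a
cross-cutting sub-mosaic in exactly one third of cells, which reproduces the
0.25/0.75 band quartet analytically (the published "30%/70%" rounds this).
Published probe coordinates are exact; band-level breakpoints are round
numbers inside the stated band, constrained to reproduce the published FISH
symbol table for every chromosome-20-target probe. Segment order inside the
der(20) short arm follows the published footnote where stated and insertion
order elsewhere. It was not determined in the source which clones carry the
5q11.2 deletions; the cross-cutting encoding is a modelling choice, not
ground truth, and the homologue history of chromosome 20 is deliberately
left unannotated.

## Numerical choices and limitations

- Coordinates 1-based inclusive internally; BED export converts to 0-based
  half-open. The bundled map carries GRCh38 lengths and coarse centromere
  intervals; acrocentric short arms are treated as telomere-bearing.
- Fraction grid 0.01 everywhere; segmentation penalty 30; band separation
  0.08; score tie window 10⁻⁶; priors 5·10⁻⁴; capture shares 25%/15%;
  reduced-signal threshold 10%; signal merge distance 2 Mb. All are
  configurable parameters with these defaults.
- Mixtures of nested states whose population averages are integral (e.g.
  50% of {(2,7),(2,1)}) are observationally identical to a single clone and
  are reported as such — a known identifiability limit of pooled array
  signal, resolved in practice only by single-cell methods.
- The solver handles at most two clones per segment (the study never needs
  more); three-state regions are approximated by the best two-clone mixture,
  which preserves total copy number and average homologue dosage.
- Mosaic-fraction accuracy at default noise is ~±0.01–0.03 (grid-limited
  plus band-position noise) for band-informative states and ~±0.02–0.04 for
  LRR-only (homozygous) states with ≥ 30 probes.
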