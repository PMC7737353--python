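# karyoweave

Reconstruction of complex cancer karyotypes from SNP-array tracks and
targeted FISH evidence — with a fully synthetic test bed and an encoded
fixture of the U937 myeloid cell line.

## The problem

Cancer cell lines and tumours carry derivative chromosomes stitched together
from pieces of several normal chromosomes. SNP arrays say *what* is gained or
lost — per-probe **log R ratio** (LRR, total intensity, `log2(n/2)` for copy
number *n*) and **B allele frequency** (BAF, the fraction of signal from the
"B" allele) — but not *where* the material sits. Metaphase FISH localises
targeted segments onto specific abnormal chromosomes. Combining the two
reconstructs each derivative, tracks which parental homologue every piece
came from, and reveals two rescue mechanisms of broken chromosomes:
**centromere capture** (acentric fragments preserved by joining to a small
segment carrying another chromosome's centromere) and **telomere capture**
(a broken end capped by another chromosome's subtelomeric segment).

For a mixture of clones with fractions `f_c` and per-clone allele copy
numbers `(nA_c, nB_c)` over a segment, the package models the observables as

```
BAF = Σ_c f_c·nB_c / Σ_c f_c·(nA_c + nB_c)        LRR = log2(Σ_c f_c·N_c / 2)
```

so a three-copy segment whose single-copy homologue is deleted in one third
of cells produces heterozygous BAF bands at exactly 0.25 and 0.75, a
half-mosaic derivative yields "three-and-a-half copies", and a 2:6 homologue
ratio over an amplicon implies ten copies on a 50%-mosaic derivative.

The analytical core inverts these relationships: changepoint segmentation of
LRR + folded BAF, band extraction, exhaustive enumeration of one- and
two-clone allele configurations, mosaic-fraction profiling with bootstrap
CIs, homologue-dosage calls, FISH-guided composition of derivatives, and
rule-based centromere/telomere-capture detection.

## Layout

- `src/karyoweave/` — the library: genome map, homologue-tagged karyotype
  model and rearrangement events, U937 fixture, array and FISH simulators,
  segmentation/inference, assembly and capture detection, scenario
  generator, CLI (`karyoweave`).
- `analysis/` — numbered narrative drivers (fixture anatomy, simulate+call,
  assembly, parameter recovery) writing tables under `results/`.
- `tests/` — the pytest suite, including `tests/test_acceptance.py`.
- `scripts/acceptance.py` — recomputes the headline numbers (below).

## Worked example

```python
from karyoweave import call_segments, u937_fixture
from karyoweave.scenarios import u937_scenario

sc = u937_scenario(seed=1, chromosomes=["6"])       # simulate chr6 at default noise
for c in call_segments(sc.track, seed=1, bootstrap=False):
    print(f"{c.chrom}:{c.start/1e6:6.1f}-{c.end/1e6:6.1f}  "
          f"CN={c.cn_total:4.2f}  dosage=({c.n_major:.2f},{c.n_minor:.2f})")
```

prints the six-state chromosome-6 profile recovered from noisy data:

```
6:   0.0-  24.9  CN=2.00  dosage=(1.00,1.00)
6:  25.1-  30.0  CN=3.00  dosage=(2.00,1.00)
6:  30.1-  33.0  CN=8.00  dosage=(6.00,2.00)
6:  33.0-  48.1  CN=4.00  dosage=(2.00,2.00)
6:  48.2- 160.6  CN=3.51  dosage=(2.00,1.51)
6: 160.6- 170.7  CN=3.69  dosage=(2.23,1.46)
```

— two normal copies distally on 6p, a three-copy state, the 6p21.3 amplicon
averaging eight copies with 6:2 homologue dosage, the four-copy duplicated
block, the "three-and-a-half copies" half-mosaic long arm, and the 6q26→qter
gain. `analysis/03_assemble_derivatives.py` then reports:

```
centromere capture on der(11)t(11;16;20): donor chr11, 6.0 Mb
telomere capture on der(7)t(6;7): donor chr6, 10.2 Mb
```

The command-line demo produces the same artefacts:
`karyoweave u937-demo --out-dir u937_out`.

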