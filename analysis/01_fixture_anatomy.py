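#!/usr/bin/env python
"""Fixture anatomy: clone structure, key copy-number regions, FISH tables.

Writes results/fixture_summary.txt, results/fish_table_chr20.tsv and
results/karyotype.json.  Headline findings printed: the stemline has 62
chromosomes; the 20q12 common deleted region sits at two copies of a single
homologue; the 20p11.21 RP11-500O11 region reaches four copies on the
der(20)t(15;20); the 6p21.3 amplicon averages 2:6 homologue dosage,
implying ten amplicon copies on the 50%-mosaic der(6)del(6)dup(6).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from karyoweave import (  # noqa: E402
    copy_number_profile, count_chromosomes, grch38_map,
    homologue_dosage_profile, major_minor, simulate_locus_fish, u937_fixture,
)
from karyoweave.fish import probe_from_dict  # noqa: E402
from karyoweave.io import (  # noqa: E402
    karyotype_summary, render_fish_table, write_fish_table,
    write_karyotype_json,
)
from karyoweave.u937 import (  # noqa: E402
    REGION_20Q12_CDR, REGION_6_AMPLICON, REGION_6_MID_Q, REGION_RP11_500O11,
    U937_FISH_PROBES, minimum_11q24_segment_length,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    genome = grch38_map()
    pop = u937_fixture("nominal", genome)
    stem = pop.clones[0].karyotype

    lines = [karyotype_summary(pop), ""]
    lines.append(f"stemline chromosomes: {count_chromosomes(stem)}")
    cn_cdr = copy_number_profile(pop, *REGION_20Q12_CDR)
    maj, mino = major_minor(homologue_dosage_profile(pop, *REGION_20Q12_CDR))
    lines.append(f"20q12 CDR: {cn_cdr:.2f} copies, homologue dosage "
                 f"{maj:.1f}:{mino:.1f} (single-homologue LOH)")
    chrom, a, b = REGION_RP11_500O11
    der20 = stem.member("der(20)t(15;20)")
    lines.append(f"RP11-500O11 region copies on der(20)t(15;20): "
                 f"{der20.copies(chrom, a, b):.0f}")
    maj, mino = major_minor(homologue_dosage_profile(pop, *REGION_6_AMPLICON))
    lines.append(f"6p21.3 amplicon dosage (major:minor): {maj:.1f}:{mino:.1f} "
                 f"-> {(maj - 1) / 0.5:.0f} copies on the 50%-mosaic derivative")
    lines.append(f"6p12.3->6q26 average copies: "
                 f"{copy_number_profile(pop, *REGION_6_MID_Q):.2f}")
    lines.append(f"11q24 segment minimum length: "
                 f"{minimum_11q24_segment_length() / 1e6:.3f} Mb")

    probes = [probe_from_dict(d) for d in U937_FISH_PROBES
              if d["kind"] == "locus" and d["chrom"] == "20"]
    tables = {p.name: simulate_locus_fish(p, stem, genome) for p in probes}
    df = render_fish_table(probes, tables,
                           ["der(11)t(11;16;20)", "der(20)t(15;20)"])
    write_fish_table(df, OUT / "fish_table_chr20.tsv")
    write_karyotype_json(pop, OUT / "karyotype.json")

    text = "\n".join(lines)
    (OUT / "fixture_summary.txt").write_text(text + "\n")
    print(text)
    print(f"\nwrote {OUT / 'fixture_summary.txt'}, fish_table_chr20.tsv, "
          f"karyotype.json")


if __name__ == "__main__":
    main()
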