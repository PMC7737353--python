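"""File formats: track TSV, SEG/BED export, FISH tables, karyotype JSON.

Internal coordinates are 1-based inclusive; BED output is 0-based half-open.
FISH tables use the conventional symbols "+" (one copy-equivalent per sign),
"(+)" (reduced signal) and "–" (absent).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .arrays import TRACK_COLUMNS
from .assembly import CaptureCall, DerivativeComposition
from .inference import SegmentCall
from .karyotype import CellPopulation, Karyotype


def write_track(track: pd.DataFrame, path) -> None:
    track[TRACK_COLUMNS].to_csv(path, sep="\t", index=False)


def read_track(path) -> pd.DataFrame:
    track = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(TRACK_COLUMNS) - set(track.columns)
    if missing:
        raise ValueError(f"track file missing columns: {sorted(missing)}")
    return track


def calls_to_frame(calls: list[SegmentCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "chrom": c.chrom, "start0": c.start - 1, "end": c.end,
            "n_probes": c.n_probes, "mean_lrr": round(c.mean_lrr, 4),
            "bands": ";".join(f"{b:.4f}" for b in (c.bands.centers if c.bands else ())),
            "cn_total": round(c.cn_total, 3) if c.selected else "",
            "n_major": round(c.n_major, 3) if c.selected else "",
            "n_minor": round(c.n_minor, 3) if c.selected else "",
            "mosaic_f": round(c.mosaic.fraction, 3) if c.mosaic else "",
            "ambiguous": int(c.ambiguous),
        })
    return pd.DataFrame(rows)


def write_seg(calls: list[SegmentCall], path) -> None:
    """SEG-style TSV of segment calls (start0 is 0-based)."""
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_bed(comps: list[DerivativeComposition], path) -> None:
    """Per-derivative content as BED (0-based half-open), one row per placement."""
    with open(path, "w") as fh:
        for comp in comps:
            for seg in comp.segments:
                fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t"
                         f"{comp.name}\t{seg.copies:.3f}\n")


def render_fish_table(probes: list, tables: dict[str, dict],
                      derivatives: list[str]) -> pd.DataFrame:
    """Assemble a FISH results table: one row per probe, one symbol column per
    derivative.  ``tables[probe_name][member]`` holds IntensityClass objects."""
    rows = []
    for probe in probes:
        row = {"probe": probe.name, "band": probe.band, "chrom": probe.chrom,
               "start": probe.start or "", "end": probe.end or ""}
        table = tables.get(probe.name, {})
        for der in derivatives:
            cls = table.get(der)
            row[der] = cls.symbol if cls is not None else "–"
        rows.append(row)
    return pd.DataFrame(rows)


def write_fish_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_karyotype_json(obj: Karyotype | CellPopulation, path) -> None:
    if isinstance(obj, CellPopulation):
        payload = {
            "name": obj.name,
            "clones": [{"fraction": c.fraction, "karyotype": c.karyotype.to_dict()}
                       for c in obj.clones],
            "sub_mosaics": [
                {"name": s.name, "fraction": s.fraction, "member": s.member,
                 "variant": s.variant.to_dict() if s.variant else None}
                for s in obj.sub_mosaics],
        }
    else:
        payload = obj.to_dict()
    Path(path).write_text(json.dumps(payload, indent=1))


def read_karyotype_json(path) -> Karyotype:
    return Karyotype.from_dict(json.loads(Path(path).read_text()))


def write_capture_report(captures: list[CaptureCall], conflicts, path) -> None:
    payload = {
        "captures": [c.__dict__ for c in captures],
        "conflicts": [c.__dict__ for c in conflicts],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def karyotype_summary(pop: CellPopulation) -> str:
    """Human-readable clone summary: chromosome counts and member names."""
    from .karyotype import count_chromosomes

    lines = [f"population: {pop.name}"]
    for clone in pop.clones:
        kt = clone.karyotype
        lines.append(f"  clone {kt.name!r}: fraction {clone.fraction:.3f}, "
                     f"{count_chromosomes(kt)} chromosomes")
    for sm in pop.sub_mosaics:
        lines.append(f"  sub-mosaic {sm.name!r}: fraction {sm.fraction:.3f} "
                     f"affecting {sm.member!r}")
    return "\n".join(lines)
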