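"""CIS annotation against a gene BED file, and track/table export.

Each CIS is annotated with the names of all gene records within 20 kb of
the CIS interval (edge-to-edge; overlap counts as distance 0).  Known
artifact regions — high-copy loci misassembled as single copy, or
transposon-internal sequence such as the En2 fragment carried by T2/Onc —
are marked in the annotation file with names containing the string 'BAD';
any CIS touching one is suppressed from the report entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import log10
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .scan import CIS

NO_RESULT = "No results within a 20,000 bp window"
BAD_MARKER = "BAD"
DEFAULT_RADIUS = 20_000


@dataclass(frozen=True)
class GeneRecord:
    chrom: str
    start: int  # 0-based half-open
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval for {self.name}")


def read_gene_bed(path) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED4 requires 4 columns")
            genes.append(GeneRecord(parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return genes


def annotate_cis(cis_list: Sequence[CIS], genes: Sequence[GeneRecord],
                 radius: int = DEFAULT_RADIUS) -> list[CIS]:
    """Fill the annotation column; drop CISs near 'BAD'-marked records.

    Gene names are joined with "," in input order, duplicates removed;
    a CIS with no record within `radius` gets the fixed no-result string.
    """
    trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        # +1 on the expanded end (and on the query end below) makes the
        # edge-to-edge distance test inclusive: a gap of exactly `radius`
        # still counts as "within", despite half-open interval overlap.
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - radius, g.end + radius + 1, (i, g.name))
    out: list[CIS] = []
    for cis in cis_list:
        hits = sorted(iv.data for iv in trees.get(cis.chrom, IntervalTree())
                      .overlap(cis.start, cis.end + 1))
        names = list(dict.fromkeys(name for _, name in hits))
        if any(BAD_MARKER in name for name in names):
            continue
        annotation = ",".join(names) if names else NO_RESULT
        out.append(replace(cis, annotation=annotation))
    return out


def cis_frame(cis_list: Sequence[CIS]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chrom": c.chrom, "start": c.start, "end": c.end,
          "window_size": c.window_size,
          "insert_count": c.insert_count, "library_count": c.library_count,
          "region_count": c.region_count,
          "p_insert": c.p_insert, "p_library": c.p_library,
          "p_region": c.p_region,
          "n_pos_strand": c.n_pos_strand,
          "libraries": ",".join(c.libraries),
          "annotation": c.annotation}
         for c in cis_list],
        columns=["chrom", "start", "end", "window_size", "insert_count",
                 "library_count", "region_count", "p_insert", "p_library",
                 "p_region", "n_pos_strand", "libraries", "annotation"],
    )


def write_cis_table(cis_list: Sequence[CIS], path) -> None:
    cis_frame(cis_list).to_csv(path, sep="\t", index=False)


def write_cis_wig(cis_list: Sequence[CIS], path, which: str = "p_region",
                  name: str = "CIS") -> None:
    """WIG track: one span per CIS, height = -log10 of the chosen p-value."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for c in sorted(cis_list, key=lambda c: (c.chrom, c.start)):
            p = getattr(c, which)
            height = 999.0 if p <= 0 else -log10(p)
            fh.write(f"variableStep chrom={c.chrom} span={c.end - c.start}\n")
            fh.write(f"{c.start + 1}\t{height:.6g}\n")  # WIG is 1-based
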