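"""File-backed project store, summary reports, and meta-analysis merging.

A Project collects every intermediate of one screen analysis: collapsed
fragments, mappings, insertion events, and per-library statistics, plus
the rejection/unmapped tallies needed for the three-level summary report.
Projects persist as a directory of TSVs, and any number of projects can
be merged for meta-analysis: the library *name* is the unique identifier,
so same-named libraries combine (bin-level read counts summed) while
barcodes may be freely reused across projects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .demux import TrimmedFragment, RejectionStats, write_fragment_table, read_fragment_table
from .mapping import FragmentMapping, UnmappedStats, MIN_FRAGMENT_LEN
from .events import InsertionEvent, LibraryStats, library_stats


@dataclass
class Project:
    name: str
    fragments: list[TrimmedFragment] = field(default_factory=list)
    mappings: list[FragmentMapping] = field(default_factory=list)
    events: list[InsertionEvent] = field(default_factory=list)
    rejections: RejectionStats = field(default_factory=RejectionStats)
    unmapped: UnmappedStats = field(default_factory=UnmappedStats)
    cutoff_fraction: float | None = None

    @property
    def stats(self) -> dict[str, LibraryStats]:
        return library_stats(self.mappings, self.events)

    # -- persistence ---------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_fragment_table(self.fragments, d / "fragments.tsv")
        pd.DataFrame([asdict(m) for m in self.mappings]).to_csv(
            d / "mappings.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(e) for e in self.events]).to_csv(
            d / "events.tsv", sep="\t", index=False)
        meta = {"name": self.name, "cutoff_fraction": self.cutoff_fraction,
                **{f"rej_{k}": v for k, v in asdict(self.rejections).items()},
                **{f"unm_{k}": v for k, v in asdict(self.unmapped).items()}}
        pd.Series(meta).to_csv(d / "meta.tsv", sep="\t", header=False)

    @classmethod
    def load(cls, directory) -> "Project":
        d = Path(directory)
        meta = pd.read_csv(d / "meta.tsv", sep="\t", header=None,
                           index_col=0).iloc[:, 0].to_dict()
        proj = cls(name=str(meta["name"]))
        cutoff = meta.get("cutoff_fraction")
        proj.cutoff_fraction = None if pd.isna(cutoff) or cutoff == "" else float(cutoff)
        proj.rejections = RejectionStats(**{
            k[4:]: int(meta[k]) for k in meta if k.startswith("rej_")})
        proj.unmapped = UnmappedStats(**{
            k[4:]: int(meta[k]) for k in meta if k.startswith("unm_")})
        proj.fragments = read_fragment_table(d / "fragments.tsv")
        mdf = pd.read_csv(d / "mappings.tsv", sep="\t")
        proj.mappings = [FragmentMapping(**row) for row in mdf.to_dict("records")]
        edf = pd.read_csv(d / "events.tsv", sep="\t")
        proj.events = [InsertionEvent(**row) for row in edf.to_dict("records")]
        return proj


@dataclass
class SummaryReport:
    """Three-level count report: project, directional library, library."""

    project: pd.DataFrame
    directional: pd.DataFrame
    library: pd.DataFrame


def _directional_name(frag: TrimmedFragment) -> str:
    return f"{frag.library}-{'L' if frag.side == 'left' else 'R'}"


def summarize_project(project: Project) -> SummaryReport:
    """Counts of reads, mappable reads, mapped reads and threshold-passing
    regions, at project, directional-library and merged-library level,
    with mapping percentages."""
    dir_reads: dict[str, int] = defaultdict(int)
    dir_mappable: dict[str, int] = defaultdict(int)
    lib_reads: dict[str, int] = defaultdict(int)
    lib_mappable: dict[str, int] = defaultdict(int)
    for f in project.fragments:
        dname = _directional_name(f)
        dir_reads[dname] += f.read_count
        lib_reads[f.library] += f.read_count
        if len(f.genomic_seq) >= MIN_FRAGMENT_LEN:
            dir_mappable[dname] += f.read_count
            lib_mappable[f.library] += f.read_count
    dir_mapped: dict[str, int] = defaultdict(int)
    lib_mapped: dict[str, int] = defaultdict(int)
    for m in project.mappings:
        dname = f"{m.library}-{'L' if m.side == 'left' else 'R'}"
        dir_mapped[dname] += m.read_count
        lib_mapped[m.library] += m.read_count
    lib_regions: dict[str, int] = defaultdict(int)
    for e in project.events:
        lib_regions[e.library] += 1

    def pct(num: int, den: int) -> float:
        return round(100.0 * num / den, 2) if den else 0.0

    directional = pd.DataFrame(
        [{"directional_library": d, "reads": dir_reads[d],
          "mappable": dir_mappable[d], "mapped": dir_mapped[d],
          "pct_mapped": pct(dir_mapped[d], dir_reads[d])}
         for d in sorted(dir_reads)])
    library = pd.DataFrame(
        [{"library": l, "reads": lib_reads[l], "mappable": lib_mappable[l],
          "mapped": lib_mapped[l],
          "pct_mapped": pct(lib_mapped[l], lib_reads[l]),
          "regions_at_threshold": lib_regions.get(l, 0)}
         for l in sorted(lib_reads)])
    total_assigned = sum(lib_reads.values())
    total_input = total_assigned + project.rejections.total
    proj = pd.DataFrame([{
        "project": project.name,
        "reads_input": total_input,
        "reads_assigned": total_assigned,
        "reads_rejected": project.rejections.total,
        "reads_mappable": sum(lib_mappable.values()),
        "reads_mapped": sum(lib_mapped.values()),
        "pct_mapped": pct(sum(lib_mapped.values()), total_assigned),
        "regions_at_threshold": sum(lib_regions.values()),
    }])
    return SummaryReport(proj, directional, library)


def write_summary(report: SummaryReport, path) -> None:
    with open(path, "w") as fh:
        for title, df in (("# project", report.project),
                          ("# directional libraries", report.directional),
                          ("# libraries", report.library)):
            fh.write(title + "\n")
            df.to_csv(fh, sep="\t", index=False)


def merge_projects(projects: Sequence[Project], name: str = "merged") -> Project:
    """Combine projects for meta-analysis; same-named libraries merge.

    Event read counts sum at the bin level; distinct raw-position counts
    sum as an upper bound (the underlying coordinates are not retained
    across projects).  Merging is associative and commutative.
    """
    merged = Project(name=name)
    for p in projects:
        merged.fragments.extend(p.fragments)
        merged.mappings.extend(p.mappings)
        merged.rejections = RejectionStats(*(
            a + b for a, b in zip(_stat_tuple(merged.rejections),
                                  _stat_tuple(p.rejections))))
        merged.unmapped = UnmappedStats(
            merged.unmapped.too_short + p.unmapped.too_short,
            merged.unmapped.multimapped + p.unmapped.multimapped,
            merged.unmapped.unmapped + p.unmapped.unmapped)
    acc: dict[tuple[str, str, int, str], tuple[int, int]] = {}
    for p in projects:
        for e in p.events:
            key = (e.library, e.chrom, e.bin_index, e.orientation)
            n, npos = acc.get(key, (0, 0))
            acc[key] = (n + e.read_count, npos + e.n_raw_positions)
    merged.events = [InsertionEvent(lib, chrom, b, o, n, npos)
                     for (lib, chrom, b, o), (n, npos) in sorted(acc.items())]
    merged.fragments = sorted(merged.fragments,
                              key=lambda f: (f.library, f.side, f.genomic_seq))
    merged.mappings = sorted(merged.mappings,
                             key=lambda m: (m.library, m.chrom, m.pos, m.strand, m.side))
    return merged


def _stat_tuple(s: RejectionStats) -> tuple[int, ...]:
    return (s.bad_alphabet, s.no_barcode, s.no_tag, s.empty, s.no_ta)
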