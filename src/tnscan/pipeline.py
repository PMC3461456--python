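"""End-to-end orchestration: reads in, ranked CISs and associations out."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotate import GeneRecord, annotate_cis, write_cis_table, write_cis_wig
from .association import (PresenceMatrix, AssociationResult, associations_frame,
                          build_presence_matrix, run_associations)
from .config import ScanConfig, TrimConfig
from .demux import (BarcodeSpec, RawRead, collapse_duplicates, demux_and_trim)
from .events import (apply_cutoff, bin_events, exclude_chromosomes,
                     library_stats, write_events_bed)
from .mapping import (GenomeIndex, MappingStage, map_iteratively,
                      write_mappings_bed)
from .project import Project, summarize_project, write_summary
from .scan import CIS, call_cis


@dataclass
class ScreenResult:
    project: Project
    cis: list[CIS]
    presence: PresenceMatrix | None = None
    associations: dict[str, list[AssociationResult]] | None = None


def run_screen(
    reads: Iterable[RawRead],
    barcode_specs: Sequence[BarcodeSpec],
    trim_cfg: TrimConfig,
    genome: GenomeIndex,
    metadata: Mapping[str, Iterable[str]] | None = None,
    cutoff_fraction: float | None = None,
    excluded_chroms: Sequence[str] = (),
    scan_cfg: ScanConfig | None = None,
    schedule: Sequence[MappingStage] | None = None,
    genes: Sequence[GeneRecord] | None = None,
    cis_p_filter: float = 1e-5,
    name: str = "project",
) -> ScreenResult:
    """Run the whole pipeline on one set of reads.

    The scan's genome size is the summed length of the non-excluded
    chromosomes unless an explicit ScanConfig is given.
    """
    frags, rejections = demux_and_trim(reads, list(barcode_specs), trim_cfg)
    frags = collapse_duplicates(frags)
    mappings, unmapped = map_iteratively(frags, genome, schedule)
    events = bin_events(mappings)
    stats = library_stats(mappings, events)
    events = apply_cutoff(events, stats, cutoff_fraction)
    events = exclude_chromosomes(events, excluded_chroms)
    project = Project(name=name, fragments=frags, mappings=mappings,
                      events=events, rejections=rejections, unmapped=unmapped,
                      cutoff_fraction=cutoff_fraction)
    if scan_cfg is None:
        size = sum(l for c, l in genome.chrom_lengths.items()
                   if c not in set(excluded_chroms))
        scan_cfg = ScanConfig(genome_size=size, cutoff_fraction=cutoff_fraction)
    cis = call_cis(events, scan_cfg)
    if genes is not None:
        cis = annotate_cis(cis, genes)
    result = ScreenResult(project=project, cis=cis)
    if metadata is not None:
        result.presence = build_presence_matrix(cis, events, metadata,
                                                cis_p_filter=cis_p_filter)
        result.associations = run_associations(result.presence)
    return result


def rescan(project: Project, scan_cfg: ScanConfig,
           libraries: Sequence[str] | None = None) -> list[CIS]:
    """Re-run the CIS scan on a (subset of a) stored project."""
    events = project.events
    if libraries is not None:
        wanted = set(libraries)
        events = [e for e in events if e.library in wanted]
    return call_cis(events, scan_cfg)


def write_tracks(result: ScreenResult, outdir) -> list[Path]:
    """Write every track and table for one analysis.

    Emits the raw-mapping BED (read strand), the insertion-event BED
    (biological orientation in the strand column), the CIS WIG (peak
    height = -log10 of the region p-value), the CIS TSV, the three
    association TSVs, the incidence matrix, and the three-level summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    write_mappings_bed(result.project.mappings, out("raw_mappings.bed"))
    write_events_bed(result.project.events, out("insertions.bed"))
    write_cis_wig(result.cis, out("cis.wig"))
    write_cis_table(result.cis, out("cis.tsv"))
    write_summary(summarize_project(result.project), out("summary.tsv"))
    if result.associations is not None:
        for family, results in result.associations.items():
            associations_frame(results).to_csv(out(f"{family}.tsv"),
                                               sep="\t", index=False)
    if result.presence is not None:
        result.presence.data.astype(int).to_csv(out("presence_matrix.tsv"), sep="\t")
    return written
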