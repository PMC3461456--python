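"""From mapped fragments to clonal insertion events.

Three concerns live here.  First, read strand plus priming side are
converted to the biological orientation of the insertion: the Sleeping
Beauty transposon is asymmetric, and an insertion is recorded on the
strand whose transcription it can activate (a right-side read on '+' or a
left-side read on '-' both witness a '+' insertion).  Second, mapped
positions are binned into fixed 100-bp genome tiles per library and
orientation: local hopping and junction sequencing errors scatter a clonal
insertion over neighbouring TA sites, and binning re-groups these with the
dominant site.  Third, a read-fraction cutoff removes low-abundance
passenger insertions (late, few-cell events counted only once or twice),
keeping a binned region only if it carries at least a set fraction of its
library's total mapped reads.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .demux import LEFT, RIGHT
from .mapping import FragmentMapping

log = logging.getLogger(__name__)

BIN_SIZE = 100

_ORIENT = {
    (RIGHT, "+"): "+",
    (LEFT, "-"): "+",
    (RIGHT, "-"): "-",
    (LEFT, "+"): "-",
}

_SUFFIX_RE = re.compile(r"-(L|R)$")


@dataclass(frozen=True)
class InsertionEvent:
    """A binned, orientation-resolved insertion for one library."""

    library: str
    chrom: str
    bin_index: int
    orientation: str  # "+" | "-"
    read_count: int
    n_raw_positions: int = 1

    @property
    def bin_start(self) -> int:
        return self.bin_index * BIN_SIZE


@dataclass(frozen=True)
class LibraryStats:
    library: str
    total_mapped_reads: int
    total_events: int


def resolve_orientation(side: str, strand: str) -> str:
    """Biological insertion orientation from priming side and read strand."""
    return _ORIENT[(side, strand)]


def merge_directional_libraries(mappings: Iterable[FragmentMapping]) -> list[FragmentMapping]:
    """Strip -L/-R suffixes from directional library names.

    Used for records imported with directional names (e.g. from SAM); the
    internal demux path already stores the merged name with the side kept
    as a separate field.
    """
    out = []
    for m in mappings:
        match = _SUFFIX_RE.search(m.library)
        if not match:
            raise ValueError(f"library name {m.library!r} lacks -L/-R suffix")
        side = LEFT if match.group(1) == "L" else RIGHT
        out.append(FragmentMapping(m.library[: match.start()], side, m.chrom,
                                   m.pos, m.strand, m.stage_index, m.mismatches,
                                   m.read_count))
    return out


def bin_events(mappings: Iterable[FragmentMapping],
               bin_size: int = BIN_SIZE) -> list[InsertionEvent]:
    """Group mappings into (library, chrom, 100-bp bin, orientation) events.

    Read mass is conserved; n_raw_positions counts the distinct mapped
    coordinates collapsed into each bin.
    """
    acc: dict[tuple[str, str, int, str], tuple[int, set[int]]] = {}
    for m in mappings:
        orient = resolve_orientation(m.side, m.strand)
        key = (m.library, m.chrom, m.pos // bin_size, orient)
        if key in acc:
            n, positions = acc[key]
            positions.add(m.pos)
            acc[key] = (n + m.read_count, positions)
        else:
            acc[key] = (m.read_count, {m.pos})
    return [InsertionEvent(lib, chrom, b, orient, n, len(pos))
            for (lib, chrom, b, orient), (n, pos) in sorted(acc.items())]


def library_stats(mappings: Iterable[FragmentMapping],
                  events: Sequence[InsertionEvent]) -> dict[str, LibraryStats]:
    reads: dict[str, int] = defaultdict(int)
    for m in mappings:
        reads[m.library] += m.read_count
    n_events: dict[str, int] = defaultdict(int)
    for e in events:
        n_events[e.library] += 1
    return {lib: LibraryStats(lib, reads[lib], n_events.get(lib, 0))
            for lib in sorted(reads)}


def apply_cutoff(events: Sequence[InsertionEvent],
                 stats: Mapping[str, LibraryStats],
                 fraction: float | None) -> list[InsertionEvent]:
    """Keep an event iff its reads are >= fraction of its library's mapped reads.

    fraction None disables the cutoff (recommended for 454-depth data); the
    Illumina recommendation is 1/10,000 — e.g. a library with 100,000
    mapped reads keeps exactly the regions identified by >= 10 reads.
    """
    if fraction is None:
        return list(events)
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0,1) or None")
    kept = [e for e in events
            if e.read_count >= fraction * stats[e.library].total_mapped_reads]
    log.info("clonality cutoff %.3g kept %d of %d events", fraction, len(kept), len(events))
    return kept


def exclude_chromosomes(events: Sequence[InsertionEvent],
                        excluded: Iterable[str]) -> list[InsertionEvent]:
    """Drop events on listed chromosomes (e.g. the transposon donor
    chromosome, enriched for local-hopping artifacts)."""
    excluded = set(excluded)
    kept = [e for e in events if e.chrom not in excluded]
    if len(kept) != len(events):
        log.info("excluded %d events on %s", len(events) - len(kept), sorted(excluded))
    return kept


def read_excluded_chromosomes(path) -> list[str]:
    """One chromosome name per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_events_bed(events: Iterable[InsertionEvent], path,
                     bin_size: int = BIN_SIZE) -> None:
    """Insertion-event BED track; strand column = biological orientation."""
    with open(path, "w") as fh:
        for e in sorted(events, key=lambda e: (e.chrom, e.bin_index, e.orientation, e.library)):
            start = e.bin_index * bin_size
            fh.write(f"{e.chrom}\t{start}\t{start + bin_size}\t{e.library}\t"
                     f"{e.read_count}\t{e.orientation}\n")
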