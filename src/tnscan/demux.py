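"""Demultiplexing and trimming of barcoded junction-fragment reads.

A junction-fragment read has the layout::

    barcode + transposon_tag + genomic sequence [+ linker]

The barcode identifies the directional library (one PCR reaction per side
of the insertion, named ``<library>-L`` or ``<library>-R``); the transposon
tag is the terminal IRDR/LTR sequence; everything after it, up to the
ligation linker, is endogenous genomic sequence.  For Sleeping Beauty
screens the genomic part must start with the TA dinucleotide the
transposon integrated into — reads violating this are rejected to guard
against multimer-ligation artifacts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .config import TrimConfig

_VALID = set("ACGTN")

LEFT = "left"
RIGHT = "right"

_SIDE_ALIASES = {
    "left": LEFT, "l": LEFT, "right": RIGHT, "r": RIGHT,
}
_SUFFIX_FOR_SIDE = {LEFT: "-L", RIGHT: "-R"}


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str


@dataclass(frozen=True)
class BarcodeSpec:
    """One row of the barcode table: barcode -> directional library."""

    barcode: str
    directional_library: str
    side: str  # "left" | "right"

    @property
    def library(self) -> str:
        """Library name with the -L/-R direction suffix stripped."""
        return self.directional_library[:-2]


@dataclass(frozen=True)
class TrimmedFragment:
    library: str
    side: str
    genomic_seq: str
    read_count: int = 1


@dataclass
class RejectionStats:
    """Per-class counts of reads that could not be assigned."""

    bad_alphabet: int = 0
    no_barcode: int = 0
    no_tag: int = 0
    empty: int = 0
    no_ta: int = 0

    @property
    def total(self) -> int:
        return self.bad_alphabet + self.no_barcode + self.no_tag + self.empty + self.no_ta


def read_sequences(path, fmt: str | None = None) -> list[RawRead]:
    """Load reads from FASTA, FASTQ, or a two-column id/sequence tab file."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".fa": "fasta", ".fasta": "fasta", ".fna": "fasta",
               ".fq": "fastq", ".fastq": "fastq"}.get(suffix, "tab")
    if fmt in ("fasta", "fastq"):
        return [RawRead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            reads.append(RawRead(parts[0], parts[1].upper()))
    return reads


def parse_barcode_table(path) -> list[BarcodeSpec]:
    """Parse the tab-delimited barcode table (barcode, directional library, side).

    Barcodes must be unique; library names must carry a -L or -R suffix
    consistent with the stated priming side.
    """
    specs: list[BarcodeSpec] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            barcode, dirlib, side_raw = parts[0].upper(), parts[1], parts[2].strip().lower()
            if side_raw not in _SIDE_ALIASES:
                raise ValueError(f"{path}:{lineno}: unknown priming side {parts[2]!r}")
            side = _SIDE_ALIASES[side_raw]
            if not dirlib.endswith(("-L", "-R")):
                raise ValueError(
                    f"{path}:{lineno}: directional library {dirlib!r} lacks -L/-R suffix")
            if dirlib[-2:] != _SUFFIX_FOR_SIDE[side]:
                raise ValueError(
                    f"{path}:{lineno}: suffix of {dirlib!r} inconsistent with side {side!r}")
            if barcode in seen:
                raise ValueError(f"{path}:{lineno}: duplicate barcode {barcode!r}")
            seen.add(barcode)
            specs.append(BarcodeSpec(barcode, dirlib, side))
    if not specs:
        raise ValueError(f"{path}: empty barcode table")
    return specs


def _hamming_no_n(a: str, b: str) -> int:
    # N never matches: any N counts as a mismatch on either side.
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def _match_barcode(seq: str, by_len: dict[int, dict[str, BarcodeSpec]],
                   specs: list[BarcodeSpec], mismatches: int) -> BarcodeSpec | None:
    # Exact match first, longest barcodes taking precedence.
    for blen in sorted(by_len, reverse=True):
        spec = by_len[blen].get(seq[:blen])
        if spec is not None and "N" not in spec.barcode and "N" not in seq[:blen]:
            return spec
    if mismatches > 0:
        candidates = [s for s in specs
                      if len(seq) >= len(s.barcode)
                      and _hamming_no_n(seq[: len(s.barcode)], s.barcode) <= mismatches]
        if len(candidates) == 1:
            return candidates[0]
    return None


def demux_and_trim(
    reads: Iterable[RawRead | tuple[str, str]],
    specs: list[BarcodeSpec],
    cfg: TrimConfig,
) -> tuple[list[TrimmedFragment], RejectionStats]:
    """Assign each read to its library and strip non-genomic sequence.

    Returns one fragment per assigned read (read_count 1; collapse with
    :func:`collapse_duplicates`) plus rejection counts.  Rejections are
    never fatal.  Read conservation holds: assigned + rejected == input.
    """
    if not specs:
        raise ValueError("no barcode specs supplied")
    by_len: dict[int, dict[str, BarcodeSpec]] = {}
    for s in specs:
        by_len.setdefault(len(s.barcode), {})[s.barcode] = s
    tag = cfg.transposon_tag.upper()
    linker = cfg.linker.upper()
    stats = RejectionStats()
    frags: list[TrimmedFragment] = []
    for read in reads:
        seq = read.sequence if isinstance(read, RawRead) else read[1]
        if not seq or set(seq) - _VALID:
            stats.bad_alphabet += 1
            continue
        spec = _match_barcode(seq, by_len, specs, cfg.barcode_mismatches)
        if spec is None:
            stats.no_barcode += 1
            continue
        rest = seq[len(spec.barcode):]
        if not rest.startswith(tag) or "N" in rest[: len(tag)]:
            stats.no_tag += 1
            continue
        genomic = rest[len(tag):]
        if linker:
            cut = genomic.find(linker)
            if cut >= 0:
                genomic = genomic[:cut]
        if not genomic:
            stats.empty += 1
            continue
        if cfg.require_ta and not genomic.startswith("TA"):
            stats.no_ta += 1
            continue
        frags.append(TrimmedFragment(spec.library, spec.side, genomic))
    return frags, stats


def collapse_duplicates(frags: Iterable[TrimmedFragment]) -> list[TrimmedFragment]:
    """Condense identical sequences from the same library and side.

    The total read count is conserved; output is sorted for determinism.
    """
    counts: Counter[tuple[str, str, str]] = Counter()
    for f in frags:
        counts[(f.library, f.side, f.genomic_seq)] += f.read_count
    return [TrimmedFragment(lib, side, seq, n)
            for (lib, side, seq), n in sorted(counts.items())]


def write_fragment_table(frags: Iterable[TrimmedFragment], path) -> None:
    with open(path, "w") as fh:
        fh.write("library\tside\tgenomic_seq\tread_count\n")
        for f in frags:
            fh.write(f"{f.library}\t{f.side}\t{f.genomic_seq}\t{f.read_count}\n")


def read_fragment_table(path) -> list[TrimmedFragment]:
    frags = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            lib, side, seq, n = line.rstrip("\n").split("\t")
            frags.append(TrimmedFragment(lib, side, seq, int(n)))
    return frags
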