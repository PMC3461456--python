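"""Iterative prefix mapping of trimmed fragments to a reference genome.

The mapper enforces two biological constraints: the alignment must start at
the very first genomic base 3' of the transposon (no soft-clipping of the
junction), and it must be unique in the genome.  Because partial linker
sequence and unintended ligation products can trail the 3' end of a read,
fragments that fail to map at full length are retried with progressively
shorter prefixes, each with a length-calibrated mismatch allowance:

    stage 1  full length (> 33 bp)   3 mismatches
    stage 2  first 33 bp             3 mismatches
    stage 3  first 30 bp             2 mismatches
    stage 4  first 28 bp             1 mismatch
    stage 5  first 24 bp             0 mismatches

Fragments of 23 bases or fewer are discarded outright: below these
length/mismatch cutoffs a substantial fraction of *random* sequence maps
uniquely to a mammalian genome, so shorter prefixes cannot be trusted.

The built-in aligner is an exact all-hits end-to-end Hamming matcher
(pigeonhole 8-mer seeding + vectorised verification), adequate for the
small genomes used in simulation and testing; large-genome alignments can
be produced externally and imported from SAM via :func:`import_sam`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from .demux import TrimmedFragment

log = logging.getLogger(__name__)

FULL = None  # sentinel prefix_length: use the fragment's full length

MIN_FRAGMENT_LEN = 24

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_COMP = str.maketrans("ACGTN", "TGCAN")

_SEED = 8  # pigeonhole seed length


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class MappingStage:
    """One round of the iterative schedule."""

    prefix_length: int | None  # None = full fragment length
    max_mismatches: int

    def __post_init__(self) -> None:
        if self.prefix_length is not None and self.prefix_length < MIN_FRAGMENT_LEN:
            raise ValueError("prefix_length must be >= 24")
        if not 0 <= self.max_mismatches <= 3:
            raise ValueError("max_mismatches must be in 0..3")


def default_schedule() -> list[MappingStage]:
    """The five-round length/mismatch schedule calibrated on the mouse genome."""
    return [
        MappingStage(FULL, 3),
        MappingStage(33, 3),
        MappingStage(30, 2),
        MappingStage(28, 1),
        MappingStage(24, 0),
    ]


@dataclass(frozen=True)
class FragmentMapping:
    """A uniquely mapped fragment.

    pos is the 0-based coordinate of the first genomic base 3' of the
    transposon (for minus-strand alignments this is the *rightmost* base of
    the aligned interval).
    """

    library: str
    side: str
    chrom: str
    pos: int
    strand: str  # "+" | "-"
    stage_index: int
    mismatches: int
    read_count: int


@dataclass
class UnmappedStats:
    too_short: int = 0
    multimapped: int = 0
    unmapped: int = 0

    @property
    def total(self) -> int:
        return self.too_short + self.multimapped + self.unmapped


class GenomeIndex:
    """Reference genome: names, lengths, and (optionally) sequence.

    Sequence is required for the built-in aligner; when alignments come
    from an external aligner via SAM, a chrom.sizes table is enough.
    """

    def __init__(self, chrom_names: Sequence[str], chrom_lengths: Sequence[int],
                 sequences: dict[str, str] | None = None):
        if len(set(chrom_names)) != len(chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        self.chrom_names = list(chrom_names)
        self.chrom_lengths = {n: int(l) for n, l in zip(chrom_names, chrom_lengths)}
        self.sequences = sequences
        if sequences is not None:
            for name in chrom_names:
                if len(sequences[name]) != self.chrom_lengths[name]:
                    raise ValueError(f"sequence/length mismatch for {name}")
        self._codes: dict[str, np.ndarray] = {}
        self._seed_idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_lengths.values())

    @classmethod
    def from_fasta(cls, path) -> "GenomeIndex":
        names, lengths, seqs = [], [], {}
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            s = str(rec.seq).upper()
            lengths.append(len(s))
            seqs[rec.id] = s
        return cls(names, lengths, seqs)

    @classmethod
    def from_sizes(cls, path) -> "GenomeIndex":
        names, lengths = [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                name, size = line.split()[:2]
                names.append(name)
                lengths.append(int(size))
        return cls(names, lengths, None)

    # -- built-in aligner internals ------------------------------------

    def _chrom_codes(self, chrom: str) -> np.ndarray:
        if chrom not in self._codes:
            if self.sequences is None:
                raise ValueError("GenomeIndex has no sequence; use import_sam instead")
            self._codes[chrom] = _encode(self.sequences[chrom])
        return self._codes[chrom]

    def _seed_index(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted base-5 hashes of every 8-mer window plus their positions."""
        if chrom not in self._seed_idx:
            codes = self._chrom_codes(chrom).astype(np.uint64)
            n = len(codes) - _SEED + 1
            if n <= 0:
                self._seed_idx[chrom] = (np.empty(0, np.uint64), np.empty(0, np.int64))
                return self._seed_idx[chrom]
            h = np.zeros(n, dtype=np.uint64)
            for j in range(_SEED):
                h = h * np.uint64(5) + codes[j : j + n]
            order = np.argsort(h, kind="stable").astype(np.int64)
            self._seed_idx[chrom] = (h[order], order)
        return self._seed_idx[chrom]


def _seed_hash(codes: np.ndarray, offset: int) -> int | None:
    chunk = codes[offset : offset + _SEED]
    if (chunk >= 4).any():  # N in chunk: cannot exact-match
        return None
    v = 0
    for c in chunk:
        v = v * 5 + int(c)
    return v


def _candidate_starts(genome: GenomeIndex, chrom: str, qcodes: np.ndarray,
                      max_mm: int) -> np.ndarray:
    """Pigeonhole: alignment start positions whose window shares an exact
    8-mer chunk with the query at one of max_mm+1 disjoint offsets."""
    sorted_h, order = genome._seed_index(chrom)
    cands = []
    for j in range(max_mm + 1):
        off = j * _SEED
        h = _seed_hash(qcodes, off)
        if h is None:
            continue
        lo = np.searchsorted(sorted_h, np.uint64(h), side="left")
        hi = np.searchsorted(sorted_h, np.uint64(h), side="right")
        if hi > lo:
            cands.append(order[lo:hi] - off)
    if not cands:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(cands))


def _verify(codes: np.ndarray, starts: np.ndarray, qcodes: np.ndarray,
            max_mm: int) -> tuple[np.ndarray, np.ndarray]:
    L = len(qcodes)
    starts = starts[(starts >= 0) & (starts + L <= len(codes))]
    if len(starts) == 0:
        return starts, np.empty(0, dtype=np.int64)
    window = codes[starts[:, None] + np.arange(L)]
    mm = (window != qcodes).sum(axis=1)
    ok = mm <= max_mm
    return starts[ok], mm[ok].astype(np.int64)


def _scan_one_strand(genome: GenomeIndex, chrom: str, query: str,
                     max_mm: int) -> tuple[np.ndarray, np.ndarray]:
    codes = genome._chrom_codes(chrom)
    qcodes = _encode(query)
    L = len(qcodes)
    if L > len(codes):
        return np.empty(0, np.int64), np.empty(0, np.int64)
    if (max_mm + 1) * _SEED > L:
        # query too short for pigeonhole seeding: brute-force scan
        n = len(codes) - L + 1
        mm = np.zeros(n, dtype=np.int32)
        for j in range(L):
            mm += codes[j : j + n] != qcodes[j]
        starts = np.nonzero(mm <= max_mm)[0].astype(np.int64)
        return starts, mm[starts].astype(np.int64)
    return _verify(codes, _candidate_starts(genome, chrom, qcodes, max_mm), qcodes, max_mm)


def align_prefix(fragment: TrimmedFragment | str, genome: GenomeIndex,
                 length: int, max_mm: int) -> list[tuple[str, int, str, int]]:
    """All end-to-end alignments of the fragment's first `length` bases.

    Returns (chrom, pos, strand, mismatches) tuples for every genome
    position on either strand within Hamming distance max_mm.  Minus-strand
    hits are reported at the genome coordinate of the fragment's *first*
    base (the rightmost base of the aligned interval).
    """
    seq = fragment if isinstance(fragment, str) else fragment.genomic_seq
    if length > len(seq):
        raise ValueError(f"prefix length {length} exceeds fragment length {len(seq)}")
    query = seq[:length]
    rc = revcomp(query)
    hits: list[tuple[str, int, str, int]] = []
    for chrom in genome.chrom_names:
        starts, mms = _scan_one_strand(genome, chrom, query, max_mm)
        hits.extend((chrom, int(p), "+", int(m)) for p, m in zip(starts, mms))
        starts, mms = _scan_one_strand(genome, chrom, rc, max_mm)
        hits.extend((chrom, int(p) + length - 1, "-", int(m)) for p, m in zip(starts, mms))
    hits.sort(key=lambda h: (genome.chrom_names.index(h[0]), h[1], h[2]))
    return hits


def map_iteratively(
    frags: Iterable[TrimmedFragment],
    genome: GenomeIndex,
    schedule: Sequence[MappingStage] | None = None,
) -> tuple[list[FragmentMapping], UnmappedStats]:
    """Map each fragment through the staged schedule.

    A fragment maps at the first stage yielding exactly one hit; two or
    more hits retire it as a multimapper (shorter prefixes can only gain
    hits, never lose them); zero hits fall through to the next stage.
    Fragments shorter than 24 bases are discarded before stage 1.
    """
    if schedule is None:
        schedule = default_schedule()
    stats = UnmappedStats()
    mappings: list[FragmentMapping] = []
    for frag in frags:
        n = len(frag.genomic_seq)
        if n < MIN_FRAGMENT_LEN:
            stats.too_short += 1
            continue
        fate = "unmapped"
        for idx, stage in enumerate(schedule, start=1):
            if stage.prefix_length is FULL:
                if n <= 33:
                    continue  # full-length round only for fragments > 33 bp
                length = n
            else:
                if n < stage.prefix_length:
                    continue
                length = stage.prefix_length
            hits = align_prefix(frag, genome, length, stage.max_mismatches)
            if len(hits) == 1:
                chrom, pos, strand, mm = hits[0]
                mappings.append(FragmentMapping(
                    frag.library, frag.side, chrom, pos, strand, idx, mm,
                    frag.read_count))
                fate = "mapped"
                break
            if len(hits) >= 2:
                fate = "multimapped"
                break
        if fate == "multimapped":
            stats.multimapped += 1
        elif fate == "unmapped":
            stats.unmapped += 1
    return mappings, stats


def import_sam(
    path,
    fragments: dict[str, TrimmedFragment],
    stage_index: int = 0,
) -> list[FragmentMapping]:
    """Translate external aligner output (SAM) into FragmentMappings.

    Records must be named with fragment ids present in `fragments`.
    Unmapped records are skipped; query names with more than one aligned
    record (secondary hits or repeated primaries) are dropped as
    multimappers.  Reverse-strand records are reported at the coordinate
    of the fragment's first base, i.e. the alignment's rightmost base.
    """
    records: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.query_name not in fragments:
                raise ValueError(f"unknown fragment id {rec.query_name!r} in {path}")
            records.setdefault(rec.query_name, []).append(
                (rec.reference_name, rec.reference_start, rec.reference_end,
                 rec.is_reverse, rec.get_tag("NM") if rec.has_tag("NM") else 0))
    mappings = []
    for qname, recs in records.items():
        if len(recs) != 1:
            continue  # multimapper
        chrom, start, end, is_rev, nm = recs[0]
        frag = fragments[qname]
        pos = end - 1 if is_rev else start
        mappings.append(FragmentMapping(
            frag.library, frag.side, chrom, int(pos), "-" if is_rev else "+",
            stage_index, int(nm), frag.read_count))
    mappings.sort(key=lambda m: (m.chrom, m.pos, m.strand, m.library))
    return mappings


def estimate_false_mapping_rate(n: int, length: int, max_mm: int,
                                genome: GenomeIndex, seed: int = 0) -> float:
    """Fraction of uniform random sequences of `length` mapping uniquely.

    Used to validate the length/mismatch cutoffs on a given genome: at the
    default cutoffs the unique-mapping fraction of random sequence should
    be ~0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    unique = 0
    for _ in range(n):
        seq = "".join(rng.choice(bases, size=length))
        if len(align_prefix(seq, genome, length, max_mm)) == 1:
            unique += 1
    return unique / n


def write_mappings_bed(mappings: Iterable[FragmentMapping], path) -> None:
    """Raw-mappings BED track (0-based half-open; strand = mapping strand)."""
    with open(path, "w") as fh:
        for m in sorted(mappings, key=lambda m: (m.chrom, m.pos, m.strand, m.library)):
            fh.write(f"{m.chrom}\t{m.pos}\t{m.pos + 1}\t{m.library}\t"
                     f"{m.read_count}\t{m.strand}\n")
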