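"""Synthetic genomes and insertion screens with known ground truth.

The simulator emulates a Sleeping Beauty junction-fragment sequencing
experiment end to end: a random genome with its TA-dinucleotide sites,
per-library clonal insertions (many reads), late passenger insertions
(1-2 reads), local hops (satellite low-read insertions within 5 kb of a
clonal parent), optional shared-TA and donor-chromosome artifacts, and
planted driver loci shared by a chosen subset of libraries.  Reads are
emitted with the real layout barcode + transposon tag + genomic sequence
(+ linker), from both priming sides, so every pipeline stage — demux,
trimming, the TA-start rule, iterative mapping, orientation resolution,
binning, the clonality cutoff and the CIS scan — is exercised against a
recorded truth table.

All randomness flows from one integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import TrimConfig
from .demux import RawRead, BarcodeSpec, LEFT, RIGHT
from .events import InsertionEvent
from .mapping import GenomeIndex, revcomp

DEFAULT_TAG = "GTGTATGT"
DEFAULT_LINKER = "CTAGCTAG"


@dataclass
class SimGenome:
    """A synthetic reference with its indexed TA insertion sites."""

    genome: GenomeIndex
    ta_positions: dict[str, np.ndarray]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.genome.chrom_names:
                fh.write(f">{name}\n")
                seq = self.genome.sequences[name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.genome.chrom_names:
                fh.write(f"{name}\t{self.genome.chrom_lengths[name]}\n")


def make_genome(length: int, seed: int = 0, chrom_count: int = 1) -> SimGenome:
    """Uniform random ACGT genome of `length` bp over `chrom_count` chromosomes."""
    if length < 10_000:
        raise ValueError("genome length must be >= 10000")
    rng = np.random.default_rng(seed)
    base = length // chrom_count
    sizes = [base] * chrom_count
    sizes[-1] += length - base * chrom_count
    names, seqs, tas = [], {}, {}
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i, size in enumerate(sizes):
        name = f"chr{i + 1}"
        codes = rng.integers(0, 4, size=size)
        seq = alphabet[codes].tobytes().decode()
        names.append(name)
        seqs[name] = seq
        tas[name] = np.nonzero((codes[:-1] == 3) & (codes[1:] == 0))[0]
    return SimGenome(GenomeIndex(names, sizes, seqs), tas)


@dataclass(frozen=True)
class DriverLocus:
    chrom: str
    position: int  # locus centre; carriers insert at TAs within the spread
    orientation: str
    libraries: tuple[str, ...]


@dataclass(frozen=True)
class TruthInsert:
    insert_id: int
    library: str
    chrom: str
    pos: int  # TA coordinate (0-based)
    orientation: str
    reads: int
    kind: str  # clonal | driver | passenger | hop | donor | shared_ta
    parent_id: int | None = None


@dataclass
class ScreenTruth:
    driver_loci: list[DriverLocus]
    inserts: list[TruthInsert]

    def insert_for_read(self, read_id: str) -> TruthInsert:
        """Read ids are 'i<insert_id>_<side>_<n>'."""
        return self.inserts[int(read_id.split("_")[0][1:])]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("insert_id\tlibrary\tchrom\tpos\torientation\treads\tkind\tparent_id\n")
            for t in self.inserts:
                fh.write(f"{t.insert_id}\t{t.library}\t{t.chrom}\t{t.pos}\t"
                         f"{t.orientation}\t{t.reads}\t{t.kind}\t"
                         f"{'' if t.parent_id is None else t.parent_id}\n")


@dataclass
class SimulatedScreen:
    reads: list[RawRead]
    barcode_specs: list[BarcodeSpec]
    metadata: dict[str, list[str]]
    truth: ScreenTruth
    trim_config: TrimConfig


def _draw_ta(rng, sim: SimGenome, chrom: str, margin: int = 200) -> int:
    tas = sim.ta_positions[chrom]
    upper = sim.genome.chrom_lengths[chrom] - margin
    ok = tas[(tas >= margin) & (tas < upper)]
    return int(ok[rng.integers(len(ok))])


def _nearest_ta(sim: SimGenome, chrom: str, target: int, margin: int = 200) -> int:
    tas = sim.ta_positions[chrom]
    upper = sim.genome.chrom_lengths[chrom] - margin
    ok = tas[(tas >= margin) & (tas < upper)]
    return int(ok[np.argmin(np.abs(ok - target))])


def _make_barcodes(rng, n: int, length: int = 6) -> list[str]:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = bases[rng.integers(0, 4, size=length)].tobytes().decode()
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_screen(
    sim: SimGenome,
    n_libraries: int = 20,
    driver_loci: Sequence[DriverLocus] = (),
    clonal_mean: int = 8,
    library_depth_median: float = 30_000.0,
    depth_sigma: float = 0.15,
    clonal_weight_sigma: float = 0.5,
    passenger_rate: float = 30.0,
    local_hop_rate: float = 0.3,
    shared_ta_artifact: bool = False,
    donor_chrom: str | None = None,
    seed: int = 0,
    tag: str = DEFAULT_TAG,
    linker: str = DEFAULT_LINKER,
    driver_spread: int = 2500,
    hop_distance: int = 5000,
) -> SimulatedScreen:
    """Simulate one barcoded screen with recorded truth.

    Each library receives Poisson(clonal_mean) background clonal inserts at
    random TA sites plus its planted driver insertions (a TA within
    +/- driver_spread of each carried locus, carriers of one locus at
    distinct 100-bp regions).  Sequencing emulates a fixed per-library
    depth: ~LN(library_depth_median, depth_sigma) reads are shared among
    the clonal and driver inserts with log-normal clonal weights, so the
    read-fraction cutoff behaves as it does on real data.  Passenger
    inserts (Poisson(passenger_rate) per library) carry 1-2 reads; local
    hops (per clonal/driver insert, probability local_hop_rate, a TA
    within +/- hop_distance) carry 1-5.  Driver positions must be
    plantable at TA sites (raised otherwise).
    """
    rng = np.random.default_rng(seed)
    genome = sim.genome
    libraries = [f"tum{i + 1:02d}" for i in range(n_libraries)]
    barcodes = _make_barcodes(rng, 2 * n_libraries)
    specs = []
    for i, lib in enumerate(libraries):
        specs.append(BarcodeSpec(barcodes[2 * i], f"{lib}-L", LEFT))
        specs.append(BarcodeSpec(barcodes[2 * i + 1], f"{lib}-R", RIGHT))
    bc_for = {(s.library, s.side): s.barcode for s in specs}

    for locus in driver_loci:
        tas = sim.ta_positions[locus.chrom]
        if np.abs(tas - locus.position).min() > driver_spread:
            raise ValueError(f"driver locus at {locus.chrom}:{locus.position} "
                             "has no TA site within the spread")

    inserts: list[TruthInsert] = []

    def add(lib, chrom, pos, orient, reads, kind, parent=None) -> TruthInsert:
        t = TruthInsert(len(inserts), lib, chrom, pos, orient, int(reads), kind, parent)
        inserts.append(t)
        return t

    shared_pos = None
    if shared_ta_artifact:
        chrom = genome.chrom_names[0]
        shared_pos = _draw_ta(rng, sim, chrom)

    # Carriers of one locus insert at distinct 100-bp regions: a true
    # driver under selection is hit across its span, not at one shared TA
    # (the latter is the artifact the region statistic penalises).
    locus_bins: list[set[int]] = [set() for _ in driver_loci]

    for lib in libraries:
        planned: list[tuple[str, int, str, str]] = []  # chrom, pos, orient, kind
        for li, locus in enumerate(driver_loci):
            if lib not in locus.libraries:
                continue
            for _ in range(100):
                target = locus.position + int(rng.integers(-driver_spread,
                                                           driver_spread + 1))
                pos = _nearest_ta(sim, locus.chrom, target)
                if pos // 100 not in locus_bins[li]:
                    break
            locus_bins[li].add(pos // 100)
            orient = locus.orientation if rng.random() < 0.9 else (
                "-" if locus.orientation == "+" else "+")
            planned.append((locus.chrom, pos, orient, "driver"))
        for _ in range(rng.poisson(clonal_mean)):
            chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
            pos = _draw_ta(rng, sim, chrom)
            orient = "+" if rng.random() < 0.5 else "-"
            planned.append((chrom, pos, orient, "clonal"))
        # fixed sequencing depth shared among clonal/driver inserts
        depth = rng.lognormal(np.log(library_depth_median), depth_sigma)
        weights = rng.lognormal(0.0, clonal_weight_sigma, size=len(planned))
        clonal_parents: list[TruthInsert] = []
        for (chrom, pos, orient, kind), w in zip(planned, weights):
            reads = max(10, int(round(w / weights.sum() * depth)))
            clonal_parents.append(add(lib, chrom, pos, orient, reads, kind))
        for parent in clonal_parents:
            if rng.random() < local_hop_rate:
                target = parent.pos + int(rng.integers(-hop_distance, hop_distance + 1))
                pos = _nearest_ta(sim, parent.chrom, target)
                if pos != parent.pos:
                    add(parent.library, parent.chrom, pos, parent.orientation,
                        rng.integers(1, 6), "hop", parent.insert_id)
        for _ in range(rng.poisson(passenger_rate)):
            chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
            pos = _draw_ta(rng, sim, chrom)
            orient = "+" if rng.random() < 0.5 else "-"
            add(lib, chrom, pos, orient, rng.integers(1, 3), "passenger")
        if shared_pos is not None and rng.random() < 0.8:
            add(lib, genome.chrom_names[0], shared_pos, "+",
                rng.integers(20, 200), "shared_ta")
        if donor_chrom is not None:
            centre = _nearest_ta(sim, donor_chrom,
                                 genome.chrom_lengths[donor_chrom] // 2)
            for _ in range(3):
                target = centre + int(rng.integers(-hop_distance, hop_distance + 1))
                pos = _nearest_ta(sim, donor_chrom, target)
                add(lib, donor_chrom, pos, "+", rng.integers(5, 50), "donor")

    reads: list[RawRead] = []
    for t in inserts:
        seq = genome.sequences[t.chrom]
        n_right = int(rng.binomial(t.reads, 0.5))
        for side, count in ((RIGHT, n_right), (LEFT, t.reads - n_right)):
            if count == 0:
                continue
            g = int(rng.integers(25, 70))
            read_len = int(rng.integers(75, 101))
            p = t.pos
            if (side == RIGHT) == (t.orientation == "+"):
                gseq = seq[p : p + g]  # plus-strand capture starting at the TA
            else:
                gseq = revcomp(seq[max(0, p + 2 - g) : p + 2])
            bc = bc_for[(t.library, side)]
            full = (bc + tag + gseq + linker)[:read_len]
            for j in range(count):
                reads.append(RawRead(f"i{t.insert_id}_{side}_{j}", full))

    metadata = {
        "all": list(libraries),
        "grpA": libraries[: n_libraries // 2],
        "grpB": libraries[n_libraries // 2 :],
    }
    return SimulatedScreen(
        reads=reads,
        barcode_specs=specs,
        metadata=metadata,
        truth=ScreenTruth(list(driver_loci), inserts),
        trim_config=TrimConfig(transposon_tag=tag, linker=linker, require_ta=True),
    )


def plan_drivers(
    sim: SimGenome,
    libraries_by_group: dict[str, list[str]],
    carriers: Sequence[int] = (9, 8, 9),
    seed: int = 0,
    min_separation: int = 600_000,
) -> list[DriverLocus]:
    """Place driver loci at well-separated TA sites.

    All loci recruit carriers from the full library set except the last,
    which is restricted to the "grpA" phenotype group (so phenotype-CIS
    association has a planted positive).
    """
    rng = np.random.default_rng(seed)
    genome = sim.genome
    loci: list[DriverLocus] = []
    placed: list[tuple[str, int]] = []
    for i, n_carriers in enumerate(carriers):
        for _ in range(1000):
            chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
            pos = _draw_ta(rng, sim, chrom, margin=10_000)
            if all(c != chrom or abs(p - pos) >= min_separation for c, p in placed):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place driver loci far enough apart")
        placed.append((chrom, pos))
        pool = (libraries_by_group["grpA"] if i == len(carriers) - 1
                else libraries_by_group["all"])
        libs = tuple(sorted(rng.choice(pool, size=n_carriers, replace=False)))
        orient = "+" if rng.random() < 0.5 else "-"
        loci.append(DriverLocus(chrom, pos, orient, libs))
    return loci


def simulate_default_screen(seed: int, genome_length: int = 20_000_000,
                            chrom_count: int = 3, n_libraries: int = 20,
                            **kwargs) -> tuple[SimGenome, SimulatedScreen]:
    """A full screen under the package's standard study conditions:
    20 libraries, three planted driver loci (9/8/9 carriers, the last
    restricted to phenotype grpA), passengers and local hops on."""
    sim = make_genome(genome_length, seed=seed, chrom_count=chrom_count)
    metadata_groups = {
        "all": [f"tum{i + 1:02d}" for i in range(n_libraries)],
    }
    metadata_groups["grpA"] = metadata_groups["all"][: n_libraries // 2]
    drivers = plan_drivers(sim, metadata_groups, seed=seed + 1)
    screen = simulate_screen(sim, n_libraries=n_libraries, driver_loci=drivers,
                             seed=seed + 2, **kwargs)
    return sim, screen


def simulate_random_positions(n: int, genome_size: int, n_libraries: int,
                              seed: int = 0) -> list[InsertionEvent]:
    """Uniform random insertion events for null-control injection.

    Positions are uniform on one pseudo-chromosome of `genome_size` bp,
    libraries and orientations uniform; the result is binned into
    insertion events ready for the CIS scan (no reads involved).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pos = rng.integers(0, genome_size, size=n)
    libs = rng.integers(0, n_libraries, size=n)
    orient = rng.integers(0, 2, size=n)
    acc: dict[tuple[str, str, int, str], tuple[int, set[int]]] = {}
    for p, l, o in zip(pos, libs, orient):
        key = (f"lib{l + 1:04d}", "chr1", int(p) // 100, "+-"[o])
        if key in acc:
            cnt, ps = acc[key]
            ps.add(int(p))
            acc[key] = (cnt + 1, ps)
        else:
            acc[key] = (1, {int(p)})
    return [InsertionEvent(lib, chrom, b, o, cnt, len(ps))
            for (lib, chrom, b, o), (cnt, ps) in sorted(acc.items())]
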