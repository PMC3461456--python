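# Methods

## The statistical model

Insertion events are modelled as uniform, independent placements on the
included genome.  For a scan window of size *w* on a genome of size *G*
with *N* total events, the expected per-window count is

    u = N / (G / w)

and the Poisson probability of *k* events in a window is e⁻ᵘuᵏ/k!.
Candidate windows are not arbitrary: one window is anchored at every
insertion position (a window that does not start at an insertion is
dominated by one that does).  A window's enrichment p-value is therefore
the upper tail over the events *joining* its anchor,

    p_raw = P(X ≥ x − 1 | u),

not P(X ≥ x): the anchoring insertion is given, and using the
unconditional tail would understate the false-positive probability of an
anchored window by a factor of roughly x/u.  Because the window-size plan
(below) deliberately places the integer significance threshold just under
α, that factor translates directly into spurious CIS calls on random
data; with the conditional tail, simulations of 10,000 uniform events on
a 2.5 Gb genome yield zero significant windows in ≈98 % of runs, the
behaviour expected of a family-wise error rate controlled at α = 0.05.

The Bonferroni multiplier is the total number of windows examined: the
number of insertions times the number of window sizes scanned.  Both
choices are isolated in `scan.anchored_window_p` and `scan.call_cis`;
`scan.poisson_upper_tail` itself is the plain tail P(X ≥ x).

### Window-size plan

Scanning one window size cannot serve both tight and broad CISs.  For
each integer event count k = 2, 3, … the plan takes the largest window
w ∈ [10,000, 301,000] (1,000-bp grid) at which k events is still
significant after correction; the distinct maxima form the scanned set
(typically ~6 sizes).  Below 2,000 or above 200,000 total events the
derivation degenerates and six fixed sizes are used instead: 12,500,
25,000, 50,000, 100,000, 200,000, 301,000 bp.

### Three ways to count

Each window is scored under three event definitions, each testing its own
null:

* **insert** — distinct (library, 100-bp bin, orientation) events;
* **library** — distinct contributing libraries: a tumor whose transposon
  re-mobilised locally ("local hopping") contributes several inserts to
  one window but only one library;
* **region** — distinct occupied 100-bp bins: many libraries mapping to a
  single TA is characteristic of false priming or barcode misassignment,
  not selection.

u for the insert and library tests uses the total insert-event count (the
insert total bounds the library events, keeping that test conservative);
u for the region test uses the genome-wide count of distinct occupied
bins.  A reported CIS must be significant under all three (each threshold
is user-definable; default α = 0.05 for each).

### Peak finding and resolution

Per window size, a greedy loop selects the remaining anchored window with
the highest count (ties: lowest genomic coordinate), discards windows
overlapping it, and repeats; significant survivors are kept.  Windows
whose count is below the minimal significant count are pruned before the
loop — at fixed window size significance is monotone in the count, so
pruning provably cannot change the emitted set (the test suite checks
equality against the unpruned exhaustive enumeration).  Across window
sizes, candidates are resolved greedily by ascending raw p-value; on an
exact tie the larger window wins.  All tie-breaks are deterministic, so
identical inputs yield byte-identical CIS tables.

## Upstream processing

**Trimming.**  Barcode and transposon-tag matching are exact by default
(configurable barcode mismatches; `N` never matches).  The linker is cut
at its first full occurrence; partial linker suffixes are left for the
mapping schedule to shorten away.  Sleeping Beauty fragments must start
with TA.

**Mapping.**  Alignments must start at the first base after the
transposon and be unique.  The staged schedule (full length/3 mm, then
33/3, 30/2, 28/1, 24/0) reflects length cutoffs calibrated so that random
sequence does not map uniquely; fragments of ≤ 23 bp are discarded.  A
fragment with two or more hits at its first productive stage is retired
as a multimapper rather than retried shorter — shortening can only gain
hits, never restore uniqueness.  The built-in aligner (pigeonhole 8-mer
seeding over a base-5 rolling-hash index, vectorised Hamming
verification, brute-force fallback for short queries) returns *all* hits
end-to-end and is intended for the simulator-scale genomes used here;
production-scale alignments can be imported from SAM
(`mapping.import_sam`), where reverse-strand records are converted so the
recorded position is always the fragment's first base.

**Events and clonality.**  Orientation is resolved so the insertion is
recorded on the strand whose transcription it can activate ((right, +)
and (left, −) → `+`).  Mappings are binned on fixed genome-anchored
100-bp tiles — floor(pos/100) — per library and orientation.  The
read-fraction cutoff keeps an event iff its reads ≥ fraction × the
library's total mapped reads (≥, per the worked regime where 100,000
reads at 1/10,000 keeps regions with ≥ 10 reads).  Recommended presets:
no cutoff for 454-depth data, 1/10,000 for Illumina-depth data.  Donor
chromosomes (local-hopping hotspots) can be excluded; the scan's genome
size is recomputed as the summed length of the included chromosomes.

## Associations

Presence is binary: a library is "in" a CIS iff it has ≥ 1 insertion
event inside the final CIS interval.  Only CISs with region p below a
filter (default 1e-5) enter the matrix.  Fisher's exact test is two-sided
by default (capturing both co-occurrence and mutual exclusivity), with
Bonferroni and Benjamini–Hochberg corrections applied within each family
(phenotype×CIS, CIS×CIS, phenotype×phenotype; the constant-true "all"
superset column is excluded).  Multiple-testing adjustments are delegated
to statsmodels; the Fisher p-value to scipy; both are cross-checked in
the tests against hand-rolled enumeration oracles.

## Annotation and outputs

Genes from a BED4 file within 20,000 bp of a CIS (edge-to-edge, inclusive;
overlap = distance 0) fill the annotation column, joined in file order
with duplicates removed; no hit yields the fixed string "No results
within a 20,000 bp window".  Records whose name contains `BAD`
(case-sensitive substring) mark known artifact regions — e.g. high-copy
loci misassembled as single copy, or transposon-internal genome sequence
such as the En2 fragment of T2/Onc — and any CIS touching one is
suppressed entirely.  Outputs: raw-mapping BED (read strand), insertion
BED (biological orientation), CIS WIG (height = −log₁₀ region p), CIS
TSV, association TSVs, incidence matrix, and a three-level summary
(project / directional library / library).  All coordinates are 0-based
half-open internally; conversions happen only at I/O boundaries (WIG is
1-based, SAM import converts from 1-based).

## The simulator and what it does (not) show

`simulate.make_genome` draws a uniform-random ACGT genome and indexes its
TA sites.  `simulate.simulate_screen` emulates one multiplexed run:

* **libraries**: 20 tumors, each with Poisson(8) background clonal
  insertions at random TA sites;
* **depth**: each library receives ~LN(30,000, 0.15) reads shared among
  its clonal/driver inserts with log-normal weights — sequencing depth is
  a per-library property, so the clonality cutoff denominator behaves as
  on real data (threshold ≈ 3 reads at 1/10,000);
* **passengers**: Poisson(30) per library at 1–2 reads;
* **local hops**: per clonal insert with probability 0.3, at a TA within
  ±5 kb, 1–5 reads;
* **drivers**: three planted loci with 9/8/9 carrier libraries, each
  carrier at a distinct 100-bp region within ±2.5 kb of the locus (the
  "ideal CIS" geometry: a true driver under selection is hit across its
  span, whereas one shared TA across tumors is an artifact signature);
  the third locus recruits only from the `grpA` phenotype group, giving
  the association test a planted positive.  Carrier counts are set so
  the planted signal is recoverable by design: with a 10-library
  phenotype group, 9 carriers keep the Fisher BH q below 0.05 even when
  a couple of background events contaminate the CIS window;
* **artifacts on demand**: a shared-TA column (many libraries, one TA)
  and a donor-chromosome hop cluster;
* **reads**: emitted from both priming sides with the real layout
  (barcode + tag + genomic + linker), 75–100 bp, with partial linker
  carryover so every mapping stage is exercised.

Default screens use a 20 Mb genome over 3 chromosomes — large enough that
the background event density (~300 events) matches the sparse-insertion
regime of real screens, small enough for the built-in aligner.  The
simulator does **not** model sequencing errors, indels, quality scores,
TA-density heterogeneity, chromatin-driven insertion bias, or multi-copy
genome regions; passing tests therefore demonstrate the statistical
machinery under the stated model, not robustness to those real-data
complications (the `BAD`-region mechanism exists precisely because real
genomes violate the uniform-placement null in known places).

## Validation experiments (sizes as run)

* Poisson tail vs direct pmf summation: x ≤ 100, u ∈ [0.01, 10], ≤ 1e-12.
* Fisher vs full hypergeometric enumeration: all 2×2 tables with
  total ≤ 40.
* Peak finder vs exhaustive anchored-window greedy: 50 instances,
  ≤ 200 events.
* Aligner vs brute-force Hamming scan: 50 kb genomes (property tests) and
  a 1 Mb genome (acceptance), both strands, 0–3 mismatches.
* Null control: 20 seeds × 10,000 uniform events, 2.5 Gb genome
  parameter; ≥ 95% of seeds must yield zero three-way-significant CISs.
* Driver recovery: 10 simulated screens; ≥ 90% of planted loci recovered
  with all three corrected p < 0.05, phenotype association at BH q < 0.05.

## Known limitations

* The built-in aligner is exact but O(candidates × length) per query;
  mammalian-scale genomes should go through an external aligner + SAM
  import.
* Bin edges are genome-anchored, so an insertion pair straddling a
  100-bp boundary can split into two events; the window scan (≥ 10 kb)
  absorbs this at CIS level.
* `merge_projects` sums distinct raw-position counts across projects
  (coordinates are not retained), so `n_raw_positions` is an upper bound
  after merging.
* The window plan derives sizes from the insert-event total only; the
  region-mode u is recomputed per window but shares the plan.
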