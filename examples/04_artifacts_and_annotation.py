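"""Artifact handling: the three counting schemes, donor-chromosome
exclusion, and BAD-region suppression during annotation.

A shared-TA artifact (many libraries, one 100-bp region) is rejected by
the region p-value; a donor-chromosome hop cluster disappears when the
chromosome is excluded; and a CIS overlapping a 'BAD'-named annotation
record is never reported.
"""

import tnscan as T
from tnscan import GeneRecord, ScanConfig, annotate_cis, call_cis, score_window

sim = T.make_genome(2_000_000, seed=8, chrom_count=2)
screen = T.simulate_screen(sim, n_libraries=10, seed=8, passenger_rate=0,
                           local_hop_rate=0, shared_ta_artifact=True,
                           donor_chrom="chr2")

with_donor = T.run_screen(screen.reads, screen.barcode_specs,
                          screen.trim_config, sim.genome)
without = T.run_screen(screen.reads, screen.barcode_specs,
                       screen.trim_config, sim.genome,
                       excluded_chroms=["chr2"])

shared = [t for t in screen.truth.inserts if t.kind == "shared_ta"]
pos = shared[0].pos
print(f"shared-TA artifact at chr1:{pos} hit by "
      f"{len({t.library for t in shared})} libraries")
window = ("chr1", pos // 100 * 100, pos // 100 * 100 + 10_000)
cfg = ScanConfig(genome_size=sim.genome.genome_size)
cis = score_window(window, 10_000, with_donor.project.events, cfg)
print(f"  insert p {cis.p_insert:.2e} | library p {cis.p_library:.2e} "
      f"| region p {cis.p_region:.2e}  (region count {cis.region_count})")
print("  -> the region test alone rejects it; it is never reported as a CIS\n")

donor_cis = [c for c in with_donor.cis if c.chrom == "chr2"]
print(f"donor chr2 hop cluster: {len(donor_cis)} CIS before exclusion, "
      f"{sum(c.chrom == 'chr2' for c in without.cis)} after\n")

# annotation: a nearby gene fills the name column; a 'BAD' record kills
# the CIS outright
target = donor_cis[0]
gene = GeneRecord(target.chrom, target.start - 8_000, target.start - 5_000, "En2")
for extra in ([], [GeneRecord(target.chrom, target.start, target.end, "BADrepeat")]):
    out = annotate_cis(donor_cis, [gene] + extra)
    label = "with BADrepeat" if extra else "plain gene file"
    if out:
        print(f"{label}: {out[0].chrom}:{out[0].start}-{out[0].end} "
              f"-> '{out[0].annotation}'")
    else:
        print(f"{label}: CIS suppressed from the report")
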