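"""Built-in aligner, iterative mapping schedule, and SAM import."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tnscan import (FULL, GenomeIndex, TrimmedFragment, align_prefix,
                    default_schedule, estimate_false_mapping_rate, import_sam,
                    map_iteratively, revcomp)
from tnscan.mapping import MappingStage

from conftest import brute_force_align


def frag(seq, lib="tum1", side="right", n=1):
    return TrimmedFragment(lib, side, seq, n)


class TestSchedule:
    def test_default_schedule(self):
        sched = default_schedule()
        assert len(sched) == 5
        assert sched[0].prefix_length is FULL and sched[0].max_mismatches == 3
        assert (sched[2].prefix_length, sched[2].max_mismatches) == (30, 2)
        assert (sched[4].prefix_length, sched[4].max_mismatches) == (24, 0)

    def test_stage_invariants(self):
        with pytest.raises(ValueError):
            MappingStage(20, 0)
        with pytest.raises(ValueError):
            MappingStage(30, 4)


class TestAlignPrefix:
    def test_planted_exact_hit(self, small_genome):
        g = small_genome.genome
        seq = g.sequences["chr1"][1000:1040]
        hits = align_prefix(frag(seq), g, 40, 0)
        assert hits == [("chr1", 1000, "+", 0)]

    def test_planted_twice(self):
        core = "ACGTTGCAGGCCTATAGGCCTTAACCGGATCGATCGTAGC"
        seq = "TTTT" + core + "GGGG" + core + "AAAA"
        g = GenomeIndex(["c"], [len(seq)], {"c": seq})
        hits = align_prefix(core, g, 40, 0)
        assert [h[1] for h in hits] == [4, 48]

    def test_reverse_strand_position(self, small_genome):
        g = small_genome.genome
        sub = g.sequences["chr1"][2000:2033]
        hits = align_prefix(revcomp(sub), g, 33, 0)
        # fragment's first base sits at the rightmost genome coordinate
        assert ("chr1", 2032, "-", 0) in hits

    def test_mismatch_threshold(self, small_genome):
        g = small_genome.genome
        seq = g.sequences["chr1"][3000:3040]
        mutated = seq[:10] + ("A" if seq[10] != "A" else "C") + seq[11:]
        assert align_prefix(mutated, g, 40, 0) == []
        hits = align_prefix(mutated, g, 40, 1)
        assert hits == [("chr1", 3000, "+", 1)]

    def test_length_exceeding_fragment_raises(self, small_genome):
        with pytest.raises(ValueError):
            align_prefix(frag("TAGG"), small_genome.genome, 10, 0)

    @given(st.integers(0, 10_000), st.integers(0, 3), st.booleans())
    def test_oracle_equivalence(self, small_genome, start, max_mm, rc):
        """The seeded aligner equals a brute-force Hamming scan."""
        g = small_genome.genome
        seq = g.sequences["chr1"][start : start + 33]
        if rc:
            seq = revcomp(seq)
        assert align_prefix(seq, g, 33, max_mm) == brute_force_align(
            seq, g, 33, max_mm)

    @given(st.integers(0, 50))
    def test_oracle_equivalence_multichrom_short(self, two_chrom_genome, i):
        g = two_chrom_genome.genome
        chrom = g.chrom_names[i % 2]
        seq = g.sequences[chrom][i * 37 : i * 37 + 24]
        assert align_prefix(seq, g, 24, 0) == brute_force_align(seq, g, 24, 0)


class TestMapIteratively:
    def test_short_fragments_discarded(self, small_genome):
        maps, stats = map_iteratively(
            [frag(small_genome.genome.sequences["chr1"][100:123])],
            small_genome.genome)
        assert maps == [] and stats.too_short == 1

    def test_stage_assignment(self, small_genome):
        g = small_genome.genome
        ref = g.sequences["chr1"]

        def junk(start, n):
            # guaranteed mismatch at every junk base vs the reference
            flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
            return "".join(flip[b] for b in ref[start : start + n])

        fixtures = {
            # clean 60-mer, unique: full-length stage 1
            1: ref[5000:5060],
            # 33 clean bases + 5 mismatching: >3 mm at full length,
            # clean at 33 bp
            2: ref[6000:6033] + junk(6033, 5),
            # 29 clean + 6 junk: 4 mm within 33 bp, 1 mm within 30 bp
            3: ref[7000:7029] + junk(7029, 6),
            # 27 clean + 7 junk: 3 mm within 30 bp, 1 mm within 28 bp
            4: ref[8000:8027] + junk(8027, 7),
            # 26-mer whose 24-bp prefix is clean: skips to stage 5
            5: ref[9000:9024] + junk(9024, 2),
        }
        for expect, seq in fixtures.items():
            maps, _ = map_iteratively([frag(seq)], g)
            assert len(maps) == 1, f"fixture {expect} did not map"
            assert maps[0].stage_index == expect

    def test_multimapper_retired(self):
        core = "ACGTTGCAGGCCTATAGGCCTTAACCGGATCGATCGTAGC"
        seq = "TTTT" + core + "GGGG" + core + "AAAA"
        g = GenomeIndex(["c"], [len(seq)], {"c": seq})
        maps, stats = map_iteratively([frag(core)], g)
        assert maps == [] and stats.multimapped == 1

    def test_unique_mapping_records_position_and_reads(self, small_genome):
        g = small_genome.genome
        maps, _ = map_iteratively([frag(g.sequences["chr1"][4000:4040], n=7)], g)
        m = maps[0]
        assert (m.chrom, m.pos, m.strand, m.read_count) == ("chr1", 4000, "+", 7)
        assert m.mismatches == 0

    def test_order_independence(self, small_genome):
        g = small_genome.genome
        frags = [frag(g.sequences["chr1"][i : i + 40], lib=f"t{i}")
                 for i in (1000, 2000, 3000, 4000)]
        a, _ = map_iteratively(frags, g)
        b, _ = map_iteratively(frags[::-1], g)
        assert sorted(a, key=str) == sorted(b, key=str)


class TestImportSam:
    SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:50000\n"

    def test_forward_and_reverse_coordinates(self, tmp_path, small_genome):
        frags = {
            "f1": frag("T" * 33, lib="tum1"),
            "f2": frag("A" * 33, lib="tum2", side="left"),
            "f3": frag("C" * 33),
        }
        # f1 forward at 1-based 101 -> 0-based 100
        # f2 reverse, aligned interval 1-based [168, 200] -> first base at 199
        # f3 unmapped
        sam = self.SAM_HEADER + "\n".join([
            "f1\t0\tchr1\t101\t42\t33M\t*\t0\t0\t" + "T" * 33 + "\t*\tNM:i:1",
            "f2\t16\tchr1\t168\t42\t33M\t*\t0\t0\t" + "T" * 33 + "\t*\tNM:i:0",
            "f3\t4\t*\t0\t0\t*\t*\t0\t0\t" + "C" * 33 + "\t*",
        ]) + "\n"
        p = tmp_path / "aln.sam"
        p.write_text(sam)
        maps = import_sam(p, frags)
        assert len(maps) == 2
        by_lib = {m.library: m for m in maps}
        assert (by_lib["tum1"].pos, by_lib["tum1"].strand) == (100, "+")
        assert by_lib["tum1"].mismatches == 1
        assert (by_lib["tum2"].pos, by_lib["tum2"].strand) == (199, "-")

    def test_reverse_position_matches_builtin(self, tmp_path, small_genome):
        g = small_genome.genome
        sub = g.sequences["chr1"][300:333]
        query = revcomp(sub)
        builtin = align_prefix(query, g, 33, 0)
        sam = (self.SAM_HEADER +
               f"f1\t16\tchr1\t301\t42\t33M\t*\t0\t0\t{sub}\t*\tNM:i:0\n")
        p = tmp_path / "aln.sam"
        p.write_text(sam)
        maps = import_sam(p, {"f1": frag(query)})
        assert (maps[0].chrom, maps[0].pos, maps[0].strand) == builtin[0][:3]

    def test_multimapped_dropped_and_unknown_raises(self, tmp_path):
        sam = (self.SAM_HEADER +
               "f1\t0\tchr1\t10\t1\t33M\t*\t0\t0\t" + "A" * 33 + "\t*\n"
               "f1\t256\tchr1\t500\t1\t33M\t*\t0\t0\t" + "A" * 33 + "\t*\n")
        p = tmp_path / "aln.sam"
        p.write_text(sam)
        assert import_sam(p, {"f1": frag("A" * 33)}) == []
        with pytest.raises(ValueError, match="unknown fragment"):
            import_sam(p, {"other": frag("A" * 33)})


class TestFalseMappingRate:
    def test_random_sequence_rarely_maps_at_cutoffs(self, small_genome):
        rate = estimate_false_mapping_rate(200, 33, 3, small_genome.genome, seed=5)
        assert rate <= 0.02

    def test_short_sequences_map_promiscuously(self):
        # 10-mers almost always hit a 2-Mb genome somewhere (mostly multiply)
        from tnscan import make_genome
        g = make_genome(2_000_000, seed=7).genome
        rng = np.random.default_rng(3)
        any_hit = sum(
            bool(align_prefix("".join(rng.choice(list("ACGT"), 10)), g, 10, 0))
            for _ in range(50))
        assert any_hit >= 44

    def test_n_zero_rejected(self, small_genome):
        with pytest.raises(ValueError):
            estimate_false_mapping_rate(0, 33, 3, small_genome.genome)
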