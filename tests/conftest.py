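import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """A 50 kb single-chromosome random genome for alignment tests."""
    from tnscan import make_genome
    return make_genome(50_000, seed=11, chrom_count=1)


@pytest.fixture(scope="session")
def two_chrom_genome():
    from tnscan import make_genome
    return make_genome(60_000, seed=13, chrom_count=2)


def brute_force_align(seq, genome, length, max_mm):
    """Independent oracle: Hamming scan of every offset on both strands."""
    from tnscan import revcomp
    query = seq[:length]
    hits = []
    for chrom in genome.chrom_names:
        ref = genome.sequences[chrom]
        for q, strand in ((query, "+"), (revcomp(query), "-")):
            for i in range(len(ref) - length + 1):
                mm = sum(1 for a, b in zip(ref[i : i + length], q)
                         if a != b or a == "N" or b == "N")
                if mm <= max_mm:
                    pos = i if strand == "+" else i + length - 1
                    hits.append((chrom, pos, strand, mm))
    hits.sort(key=lambda h: (genome.chrom_names.index(h[0]), h[1], h[2]))
    return hits
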