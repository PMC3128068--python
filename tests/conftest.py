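import pytest

from spudsnp.pileup import PiledBase, PileupColumn, PileupResult
from spudsnp.synthetic import generate_cultivar_haplotypes, generate_genome


def make_column(
    ref_base="A",
    bases="",
    quals=30,
    mapq=60,
    three_prime_dists=None,
    ref_name="contig1",
    pos=100,
):
    """Hand-build a pileup column from a base string like 'AAAG'."""
    n = len(bases)
    if isinstance(quals, int):
        quals = [quals] * n
    if isinstance(mapq, int):
        mapq = [mapq] * n
    if three_prime_dists is None:
        three_prime_dists = [30] * n
    piled = [
        PiledBase(b, q, m, d, f"r{i}")
        for i, (b, q, m, d) in enumerate(zip(bases, quals, mapq, three_prime_dists))
    ]
    return PileupColumn(ref_name, pos, ref_base, piled)


def make_result(columns, indel_index=None):
    return PileupResult(
        columns={(c.ref_name, c.pos): c for c in columns},
        indel_index=indel_index or {},
    )


@pytest.fixture(scope="session")
def genome():
    """Ten spliced genes on one chromosome, mixed strands."""
    return generate_genome(10, exons_per_gene=(2, 4), seed=11)


@pytest.fixture(scope="session")
def cultivar(genome):
    return generate_cultivar_haplotypes(
        genome, name="Atlantic", ploidy=4, snp_rate=0.01, nonbiallelic_fraction=0.1, seed=7
    )
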