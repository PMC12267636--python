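import numpy as np
import pytest

from trdar.annotation import GeneModel
from trdar.intervals import GenomicInterval, RegionSet
from trdar.synthetic import SimulationConfig, simulate_genome, simulate_counts


@pytest.fixture(scope="session")
def toy_genes():
    """A hand-laid toy chromosome: genes on both strands with UTR/exon
    structure, leaving clear intergenic space."""
    return [
        GeneModel(
            "geneA",
            "chr1",
            "+",
            (10_000, 14_000),
            exons=((10_000, 10_400), (11_200, 11_800), (13_000, 14_000)),
            five_prime_utrs=((10_000, 10_200),),
            three_prime_utrs=((13_600, 14_000),),
        ),
        GeneModel(
            "geneB",
            "chr1",
            "-",
            (20_000, 23_500),
            exons=((20_000, 20_600), (21_500, 22_100), (23_000, 23_500)),
            five_prime_utrs=((23_200, 23_500),),
            three_prime_utrs=((20_000, 20_300),),
        ),
        GeneModel(
            "geneC",
            "chr2",
            "+",
            (5_000, 8_000),
            exons=((5_000, 5_500), (7_000, 8_000)),
        ),
    ]


@pytest.fixture(scope="session")
def small_sim():
    """One default-condition synthetic dataset, shared across tests."""
    cfg = SimulationConfig(seed=11)
    sim = simulate_genome(cfg)
    counts = simulate_counts(cfg, sim)
    return cfg, sim, counts


def random_region_set(rng, n, chroms=("chr1", "chr2"), span=10_000, width=(20, 400)):
    regions = []
    for i in range(n):
        start = int(rng.integers(0, span))
        w = int(rng.integers(*width))
        regions.append(
            GenomicInterval(
                str(rng.choice(chroms)), start, start + w, id=f"r{i:04d}"
            )
        )
    return RegionSet(regions)
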