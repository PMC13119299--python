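from __future__ import annotations

import numpy as np
import pytest

from regiondiff import GenomeDef, RegionSet


@pytest.fixture
def toy_genome() -> GenomeDef:
    return GenomeDef([("chr1", 1000), ("chr2", 500)])


@pytest.fixture
def desk_genome() -> GenomeDef:
    """The default desk-scale simulation genome: 10 Mb + 5 Mb."""
    return GenomeDef([("chr1", 10_000_000), ("chr2", 5_000_000)])


def random_genome(rng: np.random.Generator) -> GenomeDef:
    n_chrom = int(rng.integers(1, 4))
    return GenomeDef(
        [(f"chr{i + 1}", int(rng.integers(200, 5000))) for i in range(n_chrom)]
    )


def random_region_set(
    genome: GenomeDef, n: int, rng: np.random.Generator, name: str = "rand"
) -> RegionSet:
    ivals = []
    for _ in range(n):
        ci = int(rng.integers(0, len(genome)))
        L = int(genome.lengths[ci])
        start = int(rng.integers(0, L))
        end = int(rng.integers(start + 1, L + 1))
        ivals.append((genome.names[ci], start, end))
    return RegionSet(name, genome, ivals)
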