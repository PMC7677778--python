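import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from hetcorr import simulate as sim


@pytest.fixture(scope="session")
def small_haplome() -> sim.Haplome:
    """5 kb diploid genome with 25 planted heterozygous SNPs."""
    return sim.make_diploid_genome(5000, 25, seed=11)


@pytest.fixture(scope="session")
def haploid_5kb() -> sim.Haplome:
    """5 kb genome without variants (hap1 == hap2)."""
    return sim.make_diploid_genome(5000, 0, seed=7)


@pytest.fixture(scope="session")
def tiling_reads(haploid_5kb) -> sim.ReadSet:
    """Error-free 1 kb reads tiling the 5 kb genome with 500 bp overlaps."""
    g = haploid_5kb.ref
    reads = []
    step, length = 500, 1000
    for idx, start in enumerate(range(0, len(g) - length + 1, step)):
        reads.append(
            sim.Read(
                id=f"t{idx}",
                sequence=g[start : start + length],
                truth_span=(start, start + length, "+", 1),
            )
        )
    return sim.ReadSet(reads)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
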