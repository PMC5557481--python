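import numpy as np
import pytest

from breedscan.core import GenotypeMatrix, MarkerMap


def make_map(n_snps, chrom=1, start=100_000, spacing=10_000):
    """Evenly spaced single-chromosome marker map for handcrafted tests."""
    bp = start + spacing * np.arange(n_snps)
    return MarkerMap(
        chrom=np.full(n_snps, chrom),
        bp=bp,
        snp_id=np.array([f"s{chrom}_{i}" for i in range(n_snps)], dtype=object),
    )


def make_genotypes(dosages, chrom=1, spacing=10_000):
    d = np.asarray(dosages, dtype=np.int8)
    mmap = make_map(d.shape[1], chrom=chrom, spacing=spacing)
    ids = [f"ind{i}" for i in range(d.shape[0])]
    return GenotypeMatrix(dosages=d, sample_ids=ids, map=mmap)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
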