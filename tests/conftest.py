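import numpy as np
import pytest

from selsig.genio import GenotypeMatrix, MarkerMap


def make_markers(n, chrom="1", spacing=10_000, start=10_000):
    pos = start + spacing * np.arange(n)
    return MarkerMap([f"snp{i}" for i in range(n)], [chrom] * n, pos,
                     ["A"] * n, ["G"] * n)


def make_matrix(values, chrom="1", spacing=10_000, sample_prefix="s"):
    values = np.asarray(values, dtype=np.int8)
    markers = make_markers(values.shape[1], chrom=chrom, spacing=spacing)
    ids = [f"{sample_prefix}{i}" for i in range(values.shape[0])]
    return GenotypeMatrix(values, ids, markers)


def random_matrix(rng, n_samples, n_snps, missing_frac=0.0, chroms=("1",)):
    """Random genotype matrix spread over one or more chromosomes."""
    values = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    if missing_frac:
        values[rng.random(values.shape) < missing_frac] = -1
    per = n_snps // len(chroms)
    chrom_col, pos = [], []
    for ci, c in enumerate(chroms):
        k = per if ci < len(chroms) - 1 else n_snps - per * (len(chroms) - 1)
        chrom_col += [c] * k
        pos += list(np.sort(rng.choice(np.arange(1, 10_000_000), size=k,
                                       replace=False)))
    markers = MarkerMap([f"snp{i}" for i in range(n_snps)], chrom_col, pos,
                        ["A"] * n_snps, ["G"] * n_snps, sort=False)
    return GenotypeMatrix(values, [f"s{i}" for i in range(n_samples)], markers)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
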