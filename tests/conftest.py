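import numpy as np
import pytest

from epiweave.intervals import AnnotationParams, GeneModel, GenomicInterval


@pytest.fixture
def ann_params():
    return AnnotationParams()


@pytest.fixture
def two_gene_models():
    """A + strand and a - strand gene on one chromosome, well separated."""
    return [
        GeneModel("geneA", GenomicInterval("chr1", 10_000, 15_000, "+")),
        GeneModel("geneB", GenomicInterval("chr1", 300_000, 308_000, "-")),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240909)


def random_small_genome(rng, n_genes=6, chrom_len=10_000, n_chroms=2):
    """Randomized tiny genome for brute-force comparisons (<= 10 kb chroms)."""
    genes = []
    gid = 0
    for c in range(n_chroms):
        pos = int(rng.integers(0, 500))
        while gid < n_genes * (c + 1) / n_chroms and pos + 400 < chrom_len:
            length = int(rng.integers(200, 900))
            if pos + length >= chrom_len:
                break
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(f"g{gid}", GenomicInterval(f"chr{c+1}", pos, pos + length, strand))
            )
            pos += length + int(rng.integers(100, 1_200))
    return genes


def random_features(rng, n=20, chrom_len=10_000, n_chroms=2):
    feats = []
    for _ in range(n):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, chrom_len - 50))
        end = start + int(rng.integers(1, 400))
        feats.append(GenomicInterval(chrom, start, min(end, chrom_len)))
    return feats
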