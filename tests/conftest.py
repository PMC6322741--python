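import numpy as np
import pytest

from paracne.phospho_io import KinaseList, PeptideID, SpectralCountMatrix


def make_matrix(counts, kinase_genes=(), classes=None, gene_prefix="G"):
    """Build a matrix with one single-site peptide per row.

    Rows whose index is listed in ``kinase_genes`` (by name ``K{i}``) become
    kinase peptides; remaining rows are ``G{i}``.
    """
    counts = np.asarray(counts)
    peptides = []
    for i in range(counts.shape[0]):
        gene = f"K{i}" if i in kinase_genes else f"{gene_prefix}{i}"
        peptides.append(PeptideID(gene, (100 + i,)))
    samples = [f"S{j}" for j in range(counts.shape[1])]
    if classes == "all_tumor":
        classes = {s: "tumor" for s in samples}
    return SpectralCountMatrix(peptides, samples, counts, classes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    counts = np.array(
        [
            [0, 0, 3, 5, 1],
            [1, 0, 2, 4, 0],
            [0, 2, 0, 1, 7],
        ]
    )
    return make_matrix(counts, kinase_genes={0})


@pytest.fixture
def kinase_k0():
    return KinaseList.from_symbols(["K0"])
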