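import numpy as np
import pytest

from raregene_ipwc import GenotypeMatrix, SnpRecord
from raregene_ipwc.partitioning import Partition


@pytest.fixture
def tiny_genotypes() -> GenotypeMatrix:
    """4 individuals x 2 SNPs with hand-settable dosages.

    Column sample MAFs: SNP1 -> 1/8 = 0.125, SNP2 -> 4/8 = 0.5.
    """
    dosages = np.array(
        [
            [1, 1],
            [0, 2],
            [0, 0],
            [0, 1],
        ],
        dtype=np.int8,
    )
    snps = [
        SnpRecord(snp_id="S1", gene="G1", chromosome="1", synonymous=False),
        SnpRecord(snp_id="S2", gene="G1", chromosome="1", synonymous=True),
    ]
    return GenotypeMatrix(dosages, ["i1", "i2", "i3", "i4"], snps)


@pytest.fixture
def two_block_genotypes() -> GenotypeMatrix:
    """Two planted blocks of individuals sharing distinct rare variants."""
    dosages = np.zeros((8, 2), dtype=np.int8)
    dosages[:4, 0] = 1  # block A carries SNP1
    dosages[4:, 1] = 1  # block B carries SNP2
    snps = [
        SnpRecord(snp_id="S1", gene="G", synonymous=False),
        SnpRecord(snp_id="S2", gene="G", synonymous=False),
    ]
    ids = [f"i{j}" for j in range(8)]
    return GenotypeMatrix(dosages, ids, snps)


def make_partition(labels, gene="g") -> Partition:
    labels = np.asarray(labels, dtype=int)
    return Partition(gene=gene, k=int(labels.max()), labels=labels)
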