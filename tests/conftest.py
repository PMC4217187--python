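import pytest

from targetrank.genome import GeneAnnotation, GenomicWindow, SnpLocus
from targetrank.spatial import ContactMap


@pytest.fixture
def mtor_like():
    """A SNP/gene pair mirroring a published validation instance:
    SNP in chr1 bin 12, gene in chr1 bin 11, contact log-ratio 6.84."""
    snp = SnpLocus("rs652625", "chr1", 12_147_937, True)
    gene = GeneAnnotation("2475", "MTOR", "chr1", 11_100_000, 11_260_000)
    cmap = ContactMap()
    cmap.set(GenomicWindow("chr1", 12), GenomicWindow("chr1", 11), 6.84)
    return snp, gene, cmap


@pytest.fixture
def three_gene_universe():
    genes = [
        GeneAnnotation("A", "A", "chr1", 5_000_000, 5_050_000),
        GeneAnnotation("B", "B", "chr1", 20_000_000, 20_050_000),
        GeneAnnotation("C", "C", "chr1", 40_000_000, 40_050_000),
    ]
    return genes
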