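import pytest

from meripeak.models import GeneModel, GenomeInterval


@pytest.fixture
def two_exon_plus():
    """Plus-strand model: exons (99,199) and (299,399), transcript length 200."""
    return GeneModel(
        "geneA",
        "txA",
        "+",
        [GenomeInterval("chr1", 99, 199, "+"), GenomeInterval("chr1", 299, 399, "+")],
    )


@pytest.fixture
def single_exon_minus():
    """Minus-strand single-exon model on (1000, 1200)."""
    return GeneModel("geneM", "txM", "-", [GenomeInterval("chr1", 1000, 1200, "-")])


@pytest.fixture
def coding_model():
    """Single-exon plus-strand model, length 1000, CDS [200, 800)."""
    return GeneModel(
        "geneC", "txC", "+", [GenomeInterval("chr1", 1000, 2000, "+")], 200, 800
    )


def make_model(gene_id, chrom, strand, exon_spans, cds=None):
    exons = [GenomeInterval(chrom, s, e, strand) for s, e in exon_spans]
    if cds is None:
        return GeneModel(gene_id, gene_id + "_tx", strand, exons)
    return GeneModel(gene_id, gene_id + "_tx", strand, exons, cds[0], cds[1])
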