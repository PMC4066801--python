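import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from alueditability.annotations import GeneModel, GenicAlu, RepeatElement

settings.register_profile(
    "repro", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def element():
    """Factory for repeat elements with compact call syntax."""
    counter = [0]

    def _make(start, end, strand="+", chrom="chr1", name="AluSx", id=None):
        counter[0] += 1
        return RepeatElement(id or f"e{counter[0]:03d}", chrom, start, end,
                             strand, name)

    return _make


@pytest.fixture
def simple_gene():
    def _make(gene_id="g1", chrom="chr1", strand="+", tx_start=0, tx_end=10_000,
              exons=None):
        return GeneModel(gene_id, chrom, strand, tx_start, tx_end,
                         tuple(exons or [(tx_start, tx_start + 200),
                                         (tx_end - 200, tx_end)]))

    return _make


@pytest.fixture
def genic(element, simple_gene):
    """One genic Alu inside a plus-strand gene spanning [0, 10000)."""
    gene = simple_gene()

    def _make(start, end, strand="+", name="AluSx", id=None):
        el = element(start, end, strand=strand, name=name, id=id)
        cls = "polyA" if strand == gene.strand else "polyU"
        return GenicAlu(el, gene.gene_id, gene.strand, cls)

    _make.gene = gene
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20140514)
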