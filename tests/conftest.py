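import numpy as np
import pytest

from tftargets import GeneModel, GenomicInterval, Peak, PeakSet, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_915)


@pytest.fixture
def small_config():
    """A reduced-scale simulation for fast end-to-end tests."""
    return SimulationConfig(
        seed=11,
        n_genes=200,
        n_peaks={"tf": 400, "acetyl": 300, "access": 300},
        n_indirect_up=20,
        n_indirect_down=10,
        n_tumor=60,
        n_normal=20,
    )


def make_peaks(triples, condition="N", rpkms=None):
    """PeakSet from (chrom, start, end) triples."""
    peaks = [
        Peak(
            GenomicInterval(c, s, e),
            f"p{i + 1}",
            rpkm=0.0 if rpkms is None else rpkms[i],
        )
        for i, (c, s, e) in enumerate(triples)
    ]
    return PeakSet(condition=condition, peaks=peaks)


def make_gene(gene_id, chrom, start, end, strand="+"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand), strand)


@pytest.fixture
def peak_factory():
    return make_peaks


@pytest.fixture
def gene_factory():
    return make_gene
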