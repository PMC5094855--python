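import numpy as np
import pytest

from sgrnakit import annotations as ann
from sgrnakit import synthetic_fixtures as synth


@pytest.fixture(scope="session")
def toy_reference():
    return synth.make_toy_reference(seed=7, n_genes=14, contig_len=90_000,
                                    gene_spacing=9_000, n_contigs=2)


@pytest.fixture(scope="session")
def toy_annotations(toy_reference):
    out = {}
    for gene in sorted(toy_reference.tss_positions):
        out[gene] = ann.assign_tss(gene, toy_reference.transcripts, toy_reference.peaks)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
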