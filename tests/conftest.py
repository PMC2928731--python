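import numpy as np
import pytest

import haploscope as h


@pytest.fixture
def jc_model():
    return h.SubstModelParams()


@pytest.fixture
def gtr_gi_model():
    return h.SubstModelParams(
        exchangeabilities=[1.0, 4.0, 1.0, 1.0, 4.0, 1.0],
        pi=[0.30, 0.20, 0.22, 0.28],
        alpha=0.101,
        p_inv=0.3,
        K=8,
    )


@pytest.fixture
def small_alignment():
    """Six simulated haplotypes, 500 bp, under the default model."""
    tree = h.simulate_tree(6, seed=2, mean_branch=0.05)
    aln = h.evolve_sequences(tree, h.default_model(), 500, seed=3)
    return aln, tree


@pytest.fixture
def figs1_peaks():
    return h.read_peak_table(h.io.synthetic_figs1_peaks_path())


def make_alignment(seqs: dict) -> h.Alignment:
    return h.Alignment(
        [h.SequenceRecord(id=k, bases=v) for k, v in seqs.items()]
    )


@pytest.fixture
def four_taxon_tree():
    return h.parse_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
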