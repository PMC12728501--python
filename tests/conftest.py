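import pytest

import synlink as sl

RBH_TEXT = """\
COW_gene\tCOW_scaf\tCOW_pos\tHCA_gene\tHCA_scaf\tHCA_pos
cg1\tCOW1\t100\thg1\tHCA2\t5000
cg2\tCOW1\t250\thg2\tHCA2\t1200
cg3\tCOW2\t90\thg3\tHCA1\t777
"""


@pytest.fixture
def rbh_file(tmp_path):
    """Hand-written 3-row, 2-species table with base-pair coordinates."""
    p = tmp_path / "toy.rbh"
    p.write_text(RBH_TEXT)
    return p


@pytest.fixture
def toy_table(rbh_file):
    return sl.read_rbh_table(rbh_file, ["COW", "HCA"], outgroup_tag="COW")


SPECIES4 = ["RES", "EMU", "HCA", "COW"]


def planted_simulation(seed=3, translocation=0.03, loss=0.05, alg_sizes=(30, 30, 30)):
    """Four species descended from an ancestor with planted 30-gene ALGs."""
    anc = sl.AncestralGenome(list(alg_sizes))
    params = {
        t: sl.EvolutionParams(translocation_rate=translocation, loss_rate=loss)
        for t in SPECIES4
    }
    return sl.simulate(anc, params, seed=seed, outgroup="COW")


@pytest.fixture
def planted_sim():
    return planted_simulation()


def shuffled_table(seed, n_genes_per_alg=25, n_algs=8, species=SPECIES4):
    """A structureless table: every species fully translocated independently."""
    anc = sl.AncestralGenome([n_genes_per_alg] * n_algs)
    params = {t: sl.EvolutionParams(translocation_rate=1.0) for t in species}
    return sl.simulate(anc, params, seed=seed, outgroup=species[-1]).table
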