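import numpy as np
import pytest

from polyload.genes import read_gene_table
from polyload.load import read_outgroup_table, read_score_table
from polyload.simulate import simulate_population_vcf
from polyload.vcfio import read_vcf


@pytest.fixture(scope="session")
def population_sim(tmp_path_factory):
    """One default cohort scenario shared across tests (seed fixed)."""
    out = tmp_path_factory.mktemp("population")
    return simulate_population_vcf(out, seed=11)


@pytest.fixture(scope="session")
def population_inputs(population_sim):
    """Pipeline inputs re-read from the files the simulator wrote."""
    from Bio import SeqIO

    sim = population_sim
    return {
        "table": read_vcf(sim.vcf),
        "scores": read_score_table(sim.scores),
        "outgroups": read_outgroup_table(sim.outgroups),
        "genes": read_gene_table(sim.genes),
        "sequences": {r.id: str(r.seq) for r in SeqIO.parse(str(sim.fasta), "fasta")},
        "truth": sim.truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
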