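import numpy as np
import pytest

from genehurst.codec import GeneRecord, GenomeSequence
from genehurst.simulate import SyntheticGenomeSpec, generate_genome


@pytest.fixture()
def toy_genome(tmp_path):
    """A tiny hand-written genome + gene table on disk."""
    fasta = tmp_path / "toy.fasta"
    fasta.write_text(">NC_TEST toy replicon\nAAGCTTACGTACGTAAGCTT\n")
    table = tmp_path / "genes.tsv"
    table.write_text(
        "gene_id\treplicon_id\tstart\tend\tstrand\tessentiality\n"
        "g1\tNC_TEST\t1\t8\t+\tessential\n"
        "g2\tNC_TEST\t5\t16\t-\tnonessential\n"
        "g3\tNC_TEST\t9\t20\t+\tunknown\n"
    )
    return fasta, table


@pytest.fixture(scope="session")
def small_synthetic():
    """One small synthetic genome shared by file-level tests."""
    return generate_genome(
        SyntheticGenomeSpec(n_essential=10, n_nonessential=30, seed=11)
    )


@pytest.fixture()
def small_synthetic_files(small_synthetic, tmp_path):
    fasta = tmp_path / "syn.fasta"
    genes = tmp_path / "syn_genes.tsv"
    truth = tmp_path / "syn_truth.tsv"
    small_synthetic.write(fasta, genes, truth)
    return fasta, genes, truth


def as_records(genome):
    """GenomeSequence + GeneRecord view of an in-memory SyntheticGenome."""
    genomes = [GenomeSequence(genome.replicon_id, genome.residues)]
    genes = [
        GeneRecord(
            r["gene_id"], genome.replicon_id, r["start"], r["end"],
            r["strand"], r["essentiality"],
        )
        for r in genome.gene_rows
    ]
    return genomes, genes


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230915)
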