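import pytest

from metaribo import (
    FamilySpec,
    SignalModel,
    simulate_abundances,
    simulate_community,
)


@pytest.fixture(scope="session")
def small_community():
    """A 3-taxon community with 40 planted genes and filled abundances."""
    genomes, truth = simulate_community(
        n_taxa=3, genome_length_nt=20_000, n_genes=40, smorf_fraction=0.3, seed=101
    )
    simulate_abundances(truth, lognormal_sigma=1.0, seed=102)
    return genomes, truth


@pytest.fixture(scope="session")
def default_signal_model():
    return SignalModel()


@pytest.fixture(scope="session")
def family_community():
    """Five planted 5-member smORF families at 10% pairwise divergence."""
    genomes, truth = simulate_community(
        n_taxa=2,
        genome_length_nt=12_000,
        n_genes=0,
        family_spec=FamilySpec(
            n_families=5, members_per_family=5, aa_divergence=0.10, protein_len_aa=30
        ),
        seed=77,
    )
    return genomes, truth
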