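import pytest

from pangcn.simulate import SimParams, make_triplet


SMALL_TRIPLET = SimParams(
    n_genes=100,
    mean_gene_len_codons=120,
    snp_per_site=0.01,
    planted_duplication_len_bp=4000,
    unique_central_len_bp=3500,
    seed=11,
)


@pytest.fixture(scope="session")
def small_triplet():
    """One modest simulated strain triplet shared across the suite."""
    return make_triplet(SMALL_TRIPLET)


@pytest.fixture(scope="session")
def low_divergence_triplet():
    """Triplet at low divergence for truth-recovery checks."""
    params = SimParams(
        n_genes=150,
        mean_gene_len_codons=200,
        snp_per_site=0.005,
        pseudogenization_rate=0.02,
        planted_duplication_len_bp=5000,
        unique_central_len_bp=3500,
        seed=4,
    )
    return make_triplet(params)
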