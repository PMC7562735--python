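import pytest

from kgec.synthetic_data import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def small_spec():
    # Desk-scale bundle shared across tests; small enough that every stage
    # runs in well under a second.
    return FixtureSpec(n_ppi_genes=600, ppi_mean_degree=6.0,
                       n_disease_genes=120, n_components=50,
                       targets_mean=25.0, frac_targets_in_disease=0.35,
                       n_pathways=30, pathway_size_min=8,
                       pathway_size_max=40, seed=7)


@pytest.fixture(scope="session")
def bundle(small_spec, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    return generate_fixture(small_spec, outdir)
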