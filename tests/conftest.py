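import numpy as np
import pytest

from cpifusion.fixtures import FixtureSpec, make_toy_dataset, make_toy_molecules, make_toy_protein
from cpifusion.graphnet import PNAConfig
from cpifusion.model import FusionConfig, FusionModel, featurize_protein


@pytest.fixture(scope="session")
def toy_molecules():
    return make_toy_molecules(8, seed=11, fp_bits=512)


@pytest.fixture(scope="session")
def toy_protein():
    structure, pdb_text = make_toy_protein(20, seed=7, protein_id="helix20")
    return structure, pdb_text


@pytest.fixture(scope="session")
def small_fusion_config():
    return FusionConfig(
        pna=PNAConfig(hidden_dim=8, n_layers=2, out_dim=8),
        fp_bits=512, fp_embed_dim=8, attn_dim=8, n_heads=2,
        conv1d_channels=4, conv2d_channels=2, head_hidden=8,
        fourier_F=2, max_residues=32, max_atoms=128)


@pytest.fixture(scope="session")
def small_model(small_fusion_config, toy_protein):
    pin = featurize_protein(toy_protein[0], small_fusion_config)
    model = FusionModel(small_fusion_config, np.random.default_rng(42),
                        atom_matrix_width=pin.A.shape[1])
    return model, pin


@pytest.fixture(scope="session")
def planted_dataset():
    """50 compounds x 10 proteins, 200 interactions, planted linear signal."""
    spec = FixtureSpec(n_compounds=50, n_proteins=10, n_interactions=200,
                       noise_sd=0.1, seed=0)
    return make_toy_dataset(spec, fp_bits=512)
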