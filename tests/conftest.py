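import numpy as np
import pytest

from netpharm.synthetic import generate_ligand_universe, generate_query_compounds


@pytest.fixture(scope="session")
def small_universe():
    """20 targets x 8 ligands, moderate within-set similarity."""
    universe, _ = generate_ligand_universe(
        n_targets=20, ligands_per_target=8, fp_length=512,
        within_set_similarity=0.7, seed=11)
    return universe


@pytest.fixture(scope="session")
def actives_and_truth(small_universe):
    compounds, truth = generate_query_compounds(
        small_universe, n_actives=25, n_decoys=10, perturb_bits=10, seed=12)
    return compounds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
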