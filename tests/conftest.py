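import numpy as np
import pytest

from macrodissect import synthetic_data


@pytest.fixture(scope="session")
def toy_reference():
    """Idealised 8-residue macrocycle with crosslink and masks."""
    return synthetic_data.make_toy_macrocycle(8)


@pytest.fixture(scope="session")
def small_bimodal(toy_reference):
    """A 600-frame bimodal ensemble at p=0.3 with ground-truth labels."""
    spec = synthetic_data.EnsembleSpec(
        ligand_id="demo", n_frames=600, p_bioactive=0.3, seed=11
    )
    return synthetic_data.make_bimodal_ensemble(spec, toy_reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
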