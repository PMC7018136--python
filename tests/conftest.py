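import numpy as np
import pytest

from jet2dna.fixtures import FixtureSpec, make_bound_pair, make_pseudo_protein
from jet2dna.pipeline import PredictionConfig, prepare_inputs
from jet2dna.structure import parse_structure


@pytest.fixture(scope="session")
def sphere_fixture():
    """A 150-residue pseudo-protein sphere with a 12-residue planted patch."""
    spec = FixtureSpec(seed=101, n_residues=150, patch_size=12)
    pdb_text, truth = make_pseudo_protein(spec)
    structure = parse_structure(pdb_text, "sphere101")
    return structure, truth


@pytest.fixture(scope="session")
def sphere_inputs(sphere_fixture):
    """Descriptors, adjacency graph and expected size for the sphere fixture."""
    structure, truth = sphere_fixture
    config = PredictionConfig()
    descriptors, graph, expected = prepare_inputs(
        structure, config, truth.conservation
    )
    return structure, truth, config, descriptors, graph, expected


@pytest.fixture(scope="session")
def bound_pair():
    """Bound/free pseudo-protein pair with a DNA duplex over the plant."""
    spec = FixtureSpec(seed=202, n_residues=150, patch_size=12)
    bound_pdb, free_pdb, truth = make_bound_pair(spec)
    return parse_structure(bound_pdb, "bound202"), parse_structure(free_pdb, "free202"), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
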