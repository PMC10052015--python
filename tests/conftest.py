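import warnings

import pytest

from phrscan.simulate import StructureSpec, gen_structure
from phrscan.structure import classify_ligands, read_structure

# planted-geometry verdicts rely on residues without polar side chains
warnings.filterwarnings("ignore", message="residue .* has no polar side-chain atoms")


@pytest.fixture(scope="session")
def mini_structure(tmp_path_factory):
    """Mini structure with one planted contact per ligand class and two planted H-bonds."""
    spec = StructureSpec(
        n_residues=10,
        contacts=[(3, "DNA", 2.6), (7, "FAD", 2.5), (9, "HDF", 2.7)],
        hbonds=[(5, "HDF", 2.9), (2, "DNA", 3.5)],
    )
    outdir = tmp_path_factory.mktemp("mini")
    _, path, truth = gen_structure(spec, seed=7, outdir=outdir)
    s = read_structure(path)
    return s, path, truth


@pytest.fixture(scope="session")
def mini_groups(mini_structure):
    s, _, _ = mini_structure
    return classify_ligands(s, {"FAD": ["FAD"], "HDF": ["HDF"]})
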