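"""Structure parsing and contact-shell geometry."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from phrscan.simulate import StructureSpec, gen_structure
from phrscan.structure import (
    classify_ligands,
    contact_shell,
    read_structure,
    shell_to_table,
    sweep_thresholds,
    table_to_shell,
)

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  C   SER A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   SER A   1       2.000   2.600   0.000  1.00  0.00           O
ATOM      5  CB ASER A   1       2.000  -1.000   1.000  0.60  0.00           C
ATOM      6  CB BSER A   1       2.000  -1.000  -1.000  0.40  0.00           C
END
"""


def test_altloc_highest_occupancy_kept(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    s = read_structure(p)
    cb = s.df[s.df.atom == "CB"]
    assert len(cb) == 1
    assert cb.iloc[0].altloc == "A"
    assert cb.iloc[0].z == pytest.approx(1.0)


def test_read_structure_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_structure(tmp_path / "nope.pdb")
    empty = tmp_path / "empty.pdb"
    empty.write_text("END\n")
    with pytest.raises(ValueError):
        read_structure(empty)


def test_generated_structure_round_trip(mini_structure):
    s, _, truth = mini_structure
    prot = s.residues("protein")
    assert len(prot) == truth["n_residues"]
    assert "".join(prot.resname.map(lambda n: {"ALA": "A", "SER": "S"}.get(n, "X"))) == truth["sequence"]


def test_classify_ligands_groups(mini_structure, mini_groups):
    labels = {g.label for g in mini_groups}
    assert labels == {"DNA", "FAD", "HDF"}
    for g in mini_groups:
        assert len(g.atoms) >= 2


def test_classify_missing_cofactor_lists_available(mini_structure):
    s, _, _ = mini_structure
    with pytest.raises(ValueError, match="XYZ"):
        classify_ligands(s, {"XYZ": ["XYZ"]})


def test_classify_protein_only_warns(tmp_path):
    _, path, _ = gen_structure(StructureSpec(n_residues=3, ligand_labels=()), outdir=tmp_path)
    s = read_structure(path)
    with pytest.warns(UserWarning, match="protein-only"):
        groups = classify_ligands(s, {})
    assert groups == []


def test_planted_fake_cofactor(tmp_path):
    spec = StructureSpec(n_residues=4, contacts=[(2, "XXX", 2.5)], ligand_labels=("XXX",))
    _, path, _ = gen_structure(spec, outdir=tmp_path)
    s = read_structure(path)
    groups = classify_ligands(s, {"XXX": ["XXX"]})
    assert [g.label for g in groups] == ["XXX"]
    shell = contact_shell(s, groups, threshold=2.8)
    assert shell.positions == [2]
    assert shell.entries[0].min_distance == pytest.approx(2.5, abs=1e-6)


def test_planted_contacts_are_exact_minimum_distances(mini_structure, mini_groups):
    s, _, truth = mini_structure
    shell = contact_shell(s, mini_groups, threshold=3.6)
    by_key = {(e.position, e.ligand): e.min_distance for e in shell.entries}
    for c in truth["contacts"]:
        assert by_key[(c["resnum"], c["ligand"])] == pytest.approx(c["distance"], abs=1e-6)


def test_tiny_threshold_gives_empty_shell(mini_structure, mini_groups):
    s, _, _ = mini_structure
    assert contact_shell(s, mini_groups, threshold=0.1).entries == []


def _brute_force_shell(s, groups, threshold, atom_scope="all-heavy"):
    """All-pairs distance scan; independent of the KD-tree implementation."""
    backbone = {"N", "CA", "C", "O", "OXT"}
    prot = s.df[(s.df.entity == "protein") & (s.df.element != "H")]
    if atom_scope == "side-chain-heavy":
        prot = prot[~prot.atom.isin(backbone)]
    out = set()
    for (chain, resnum, icode), res in prot.groupby(["chain", "resnum", "icode"]):
        rxyz = res[["x", "y", "z"]].to_numpy(float)
        for g in groups:
            gxyz = g.atoms[g.atoms.element != "H"][["x", "y", "z"]].to_numpy(float)
            d = np.sqrt(((rxyz[:, None, :] - gxyz[None, :, :]) ** 2).sum(-1))
            if d.min() <= threshold:
                out.add((resnum, g.label))
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("atom_scope", ["all-heavy", "side-chain-heavy"])
def test_shell_matches_brute_force_oracle(tmp_path, seed, atom_scope):
    rng = np.random.default_rng(seed)
    contacts = [(int(r), lab, float(d)) for r, lab, d in zip(
        rng.choice(np.arange(1, 13), size=4, replace=False),
        ["DNA", "FAD", "HDF", "DNA"],
        rng.uniform(2.2, 4.5, size=4),
    )]
    _, path, _ = gen_structure(StructureSpec(n_residues=12, contacts=contacts), seed=seed, outdir=tmp_path / str(seed))
    s = read_structure(path)
    assert s.n_atoms <= 500
    groups = classify_ligands(s, {"FAD": ["FAD"], "HDF": ["HDF"]})
    for threshold in (2.5, 3.0, 4.0):
        shell = contact_shell(s, groups, threshold=threshold, atom_scope=atom_scope)
        assert shell.key_set() == _brute_force_shell(s, groups, threshold, atom_scope)


def test_shell_threshold_monotonicity(mini_structure, mini_groups):
    s, _, _ = mini_structure
    previous = set()
    for t in np.arange(2.0, 4.2, 0.2):
        current = contact_shell(s, mini_groups, threshold=float(t)).key_set()
        assert previous <= current
        previous = current


def test_shell_rigid_motion_invariance(mini_structure, mini_groups):
    s, _, _ = mini_structure
    shell = contact_shell(s, mini_groups, threshold=3.6)
    rot = Rotation.from_euler("xyz", [31, -77, 129], degrees=True).as_matrix()
    s2 = s.transformed(rot, np.array([11.0, -5.0, 3.0]))
    groups2 = classify_ligands(s2, {"FAD": ["FAD"], "HDF": ["HDF"]})
    shell2 = contact_shell(s2, groups2, threshold=3.6)
    assert shell.key_set() == shell2.key_set()
    d1 = {(e.position, e.ligand): e.min_distance for e in shell.entries}
    d2 = {(e.position, e.ligand): e.min_distance for e in shell2.entries}
    for k in d1:
        assert d1[k] == pytest.approx(d2[k], abs=1e-6)


def test_shell_serialization_deterministic(mini_structure, mini_groups):
    s, path, _ = mini_structure
    t1 = shell_to_table(contact_shell(s, mini_groups, threshold=3.6)).to_csv(index=False)
    s2 = read_structure(path)
    groups2 = classify_ligands(s2, {"FAD": ["FAD"], "HDF": ["HDF"]})
    t2 = shell_to_table(contact_shell(s2, groups2, threshold=3.6)).to_csv(index=False)
    assert t1 == t2


def test_shell_table_round_trip(tmp_path, mini_structure, mini_groups):
    s, _, _ = mini_structure
    shell = contact_shell(s, mini_groups, threshold=3.6)
    table = shell_to_table(shell)
    assert list(table.position) == sorted(table.position)
    f = tmp_path / "contacts.csv"
    table.to_csv(f, index=False)
    back = table_to_shell(pd.read_csv(f), threshold=3.6)
    assert back.key_set() == shell.key_set()
    assert [e.min_distance for e in back.entries] == pytest.approx([e.min_distance for e in shell.entries])


def test_empty_shell_table_has_header_only(mini_structure, mini_groups):
    s, _, _ = mini_structure
    table = shell_to_table(contact_shell(s, mini_groups, threshold=0.1))
    assert len(table) == 0
    assert list(table.columns) == ["position", "aa", "ligand", "min_distance_A", "atom_i", "atom_j"]


def test_sweep_matches_direct_computation(mini_structure, mini_groups):
    s, _, _ = mini_structure
    sweep = sweep_thresholds(s, mini_groups, tmin=2.4, tmax=3.6, step=0.2)
    for row in sweep.itertuples(index=False):
        direct = contact_shell(s, mini_groups, threshold=row.threshold)
        assert row.union_residues == direct.union_count


def test_shell_errors(mini_structure, mini_groups):
    s, _, _ = mini_structure
    with pytest.raises(ValueError):
        contact_shell(s, mini_groups, threshold=-1.0)
    with pytest.raises(ValueError):
        contact_shell(s, [], threshold=2.8)
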