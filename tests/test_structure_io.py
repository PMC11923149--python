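"""PDB reading/filtering, alanine mutation and coordinate perturbation."""

import numpy as np
import pytest

from pocketec.structure_io import (
    EmptyStructureError,
    mutate_to_alanine,
    perturb_coordinates,
    read_structure,
    write_structure,
)

# residues chosen so the protein chain has exactly 38 heavy atoms
_RES_ATOMS = {
    "LYS": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"],        # 9
    "TRP": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1",
            "CE2", "CE3", "CZ2", "CZ3", "CH2"],                        # 14
    "GLY": ["N", "CA", "C", "O"],                                      # 4
    "SER": ["N", "CA", "C", "O", "CB", "OG"],                          # 6
    "ALA": ["N", "CA", "C", "O", "CB"],                                # 5
}


def _pdb_line(serial, name, resname, chain, resseq, xyz, record="ATOM",
              altloc=" ", occ=1.0, element=None):
    element = element or name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def _protein_with_waters():
    lines, serial = [], 1
    for i, (res, names) in enumerate(_RES_ATOMS.items()):
        for j, name in enumerate(names):
            lines.append(_pdb_line(serial, name, res, "A", i + 1,
                                   (3.8 * i + 0.1 * j, 0.5 * j, 0.0)))
            serial += 1
    for k in range(10):
        lines.append(_pdb_line(serial, "O", "HOH", "W", 100 + k,
                               (50.0 + k, 0, 0), record="HETATM", element="O"))
        serial += 1
    return "\n".join(lines) + "\nEND\n"


def test_hetatm_waters_discarded_protein_kept():
    s = read_structure(_protein_with_waters())
    assert len(s) == 38
    assert all(a.residue_name != "HOH" for a in s.atoms)


def test_dna_only_file_is_empty():
    lines = [
        _pdb_line(i + 1, "P", res, "B", i + 1, (1.5 * i, 0, 0), element="P")
        for i, res in enumerate(["DA", "DC", "DG", "DT", "DA"])
    ]
    with pytest.raises(EmptyStructureError):
        read_structure("\n".join(lines) + "\nEND\n")


def test_two_chains_kept_in_file_order():
    lines = []
    serial = 1
    for chain, offset in (("A", 0.0), ("B", 20.0)):
        for i in range(3):
            for j, name in enumerate(["N", "CA", "C", "O"]):
                lines.append(_pdb_line(serial, name, "GLY", chain, i + 1,
                                       (offset + 3.8 * i + 0.1 * j, 0, 0)))
                serial += 1
        lines.append("TER")
    s = read_structure("\n".join(lines) + "\nEND\n")
    assert len(s) == 24
    assert [a.chain_id for a in s.atoms] == ["A"] * 12 + ["B"] * 12


def test_altloc_keeps_highest_occupancy():
    lines = [
        _pdb_line(1, "N", "SER", "A", 1, (0, 0, 0)),
        _pdb_line(2, "CA", "SER", "A", 1, (1.0, 0, 0), altloc="A", occ=0.4),
        _pdb_line(3, "CA", "SER", "A", 1, (2.0, 0, 0), altloc="B", occ=0.6),
        _pdb_line(4, "C", "SER", "A", 1, (2.4, 0, 0)),
        _pdb_line(5, "O", "SER", "A", 1, (3.0, 0, 0)),
    ]
    s = read_structure("\n".join(lines) + "\nEND\n")
    ca = [a for a in s.atoms if a.atom_name == "CA"]
    assert len(ca) == 1
    assert ca[0].coord[0] == pytest.approx(2.0)  # the 0.6-occupancy conformer


def test_multi_model_keeps_first_model():
    body = [
        _pdb_line(i + 1, name, "GLY", "A", 1, (float(i), 0, 0))
        for i, name in enumerate(["N", "CA", "C", "O"])
    ]
    shifted = [
        _pdb_line(i + 1, name, "GLY", "A", 1, (float(i) + 10.0, 0, 0))
        for i, name in enumerate(["N", "CA", "C", "O"])
    ]
    text = "MODEL        1\n" + "\n".join(body) + "\nENDMDL\nMODEL        2\n" \
        + "\n".join(shifted) + "\nENDMDL\nEND\n"
    s = read_structure(text)
    assert len(s) == 4
    assert s.atoms[0].coord[0] == pytest.approx(0.0)


def test_hydrogens_dropped_unless_requested():
    lines = [
        _pdb_line(1, "N", "GLY", "A", 1, (0, 0, 0)),
        _pdb_line(2, "CA", "GLY", "A", 1, (1.5, 0, 0)),
        _pdb_line(3, "C", "GLY", "A", 1, (2.9, 0, 0)),
        _pdb_line(4, "O", "GLY", "A", 1, (3.5, 1.0, 0)),
        _pdb_line(5, "H", "GLY", "A", 1, (-0.5, 0.5, 0), element="H"),
        _pdb_line(6, "HA2", "GLY", "A", 1, (1.5, 1.0, 0), element="H"),
    ]
    text = "\n".join(lines) + "\nEND\n"
    assert len(read_structure(text)) == 4
    with_h = read_structure(text, keep_hydrogens=True)
    assert len(with_h) == 6
    assert sum(a.is_hydrogen for a in with_h.atoms) == 2


def test_write_read_round_trip(tmp_path):
    s = read_structure(_protein_with_waters())
    out = tmp_path / "rt.pdb"
    write_structure(s, out)
    s2 = read_structure(out.read_text())
    assert len(s2) == len(s)
    assert [a.atom_name for a in s2.atoms] == [a.atom_name for a in s.atoms]
    np.testing.assert_allclose(s2.coords(), s.coords(), atol=1e-3)


class TestMutateToAlanine:
    def test_poly_alanine_is_fixed_point(self):
        text = "\n".join(
            _pdb_line(5 * i + j + 1, name, "ALA", "A", i + 1,
                      (3.8 * i + 0.2 * j, 0, 0))
            for i in range(3)
            for j, name in enumerate(["N", "CA", "C", "O", "CB"])
        )
        s = read_structure(text + "\nEND\n")
        m = mutate_to_alanine(s)
        assert [a.atom_name for a in m.atoms] == [a.atom_name for a in s.atoms]
        np.testing.assert_array_equal(m.coords(), s.coords())

    def test_lysine_keeps_five_atoms(self):
        s = read_structure(_protein_with_waters())
        lys_key = ("A", 1, "")
        m = mutate_to_alanine(s, [lys_key])
        lys_atoms = [a for a in m.atoms if a.residue_key() == lys_key]
        assert sorted(a.atom_name for a in lys_atoms) == ["C", "CA", "CB", "N", "O"]
        assert all(a.residue_name == "ALA" for a in lys_atoms)

    def test_backbone_coordinates_unchanged(self):
        s = read_structure(_protein_with_waters())
        m = mutate_to_alanine(s)
        for key, atoms in s.residues().items():
            before = {a.atom_name: a.coord for a in atoms if a.atom_name in ("N", "CA", "C", "O")}
            after = {a.atom_name: a.coord for a in m.residues()[key]}
            for name, coord in before.items():
                np.testing.assert_array_equal(after[name], coord)

    def test_empty_selection_returns_input_unchanged(self):
        s = read_structure(_protein_with_waters())
        m = mutate_to_alanine(s, [])
        assert [a.residue_name for a in m.atoms] == [a.residue_name for a in s.atoms]


class TestPerturbCoordinates:
    def test_zero_amplitude_identity(self):
        s = read_structure(_protein_with_waters())
        np.testing.assert_array_equal(perturb_coordinates(s, 0.0, seed=1).coords(), s.coords())

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_displacement_bounded(self, seed):
        s = read_structure(_protein_with_waters())
        p = perturb_coordinates(s, 2.5, seed=seed)
        disp = np.linalg.norm(p.coords() - s.coords(), axis=1)
        assert disp.max() <= 2.5 + 1e-12

    def test_deterministic_under_seed(self):
        s = read_structure(_protein_with_waters())
        a = perturb_coordinates(s, 1.0, seed=42)
        b = perturb_coordinates(s, 1.0, seed=42)
        np.testing.assert_array_equal(a.coords(), b.coords())

    def test_negative_amplitude_rejected(self):
        s = read_structure(_protein_with_waters())
        with pytest.raises(ValueError, match="amplitude"):
            perturb_coordinates(s, -0.1, seed=0)

    def test_atom_count_and_order_preserved(self):
        s = read_structure(_protein_with_waters())
        p = perturb_coordinates(s, 1.0, seed=3)
        assert [a.atom_name for a in p.atoms] == [a.atom_name for a in s.atoms]
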