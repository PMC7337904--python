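"""Structure reading/writing, residue classification and radius tables."""
import numpy as np
import pytest

import ribograft as rg
from ribograft.structure_io import (BONDI, EmptyStructureError, RadiusSet,
                                    Residue, AtomRecord, classify_residue,
                                    parse_config)


def test_cryst1_cell_and_space_group(one_atom_pdb):
    model = rg.read_structure(one_atom_pdb)
    assert model.cell == pytest.approx((37.1, 116.2, 56.8, 90.0, 102.9, 90.0))
    assert model.space_group == "P 1 21 1"


def test_one_atom_roundtrip(one_atom_pdb, tmp_path):
    model = rg.read_structure(one_atom_pdb)
    assert model.n_atoms == 1
    out = tmp_path / "copy.pdb"
    rg.write_structure(model, out)
    again = rg.read_structure(out)
    (_, a1), = model.atoms()
    (_, a2), = again.atoms()
    np.testing.assert_allclose(a1.position, a2.position, atol=1.5e-3)


@pytest.mark.parametrize("form", ["A", "B"])
@pytest.mark.parametrize("fmt", ["pdb", "mmcif"])
def test_fiber_roundtrip(form, fmt, tmp_path):
    model = rg.build_fiber_duplex("GTAGGACCATC", form)
    path = tmp_path / f"duplex.{ 'pdb' if fmt == 'pdb' else 'cif'}"
    rg.write_structure(model, path, format=fmt)
    again = rg.read_structure(path, format=fmt)
    assert again.n_atoms == model.n_atoms
    for (r1, a1), (r2, a2) in zip(model.atoms(), again.atoms()):
        assert a1.name == a2.name
        assert r1.category == r2.category
        np.testing.assert_allclose(a1.position, a2.position, atol=1.5e-3)


def test_classification_covers_all_residues():
    model = rg.build_fiber_duplex("GTAGGACCATC", "A", hybrid="strand1_rna")
    cats = [r.category for r in model.residues()]
    assert all(c in ("DNA", "RNA", "protein", "water", "metal", "other")
               for c in cats)
    assert cats.count("RNA") == 11 and cats.count("DNA") == 11


def test_classify_rules():
    rna = Residue("A", 1, "A")
    rna.atoms = [AtomRecord(n, n[0], [0, 0, 0]) for n in
                 ("O2'", "C1'", "C4'", "N1", "N9")]
    assert classify_residue(rna) == "RNA"
    dna = Residue("A", 1, "DA")
    dna.atoms = [AtomRecord(n, n[0], [0, 0, 0]) for n in
                 ("C1'", "C4'", "N9")]
    assert classify_residue(dna) == "DNA"
    metal = Residue("A", 1, "CA")
    metal.atoms = [AtomRecord("CA", "CA", [0, 0, 0])]
    assert classify_residue(metal) == "metal"
    water = Residue("A", 1, "HOH")
    water.atoms = [AtomRecord("O", "O", [0, 0, 0])]
    assert classify_residue(water) == "water"
    prot = Residue("A", 1, "GLY")
    prot.atoms = [AtomRecord(n, n[0], [float(i), 0, 0])
                  for i, n in enumerate(("N", "CA", "C", "O"))]
    assert classify_residue(prot) == "protein"


def test_assign_radii_bondi_and_fallback(caplog):
    model = rg.build_fiber_duplex("GT", "B")
    rg.assign_radii(model)
    for res, atom in model.atoms():
        if atom.element == "C":
            assert atom.vdw_radius == pytest.approx(1.70)
        if atom.element == "O":
            assert atom.vdw_radius == pytest.approx(1.52)
        if atom.element == "P":
            assert atom.vdw_radius == pytest.approx(1.80)
    rs = RadiusSet()
    with caplog.at_level("WARNING"):
        assert rs.radius("X") == rs.default
    assert "no vdW radius" in caplog.text


def test_empty_model_write_errors(tmp_path):
    with pytest.raises(EmptyStructureError):
        rg.write_structure(rg.StructureModel(), tmp_path / "x.pdb")


def test_altloc_keeps_highest_occupancy(tmp_path):
    text = (
        "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.30 10.00"
        "           C\n"
        "ATOM      2  CA BGLY A   1       5.000   0.000   0.000  0.70 10.00"
        "           C\n"
        "END\n")
    path = tmp_path / "alt.pdb"
    path.write_text(text)
    model = rg.read_structure(path)
    (_, atom), = model.atoms()
    assert atom.altloc == "B"
    assert atom.position[0] == pytest.approx(5.0)


def test_parse_config(tmp_path):
    path = tmp_path / "conf"
    path.write_text("radius_set = bondi\nzp_a = 1.5\n"
                    "metal_elements = NA, MG, CA\n# comment\n")
    conf = parse_config(path)
    assert conf["radius_set"] == "bondi"
    assert conf["zp_a"] == 1.5
    assert conf["metal_elements"] == ["NA", "MG", "CA"]
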