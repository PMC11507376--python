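"""Structure parsing, atom selection, and the two-body complex model."""

import numpy as np
import pytest

from edc_compare import (
    Atom,
    CofactorError,
    SelectionError,
    StructureModel,
    center_of_mass,
    pair_calpha,
    read_structure,
    select_calpha,
    select_within_radius,
    split_complex,
    write_pdb,
)
from edc_compare.structures import calpha_records

from helpers import random_rotation


def make_atom(name="CA", element="C", coord=(0, 0, 0), resnum=1, resname="ALA",
              chain="A", mass=12.011, hetero=False):
    return Atom(name, element, np.array(coord, dtype=float), resnum, resname, chain,
                mass, hetero)


class TestReading:
    def test_two_model_fixture_parses_both_models(self, toy_pdb_path):
        models = read_structure(toy_pdb_path)
        assert [m.model_index for m in models] == [1, 2]
        m2 = read_structure(toy_pdb_path, model_index=2)
        assert m2.model_index == 2
        ca = [a for a in m2.atoms if a.name == "CA" and a.chain_id == "A"]
        assert ca[0].coord[0] == pytest.approx(1.558, abs=1e-3)

    def test_waters_dropped_and_hetero_kept(self, toy_pdb_path):
        m1 = read_structure(toy_pdb_path, model_index=1)
        assert not any(a.residue_name == "HOH" for a in m1.atoms)
        assert any(a.element == "Cu" for a in m1.atoms)
        assert any(a.element == "Fe" for a in m1.atoms)

    def test_element_inferred_when_column_absent(self, toy_pdb_path):
        m1 = read_structure(toy_pdb_path, model_index=1)
        gly_ca = next(a for a in m1.atoms if a.residue_name == "GLY")
        assert gly_ca.element == "C"
        assert gly_ca.mass == pytest.approx(12.011, abs=0.01)

    def test_missing_model_index_lists_available(self, toy_pdb_path):
        with pytest.raises(LookupError, match=r"\[1, 2\]"):
            read_structure(toy_pdb_path, model_index=7)

    def test_write_then_read_round_trip(self, tmp_path, rng):
        atoms = [
            make_atom(coord=rng.uniform(-20, 20, 3), resnum=i + 1, chain="A")
            for i in range(50)
        ]
        model = StructureModel(1, atoms, "synthetic")
        write_pdb(model, tmp_path / "rt.pdb")
        back = read_structure(tmp_path / "rt.pdb", model_index=1)
        assert len(back.atoms) == 50
        np.testing.assert_allclose(back.coords, model.coords, atol=1e-3)  # PDB precision
        assert [a.residue_number for a in back.atoms] == [a.residue_number for a in atoms]
        assert all(a.name == "CA" for a in back.atoms)


class TestSplitComplex:
    def test_cofactors_resolved_by_element(self, toy_pdb_path):
        m1 = read_structure(toy_pdb_path, model_index=1)
        cplx = split_complex(m1, mobile_chains={"A"}, anchor_chains={"C"})
        assert cplx.cu_atom.element == "Cu"
        assert cplx.fe_atom.element == "Fe"
        assert cplx.fe_atom.residue_name == "HEC"
        chains_m = {a.chain_id for a in cplx.mobile.atoms}
        chains_a = {a.chain_id for a in cplx.anchor.atoms}
        assert chains_m == {"A"} and chains_a == {"C"}

    def test_duplicate_fe_is_ambiguous_and_listed(self):
        atoms = [make_atom(resnum=i + 1, chain="A", coord=(i * 3.8, 0, 0)) for i in range(3)]
        atoms.append(make_atom("CU", "Cu", (0, 5, 0), 99, "CU", "A", 63.5, True))
        anchor = [make_atom(resnum=i + 1, chain="C", coord=(i * 3.8, 10, 0)) for i in range(3)]
        anchor.append(make_atom("FE", "Fe", (0, 12, 0), 50, "HEC", "C", 55.8, True))
        anchor.append(make_atom("FE2", "Fe", (5, 12, 0), 51, "FES", "C", 55.8, True))
        model = StructureModel(1, atoms + anchor)
        with pytest.raises(CofactorError, match="found 2"):
            split_complex(model, {"A"}, {"C"})
        # but the nearest-Fe policy resolves it
        cplx = split_complex(model, {"A"}, {"C"}, multi_heme="nearest")
        assert cplx.fe_atom.residue_number == 50

    def test_missing_chain_is_a_selection_error(self, toy_pdb_path):
        m1 = read_structure(toy_pdb_path, model_index=1)
        with pytest.raises(SelectionError, match="Z"):
            split_complex(m1, {"Z"}, {"C"})


class TestSelections:
    def test_calpha_in_residue_order_skipping_missing(self):
        atoms = [
            make_atom(resnum=3, coord=(3, 0, 0)),
            make_atom(resnum=1, coord=(1, 0, 0)),
            make_atom(name="CB", resnum=2, coord=(9, 9, 9)),  # residue 2 has no CA
        ]
        coords = select_calpha(StructureModel(1, atoms))
        np.testing.assert_array_equal(coords[:, 0], [1, 3])

    def test_calcium_is_not_a_calpha(self):
        atoms = [make_atom(resnum=i + 1, coord=(i, 0, 0)) for i in range(3)]
        atoms.append(make_atom("CA", "Ca", (9, 9, 9), 50, "CA", "A", 40.08, True))
        assert len(select_calpha(StructureModel(1, atoms))) == 3

    def test_within_radius_matches_brute_force(self, rng):
        atoms = [
            make_atom(resnum=i + 1, coord=rng.uniform(-10, 10, 3)) for i in range(100)
        ]
        model = StructureModel(1, atoms)
        center = np.array([1.0, -2.0, 0.5])
        for radius in (3.0, 6.0, 9.0):
            got = select_within_radius(model, center, radius)
            expected = [a for a in atoms if np.linalg.norm(a.coord - center) <= radius]
            assert sorted(id(a) for a in got) == sorted(id(a) for a in expected)

    def test_within_radius_monotone_in_radius(self, rng):
        atoms = [make_atom(resnum=i + 1, coord=rng.uniform(-5, 5, 3)) for i in range(40)]
        model = StructureModel(1, atoms)
        small = select_within_radius(model, (0, 0, 0), 3.0)
        large = select_within_radius(model, (0, 0, 0), 6.0)
        assert {id(a) for a in small} <= {id(a) for a in large}

    def test_radius_zero_neighbourhood_errors(self):
        model = StructureModel(1, [make_atom(coord=(5, 5, 5))])
        with pytest.raises(SelectionError):
            select_within_radius(model, (0, 0, 0), 0.1)
        got = select_within_radius(model, (5, 5, 5), 0.1)
        assert len(got) == 1


class TestCenterOfMass:
    def test_single_atom_is_its_own_com(self):
        a = make_atom(coord=(1, 2, 3))
        np.testing.assert_allclose(center_of_mass([a]), [1, 2, 3], atol=1e-12)

    def test_equal_masses_midpoint(self):
        atoms = [make_atom(coord=(0, 0, 0)), make_atom(coord=(2, 0, 0), resnum=2)]
        np.testing.assert_allclose(center_of_mass(atoms), [1, 0, 0])

    def test_matches_weighted_sum_loop(self, rng):
        atoms = [
            make_atom(coord=rng.uniform(-10, 10, 3), mass=float(rng.uniform(1, 60)),
                      resnum=i + 1)
            for i in range(20)
        ]
        expected = np.zeros(3)
        total = 0.0
        for a in atoms:
            expected += a.mass * a.coord
            total += a.mass
        np.testing.assert_allclose(center_of_mass(atoms), expected / total, atol=1e-12)

    def test_equivariant_under_rigid_transforms(self, rng):
        atoms = [
            make_atom(coord=rng.uniform(-10, 10, 3), mass=float(rng.uniform(1, 60)),
                      resnum=i + 1)
            for i in range(15)
        ]
        model = StructureModel(1, atoms)
        rot = random_rotation(rng)
        t = rng.uniform(-5, 5, 3)
        moved = model.transformed(rot, t)
        np.testing.assert_allclose(
            center_of_mass(moved), rot @ center_of_mass(model) + t, atol=1e-10
        )


class TestPairing:
    def test_same_numbering_pairs_by_residue_number(self):
        a = StructureModel(1, [make_atom(resnum=i, coord=(i, 0, 0)) for i in (1, 2, 3, 5)])
        b = StructureModel(1, [make_atom(resnum=i, coord=(i, 1, 0)) for i in (2, 3, 4, 5)])
        ca, cb = pair_calpha(a, b)
        assert ca.shape == cb.shape == (3, 3)  # residues 2, 3, 5
        np.testing.assert_array_equal(ca[:, 0], [2, 3, 5])

    def test_homologs_with_shifted_numbering_pair_by_sequence(self):
        # same 6-residue sequence, numbering offset by 100
        seq = ["ALA", "GLY", "SER", "LEU", "VAL", "THR"]
        a = StructureModel(
            1, [make_atom(resnum=i + 1, resname=r, coord=(i * 3.8, 0, 0))
                for i, r in enumerate(seq)])
        b = StructureModel(
            1, [make_atom(resnum=i + 101, resname=r, coord=(i * 3.8, 2, 0))
                for i, r in enumerate(seq)])
        ca, cb = pair_calpha(a, b, mode="auto")
        assert len(ca) == 6
        np.testing.assert_allclose(np.linalg.norm(ca - cb, axis=1), 2.0)

    def test_calpha_records_one_per_residue(self, toy_pdb_path):
        m1 = read_structure(toy_pdb_path, model_index=1)
        recs = calpha_records(m1)
        assert [(r.chain_id, r.residue_number) for r in recs] == [
            ("A", 1), ("A", 2), ("A", 3), ("C", 10), ("C", 11)]
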