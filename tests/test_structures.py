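import numpy as np
import pytest

from ionsaxs.structures import (Atom, AtomicModel, AtomRole, Ensemble,
                                PDBFormatError, assign_accessibility,
                                fibonacci_sphere, read_pdb, write_pdb)
from ionsaxs.synthetic import make_helix


def make_atom(element="C", pos=(0.0, 0.0, 0.0), **kw):
    return Atom(element=element, position=np.array(pos, dtype=float), **kw)


class TestAtom:
    def test_vdw_radius_filled_from_table(self):
        assert make_atom("P").vdw_radius == pytest.approx(1.80)

    def test_rejects_unsupported_element(self):
        with pytest.raises(ValueError, match="unsupported element"):
            make_atom("FE")

    def test_rejects_non_finite_position(self):
        with pytest.raises(ValueError):
            make_atom("C", (np.nan, 0, 0))

    def test_rejects_accessibility_outside_unit_interval(self):
        with pytest.raises(ValueError):
            make_atom("C", solvent_accessibility=1.5)


class TestPDBRoundTrip:
    def test_single_record(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(
            "ATOM      1  P     G A   1       1.000   2.000   3.000"
            "  1.00  0.00           P\nEND\n")
        model = read_pdb(path)
        assert isinstance(model, AtomicModel)
        assert len(model) == 1
        assert model.atoms[0].element == "P"
        assert model.atoms[0].role is AtomRole.RNA

    def test_multi_model_yields_ensemble(self, tmp_path):
        record = ("ATOM      1  P     G A   1       1.000   2.000   3.000"
                  "  1.00  0.00           P")
        body = "".join(f"MODEL     {i:4d}\n{record}\nENDMDL\n" for i in (1, 2, 3))
        path = tmp_path / "mm.pdb"
        path.write_text(body + "END\n")
        ens = read_pdb(path)
        assert isinstance(ens, Ensemble)
        assert len(ens) == 3

    def test_round_trip_preserves_atoms_and_coordinates(self, tmp_path):
        model = make_helix(2, atoms_per_nt=5)  # 20 atoms
        path = tmp_path / "rt.pdb"
        write_pdb(model, [], path)
        back = read_pdb(path)
        assert len(back) == len(model)
        assert back.elements == model.elements
        assert [a.role for a in back.atoms] == [a.role for a in model.atoms]
        # PDB fixed-width coordinates: 3 decimals
        assert np.allclose(back.positions, model.positions, atol=5.1e-4)

    def test_ions_written_as_mg_hetatm(self, tmp_path):
        model = make_helix(2)
        path = tmp_path / "ions.pdb"
        ions = [np.array([30.0, 0.0, 0.0]), np.array([0.0, 30.0, 0.0])]
        write_pdb(model, ions, path)
        back = read_pdb(path)
        mg = [a for a in back.atoms if a.role is AtomRole.MG]
        assert len(mg) == 2
        assert {a.element for a in mg} == {"MG"}
        assert np.allclose(sorted(a.position[0] for a in mg), [0.0, 30.0],
                           atol=5.1e-4)

    def test_zero_ions_preserves_atom_count(self, tmp_path):
        model = make_helix(3)
        path = tmp_path / "same.pdb"
        write_pdb(model, [], path)
        assert len(read_pdb(path)) == len(model)

    def test_waters_recognized(self, tmp_path):
        path = tmp_path / "w.pdb"
        path.write_text(
            "ATOM      1  P     G A   1       1.000   2.000   3.000"
            "  1.00  0.00           P\n"
            "HETATM    2  O   HOH A 101       5.000   5.000   5.000"
            "  1.00  0.00           O\nEND\n")
        model = read_pdb(path)
        roles = [a.role for a in model.atoms]
        assert roles == [AtomRole.RNA, AtomRole.WATER]

    def test_unparseable_file_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(PDBFormatError):
            read_pdb(path)


class TestAccessibility:
    def test_isolated_atom_fully_exposed(self):
        model = AtomicModel([make_atom("C")])
        out = assign_accessibility(model)
        assert out.atoms[0].solvent_accessibility == 1.0

    def test_caged_atom_is_buried(self):
        # one atom at the center of a dense 30-atom cage
        cage = 2.5 * fibonacci_sphere(30)
        atoms = [make_atom("C")] + [make_atom("C", p) for p in cage]
        out = assign_accessibility(AtomicModel(atoms))
        assert out.atoms[0].solvent_accessibility < 0.1

    def test_monotone_under_added_occluders(self):
        occluders = 3.0 * fibonacci_sphere(12)
        prev = 1.0
        for k in (0, 4, 8, 12):
            atoms = [make_atom("C")] + [make_atom("C", p) for p in occluders[:k]]
            acc = assign_accessibility(AtomicModel(atoms)).atoms[0].solvent_accessibility
            assert acc <= prev + 1e-12
            prev = acc

    def test_values_in_unit_interval_and_rigid_motion_invariant(self):
        model = make_helix(4)
        acc = assign_accessibility(model).accessibilities
        assert np.all((0.0 <= acc) & (acc <= 1.0))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = model.transformed(rotation=R, translation=np.array([5.0, -3.0, 2.0]))
        acc2 = assign_accessibility(moved).accessibilities
        assert np.allclose(acc, acc2, atol=1e-6)

    def test_rejects_bad_probe_radius(self, helix):
        with pytest.raises(ValueError):
            assign_accessibility(helix, probe_radius=0.0)
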