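import numpy as np
import pytest

import bindmode as bm
from bindmode.structure_io import (PDBParseError, RosterMismatchError,
                                   SelectionError, SpaceGroupError, Selection,
                                   UnitCell, space_group)
from conftest import toy_atom
from bindmode.structure_io import Model


@pytest.fixture()
def complex_model(receptor, ligand):
    model = Model(atoms=list(receptor.atoms) + list(ligand.atoms),
                  cell=UnitCell(85.368, 85.368, 145.903, 90, 90, 120),
                  spacegroup=space_group("P 65 2 2"))
    return model


class TestReadWrite:
    def test_round_trip_preserves_fields(self, complex_model):
        back = bm.read_pdb(bm.write_pdb(complex_model))
        assert back.roster() == complex_model.roster()
        assert np.allclose(back.coords(), complex_model.coords(), atol=1e-3)
        assert [a.is_het for a in back.atoms] == [a.is_het for a in complex_model.atoms]
        assert [a.element for a in back.atoms] == [a.element for a in complex_model.atoms]
        assert back.cell is not None
        assert np.isclose(back.cell.a, 85.368)
        assert back.spacegroup.hm_symbol == "P 65 2 2"

    def test_cryst1_only_file(self):
        model = bm.read_pdb("CRYST1   50.000   60.000   70.000  90.00  90.00  90.00 P 1\nEND\n")
        assert model.n_atoms == 0
        assert model.cell == UnitCell(50, 60, 70, 90, 90, 90)

    def test_waters_and_het_flagged(self):
        text = bm.write_pdb(Model(atoms=[
            toy_atom(1, "CA", "GLY", 1, (0, 0, 0), "C"),
            toy_atom(2, "O", "HOH", 501, (5, 0, 0), "O", is_het=True, is_water=True),
        ]))
        model = bm.read_pdb(text)
        assert not model.atoms[0].is_water
        assert model.atoms[1].is_water and model.atoms[1].is_het

    def test_malformed_atom_line_names_line_number(self):
        bad = "ATOM      1  CA  GLY A   1      xx.xxx   0.000   0.000  1.00  0.00           C\n"
        with pytest.raises(PDBParseError, match="line 1"):
            bm.read_pdb(bad)

    def test_unknown_space_group_lists_supported(self):
        with pytest.raises(SpaceGroupError, match="P 21 21 21"):
            space_group("Q 9 9 9")

    def test_multi_model_rejected_by_single_reader(self, receptor):
        traj = bm.Trajectory(frames=[receptor, receptor], times=[20.0, 40.0])
        with pytest.raises(PDBParseError, match="MODEL"):
            bm.read_pdb(bm.write_multimodel_pdb(traj))

    def test_altloc_policy(self):
        lines = [
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.60  0.00           C",
            "ATOM      2  CA BGLY A   1       1.000   0.000   0.000  0.40  0.00           C",
            "END",
        ]
        text = "\n".join(lines) + "\n"
        model = bm.read_pdb(text)
        assert model.n_atoms == 1 and model.atoms[0].altloc == "A"
        model_b = bm.read_pdb(text, altloc="B")
        assert model_b.n_atoms == 1 and model_b.atoms[0].x == 1.0


class TestTrajectoryIO:
    def test_times_from_start_and_stride(self, receptor):
        traj = bm.Trajectory(frames=[receptor] * 5, times=20.0 * np.arange(1, 6))
        back = bm.read_multimodel_pdb(bm.write_multimodel_pdb(traj),
                                      start_time=20.0, stride=20.0)
        assert back.n_frames == 5
        assert np.allclose(back.times, [20, 40, 60, 80, 100])
        assert back.times[-1] == 20.0 * back.n_frames

    def test_shared_roster_verified(self, receptor, ligand):
        traj = bm.Trajectory(frames=[receptor] * 3, times=[20.0, 40.0, 60.0])
        back = bm.read_multimodel_pdb(bm.write_multimodel_pdb(traj))
        assert all(f.roster() == back.frames[0].roster() for f in back.frames)

    def test_roster_mismatch_names_model(self, receptor):
        full = bm.write_pdb(receptor).splitlines()
        atoms = [l for l in full if l.startswith(("ATOM", "HETATM"))]
        text = "\n".join(
            ["MODEL        1"] + atoms + ["ENDMDL",
             "MODEL        2"] + atoms[:-1] + ["ENDMDL", "END"]) + "\n"
        with pytest.raises(RosterMismatchError, match="model 2"):
            bm.read_multimodel_pdb(text)


class TestSelect:
    def test_ca_range_on_complete_chain(self):
        model = bm.make_receptor_template(n_res=285, start_resseq=325)
        sel = bm.select(model, names={"CA"}, resseq_range=(325, 609))
        assert len(sel) == 285

    def test_het_not_water_is_the_ligand(self, complex_model):
        sel = bm.select(complex_model, het=True, water=False)
        assert len(sel) == 39  # 26 heavy + 13 hydrogens
        heavy = bm.select(complex_model, het=True, water=False, heavy_only=True)
        assert len(heavy) == 26

    def test_name_list(self, complex_model):
        sel = bm.select(complex_model, names={"OAA", "OAC"})
        assert [complex_model.atoms[i].name for i in sel] == ["OAA", "OAC"]

    def test_idempotent_and_order_stable(self, complex_model):
        a = bm.select(complex_model, het=False, water=False, elements={"N", "O"})
        b = bm.select(complex_model, het=False, water=False, elements={"N", "O"})
        assert a.atom_indices == b.atom_indices
        assert list(a.atom_indices) == sorted(a.atom_indices)

    def test_empty_result_is_not_an_error(self, complex_model):
        assert len(bm.select(complex_model, resnames={"XXX"})) == 0

    def test_parse_selection_expressions(self, complex_model):
        assert len(bm.parse_selection(complex_model, "ca:325-348")) == 24
        assert len(bm.parse_selection(complex_model, "ligand")) == 39
        assert len(bm.parse_selection(complex_model, "name:OAA,OAC")) == 2
        with pytest.raises(SelectionError):
            bm.parse_selection(complex_model, "banana")

    def test_selection_invariants_enforced(self):
        with pytest.raises(SelectionError):
            Selection((3, 1))
        with pytest.raises(SelectionError):
            Selection((1, 1))


class TestSpaceGroups:
    @pytest.mark.parametrize("symbol,n_ops", [("P 1", 1), ("P 21 21 21", 4),
                                              ("P 65 2 2", 12)])
    def test_operator_count_and_identity(self, symbol, n_ops):
        sg = space_group(symbol)
        assert len(sg) == n_ops
        rot0, tran0 = sg.operators[0]
        assert np.array_equal(rot0, np.eye(3, dtype=int))
        assert np.allclose(tran0, 0.0)

    @pytest.mark.parametrize("symbol", ["P 1", "P 21 21 21", "P 65 2 2"])
    def test_rotations_proper_and_closed(self, symbol):
        ops = space_group(symbol).operators
        keyed = {(tuple(map(tuple, r)), tuple(np.round(t % 1.0, 6))) for r, t in ops}
        for r1, t1 in ops:
            assert round(float(np.linalg.det(r1))) == 1
            for r2, t2 in ops:
                comp = (tuple(map(tuple, r1 @ r2)),
                        tuple(np.round((r1 @ t2 + t1) % 1.0, 6)))
                assert comp in keyed

    @pytest.mark.parametrize("symbol", ["P 21 21 21", "P 65 2 2"])
    def test_matches_gemmi_tables(self, symbol):
        import gemmi
        ours = {(tuple(map(tuple, r)), tuple(np.round(t, 6)))
                for r, t in space_group(symbol).operators}
        ref = gemmi.find_spacegroup_by_name(symbol)
        theirs = {(tuple(tuple(v // gemmi.Op.DEN for v in row) for row in op.rot),
                   tuple(np.round(np.array(op.tran) / gemmi.Op.DEN, 6)))
                  for op in ref.operations()}
        assert ours == theirs

    def test_aliases(self):
        assert space_group("P6522").hm_symbol == "P 65 2 2"
        assert space_group("P212121").hm_symbol == "P 21 21 21"
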