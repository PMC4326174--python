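"""PDB-dialect I/O, the selection grammar and tabular round-trips."""

import numpy as np
import pandas as pd
import pytest

from allostery.structio import (NonbondParamTable, PDBParseError, Selection,
                                SelectionError, Structure, StructureError,
                                read_params, read_series, read_structure,
                                read_trajectory, resolve_selection,
                                write_params, write_series, write_structure,
                                write_trajectory)
from conftest import make_structure

PDB_3ATOMS = """\
ATOM      1  N   GLY A  10       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  GLY A  10       2.500  -1.250   0.125  1.00  0.00           C
HETATM    3 CA    CA A 100       9.000   9.000   9.000  1.00  0.00          CA
END
"""

PDB_2MODELS = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       1.000   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       0.000   0.000   1.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       1.000   0.000   1.000  1.00  0.00           C
ENDMDL
END
"""


class TestReadStructure:
    def test_reads_printed_coordinates(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(PDB_3ATOMS)
        s = read_structure(p)
        assert len(s) == 3
        np.testing.assert_allclose(s.atoms[0].position, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(s.atoms[1].position, [2.5, -1.25, 0.125])
        assert s.atoms[2].residue_name == "CA"  # HETATM calcium kept
        assert s.atoms[1].chain_id == "A"
        assert s.atoms[2].residue_number == 100

    def test_first_model_only(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(PDB_2MODELS)
        s = read_structure(p)
        assert len(s) == 2
        np.testing.assert_allclose(s.atoms[0].position, [0, 0, 0])

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")

    def test_no_atom_records(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(PDBParseError, match="no ATOM"):
            read_structure(p)

    def test_malformed_coordinate_names_line(self, tmp_path):
        bad = PDB_3ATOMS.replace("   2.500", "  xx.500")
        p = tmp_path / "bad.pdb"
        p.write_text(bad)
        with pytest.raises(PDBParseError, match="line 2"):
            read_structure(p)

    def test_insertion_code_rejected(self, tmp_path):
        line = "ATOM      1  CA  GLY A  10A      1.000   2.000   3.000  1.00  0.00           C\n"
        p = tmp_path / "icode.pdb"
        p.write_text(line)
        with pytest.raises(PDBParseError, match="insertion"):
            read_structure(p)

    def test_first_altloc_kept(self, tmp_path):
        text = (
            "ATOM      1  CA AGLY A  10       1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA BGLY A  10       9.000   0.000   0.000  1.00  0.00           C\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        s = read_structure(p)
        assert len(s) == 1
        np.testing.assert_allclose(s.atoms[0].position, [1, 0, 0])

    def test_roundtrip_precision(self, tmp_path):
        rng = np.random.default_rng(5)
        s = make_structure(rng.uniform(-50, 50, (20, 3)))
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_structure(s, p1)
        s2 = read_structure(p1)
        write_structure(s2, p2)
        s3 = read_structure(p2)
        # fixed-width PDB carries 3 decimals
        np.testing.assert_allclose(s2.coords, s.coords, atol=1e-3 / 2)
        np.testing.assert_array_equal(s3.coords, s2.coords)
        assert [a.key for a in s3.atoms] == [a.key for a in s.atoms]

    def test_biotite_agrees_on_written_file(self, tmp_path):
        """Independent reader oracle: biotite parses our output identically."""
        biotite_pdb = pytest.importorskip("biotite.structure.io.pdb")
        rng = np.random.default_rng(11)
        s = make_structure(rng.uniform(-20, 20, (7, 3)))
        p = tmp_path / "x.pdb"
        write_structure(s, p)
        arr = biotite_pdb.PDBFile.read(str(p)).get_structure(model=1)
        np.testing.assert_allclose(np.asarray(arr.coord), read_structure(p).coords,
                                   atol=1e-6)
        assert list(arr.res_id) == [a.residue_number for a in s.atoms]


class TestTrajectoryIO:
    def test_multi_model_read(self, tmp_path):
        p = tmp_path / "t.pdb"
        p.write_text(PDB_2MODELS)
        topo = read_structure(p)
        traj = read_trajectory(p, topo, dt_ns=0.5)
        assert len(traj) == 2
        np.testing.assert_allclose(traj.times, [0.0, 0.5])
        np.testing.assert_allclose(traj.frames[1][:, 2], [1.0, 1.0])

    def test_atom_count_mismatch_names_model(self, tmp_path):
        text = PDB_2MODELS.replace(
            "ATOM      2  CA  ALA A   2       1.000   0.000   1.000  1.00  0.00           C\n",
            "")
        p = tmp_path / "bad.pdb"
        p.write_text(text)
        topo = make_structure(np.zeros((2, 3)) + np.arange(2)[:, None])
        with pytest.raises(PDBParseError, match="MODEL 2"):
            read_trajectory(p, topo)

    def test_write_read_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        topo = make_structure(rng.uniform(-10, 10, (5, 3)))
        from allostery.structio import Trajectory
        frames = [rng.uniform(-10, 10, (5, 3)) for _ in range(4)]
        traj = Trajectory(topo, frames, np.arange(4) * 0.1)
        p = tmp_path / "t.pdb"
        write_trajectory(traj, p)
        back = read_trajectory(p, topo, times=traj.times)
        np.testing.assert_allclose(back.xyz, traj.xyz, atol=1e-3 / 2)

    def test_times_must_increase(self):
        topo = make_structure([[0, 0, 0], [1, 1, 1]])
        from allostery.structio import Trajectory
        with pytest.raises(StructureError, match="increasing"):
            Trajectory(topo, [topo.coords, topo.coords], [1.0, 1.0])


class TestSelections:
    @pytest.mark.parametrize("expr, expected", [
        ("resid 81-89 and name CA", 9),
        ("resid 85", 1),
        ("heavy", 11),
        ("all", 11),
        ("chain A", 11),
        ("resname ALA", 11),
        ("resid 80-83 or resid 88-90", 7),
        ("not resid 81", 10),
        ("(resid 81-84 or resid 86) and name CA", 5),
    ])
    def test_grammar_counts(self, expr, expected):
        s = make_structure(np.arange(33, dtype=float).reshape(11, 3),
                           resid_start=80)
        assert len(resolve_selection(expr, s)) == expected

    def test_deterministic_and_file_ordered(self, toy):
        idx1 = resolve_selection("chain A and resid 122-141", toy.structure)
        idx2 = resolve_selection("chain A and resid 122-141", toy.structure)
        np.testing.assert_array_equal(idx1, idx2)
        assert np.all(np.diff(idx1) > 0)

    def test_generator_region_indices_match_published_selections(self, toy):
        """The generator's own selection strings resolve to its index sets."""
        for name in ("loop", "lec_rigid", "egf", "cr1", "hinge1", "ligand"):
            idx = resolve_selection(toy.selections[name], toy.structure)
            np.testing.assert_array_equal(idx, toy.index_sets[name])

    def test_heavy_excludes_hydrogens(self):
        from allostery.structio import AtomRecord, Structure
        atoms = [
            AtomRecord(1, "CA", "GLY", "A", 1, np.zeros(3), "C"),
            AtomRecord(2, "HA", "GLY", "A", 1, np.ones(3), "H"),
        ]
        s = Structure(atoms)
        assert resolve_selection("heavy", s).tolist() == [0]

    def test_empty_match_is_error(self, tiny_structure):
        with pytest.raises(SelectionError, match="matched no atoms"):
            resolve_selection("resid 999", tiny_structure)

    @pytest.mark.parametrize("expr", ["resid", "bogus 5", "resid 9-5",
                                      "(resid 1", ""])
    def test_parse_errors(self, expr, tiny_structure):
        with pytest.raises(SelectionError):
            resolve_selection(expr, tiny_structure)

    def test_solvent_keyword(self):
        from allostery.structio import AtomRecord, Structure
        atoms = [
            AtomRecord(1, "CA", "GLY", "A", 1, np.zeros(3), "C"),
            AtomRecord(2, "O", "HOH", "W", 2, np.ones(3), "O"),
        ]
        s = Structure(atoms)
        assert resolve_selection("not solvent", s).tolist() == [0]


class TestParamsAndSeries:
    def test_params_roundtrip_and_resolution(self, tmp_path, toy):
        p = tmp_path / "params.csv"
        write_params(toy.params, p)
        table = read_params(p)
        q, eps, rminh = table.resolve(toy.structure)
        assert q.shape == (len(toy.structure),)
        assert np.all(eps >= 0) and np.all(rminh > 0)
        # receptor and ligand rows distinguishable
        assert q[toy.index_sets["ligand"][0]] != q[0]

    def test_missing_param_row_is_error(self, tiny_structure):
        table = NonbondParamTable({("GLY", "N"): (0.0, 0.1, 1.0)})
        with pytest.raises(StructureError, match="no nonbond parameters"):
            table.resolve(tiny_structure)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(StructureError, match="epsilon"):
            NonbondParamTable({("ALA", "CA"): (0.0, -0.1, 1.0)})

    def test_series_roundtrip_9_sig_digits(self, tmp_path):
        rng = np.random.default_rng(3)
        table = {"time_ns": np.arange(10000) * 0.002,
                 "value": rng.normal(scale=123.456, size=10000)}
        p = tmp_path / "s.csv"
        write_series(table, p)
        back = read_series(p)
        assert list(back.columns) == ["time_ns", "value"]
        np.testing.assert_allclose(back["value"], table["value"], rtol=1e-8)

    def test_ragged_columns_rejected(self, tmp_path):
        with pytest.raises(StructureError, match="ragged"):
            write_series({"a": [1, 2], "b": [1]}, tmp_path / "x.csv")

    def test_empty_table_writes_header(self, tmp_path):
        p = tmp_path / "e.csv"
        write_series({"a": [], "b": []}, p)
        assert p.read_text().splitlines()[0] == "a,b"
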