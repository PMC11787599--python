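"""Topology/trajectory parsing, selection algebra, and format round-trips."""

import numpy as np
import pytest

from trajcouple import (
    SegmentMap,
    Trajectory,
    load_topology,
    load_trajectory,
    resolve_selection,
    write_frames_table,
    write_pdb,
)
from trajcouple.errors import DimensionError, ParseError, SelectionError, ValidationError

from conftest import bead_trajectory


class TestLoadTopology:
    def test_toy_pdb_atoms_and_residues(self, toy_pdb):
        topo = load_topology(toy_pdb)
        assert topo.n_atoms == 3
        assert topo.residue_numbers.tolist() == [1, 1, 2]
        assert topo.residue_names.tolist() == ["ALA", "ALA", "GLY"]
        assert topo.masses[0] == pytest.approx(14.007)

    def test_two_models_topology_from_first(self, toy_pdb_2model):
        topo = load_topology(toy_pdb_2model)
        assert topo.n_atoms == 3

    def test_blank_element_inferred_from_name(self, toy_pdb):
        # third atom has no element columns; "CA" names a carbon in ATOM records
        topo = load_topology(toy_pdb)
        assert topo.elements[2] == "C"

    def test_zero_atoms_is_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(ParseError):
            load_topology(p)

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  CA  ALA A   1      bogus   0.000   0.000\n")
        with pytest.raises(ParseError, match="line 1"):
            load_topology(p)


class TestLoadTrajectory:
    def test_multimodel_pdb_frames(self, toy_pdb_2model):
        topo = load_topology(toy_pdb_2model)
        traj = load_trajectory(topo, toy_pdb_2model)
        assert traj.n_frames == 2
        assert traj.coordinates.shape == (2, 3, 3)
        assert traj.coordinates[1, 0, 2] == pytest.approx(1.0)

    def test_frames_table_equals_pdb_route(self, toy_pdb_2model, tmp_path):
        topo = load_topology(toy_pdb_2model)
        via_pdb = load_trajectory(topo, toy_pdb_2model)
        table = tmp_path / "frames.csv"
        write_frames_table(via_pdb, table)
        via_table = load_trajectory(topo, table)
        np.testing.assert_array_equal(via_pdb.coordinates, via_table.coordinates)

    def test_frames_table_round_trip_bitwise(self, tmp_path):
        rng = np.random.default_rng(0)
        coords = np.round(rng.normal(size=(4, 6, 3)) * 10, 6)  # at the written precision
        traj = bead_trajectory(coords)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_frames_table(traj, p1)
        reloaded = load_trajectory(traj.topology, p1)
        np.testing.assert_array_equal(reloaded.coordinates, coords)
        write_frames_table(reloaded, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_xtc_nanometers_become_angstroms(self, tmp_path):
        # write raw nm coordinates through the low-level XTC writer
        from MDAnalysis.lib.formats.libmdaxdr import XTCFile

        path = str(tmp_path / "one.xtc")
        xyz = np.array([[1.0, 2.0, 3.0]], dtype=np.float32)  # nm
        box = np.eye(3, dtype=np.float32) * 10
        with XTCFile(path, "w") as f:
            f.write(xyz, box, 0, 0.0, 1000.0)
            f.write(xyz + 1, box, 1, 10.0, 1000.0)
        traj = load_trajectory(bead_trajectory(np.zeros((1, 1, 3))).topology, path)
        np.testing.assert_allclose(traj.coordinates[0, 0], [10.0, 20.0, 30.0], atol=1e-4)

    def test_atom_count_mismatch(self, toy_pdb_2model, tmp_path):
        traj = bead_trajectory(np.zeros((2, 5, 3)))
        table = tmp_path / "five.csv"
        write_frames_table(traj, table)
        topo3 = load_topology(toy_pdb_2model)
        with pytest.raises(DimensionError):
            load_trajectory(topo3, table)

    def test_nonfinite_coordinate_reports_frame(self):
        coords = np.zeros((3, 2, 3))
        coords[2, 1, 0] = np.nan
        with pytest.raises(ValidationError, match="frame 2"):
            bead_trajectory(coords)


class TestResolveSelection:
    @pytest.fixture
    def system(self):
        traj = bead_trajectory(np.zeros((1, 30, 3)), segment="REC")
        segmap = SegmentMap(
            regions={
                "RECEPTOR": ("REC", (1, 30)),
                "TM3": ("REC", (10, 20)),
                "TM4": ("REC", (21, 25)),
                "ICL3": ("REC", (26, 28)),
                "C-term": ("REC", (29, 30)),
            }
        )
        return traj.topology, segmap

    def test_plain_region(self, system):
        topo, segmap = system
        sel = resolve_selection(topo, segmap, "TM3")
        assert len(sel) == 11
        assert topo.residue_numbers[sel.atom_indices].min() == 10

    def test_difference_counts(self, system):
        topo, segmap = system
        sel = resolve_selection(topo, segmap, "RECEPTOR - ICL3 - C-term")
        assert len(sel) == 30 - 3 - 2

    def test_union_matches_concatenation(self, system):
        topo, segmap = system
        union = resolve_selection(topo, segmap, "TM3 + TM4")
        parts = np.union1d(
            resolve_selection(topo, segmap, "TM3").atom_indices,
            resolve_selection(topo, segmap, "TM4").atom_indices,
        )
        np.testing.assert_array_equal(union.atom_indices, parts)

    def test_union_order_independent_and_idempotent(self, system):
        topo, segmap = system
        a = resolve_selection(topo, segmap, "TM3 + TM4")
        b = resolve_selection(topo, segmap, "TM4 + TM3")
        c = resolve_selection(topo, segmap, "TM3 + TM3 + TM4")
        np.testing.assert_array_equal(a.atom_indices, b.atom_indices)
        np.testing.assert_array_equal(a.atom_indices, c.atom_indices)

    def test_residue_range_token(self, system):
        topo, segmap = system
        sel = resolve_selection(topo, segmap, "10-12")
        assert len(sel) == 3

    def test_unknown_label_and_empty_result(self, system):
        topo, segmap = system
        with pytest.raises(SelectionError):
            resolve_selection(topo, segmap, "TM99")
        with pytest.raises(SelectionError):
            resolve_selection(topo, segmap, "TM3 - TM3")


class TestWritePdb:
    def test_round_trip_through_pdb(self, tmp_path):
        rng = np.random.default_rng(1)
        coords = np.round(rng.normal(size=(2, 4, 3)) * 5, 3)
        traj = bead_trajectory(coords)
        p = tmp_path / "out.pdb"
        write_pdb(traj.topology, traj.coordinates, p)
        topo = load_topology(p)
        back = load_trajectory(topo, p)
        assert topo.n_atoms == 4
        np.testing.assert_allclose(back.coordinates, coords, atol=5e-4)
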