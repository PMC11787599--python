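"""Ligand-residue contact detection and the hotspot rule."""

import numpy as np
import pytest

from trajcouple import (
    ContactConfig,
    ContactTimeline,
    ResidueRef,
    Selection,
    contact_timeline,
    frame_contacts,
    hotspots,
    pathway_report,
    residues_from_selection,
    state_series,
)
from trajcouple.errors import AlignmentError
from trajcouple.geometry import ccd_series
from trajcouple.synthetic import EgressConfig, gen_egress

from conftest import bead_trajectory


def shell_system(distances):
    """One ligand bead at the origin, residue beads at given distances on the x axis."""
    coords = np.array([[[0.0, 0, 0]] + [[d, 0, 0] for d in distances]])
    traj = bead_trajectory(coords)
    lig = Selection("lig", np.array([0]))
    residues = [ResidueRef("A", i + 2, "BEA") for i in range(len(distances))]
    return traj, lig, residues


class TestFrameContacts:
    def test_enumerated_shell_distances(self):
        traj, lig, residues = shell_system([2, 3, 4, 5, 6])
        got = frame_contacts(traj, 0, lig, residues, ContactConfig(cutoff=4.0))
        assert {r.residue_number for r in got} == {2, 3, 4}  # exactly 3 contacts

    @pytest.mark.parametrize("d,expected", [(3.9, True), (4.1, False)])
    def test_cutoff_boundary(self, d, expected):
        traj, lig, residues = shell_system([d])
        got = frame_contacts(traj, 0, lig, residues, ContactConfig(cutoff=4.0))
        assert (len(got) == 1) is expected

    def test_cutoff_monotonicity(self):
        traj, lig, residues = shell_system([1.5, 3.2, 4.8, 7.0])
        small = frame_contacts(traj, 0, lig, residues, ContactConfig(cutoff=3.5))
        large = frame_contacts(traj, 0, lig, residues, ContactConfig(cutoff=5.0))
        assert small <= large

    def test_hydrogens_excluded_by_default(self):
        traj, lig, residues = shell_system([2.0])
        topo = traj.topology
        hydro = type(topo)(
            atom_names=topo.atom_names, elements=np.array(["C", "H"]),
            residue_numbers=topo.residue_numbers, residue_names=topo.residue_names,
            segment_ids=topo.segment_ids, masses=np.array([12.011, 1.008]),
        )
        traj_h = type(traj)(hydro, traj.coordinates, traj.times)
        assert len(frame_contacts(traj_h, 0, lig, residues, ContactConfig())) == 0
        assert len(frame_contacts(traj_h, 0, lig, residues, ContactConfig(include_hydrogens=True))) == 1


class TestTimelineAndHotspots:
    def test_static_system_identical_sets(self):
        traj, lig, residues = shell_system([2, 5])
        multi = type(traj)(traj.topology, np.repeat(traj.coordinates, 4, axis=0),
                           np.arange(4, dtype=float))
        tl = contact_timeline(multi, lig, residues)
        assert len(set(tl.contacts)) == 1

    def test_fraction_conservation(self):
        traj, truth = gen_egress()
        lig = Selection("lig", np.flatnonzero(traj.topology.segment_ids == "LIG"))
        tl = contact_timeline(traj, lig, list(truth.residues))
        per_residue = sum(
            sum(1 for s in tl.contacts if r in s) for r in truth.residues
        )
        per_frame = sum(len(s) for s in tl.contacts)
        assert per_residue == per_frame

    def test_planted_fractions_recovered_exactly(self):
        traj, truth = gen_egress()
        lig = Selection("lig", np.flatnonzero(traj.topology.segment_ids == "LIG"))
        tl = contact_timeline(traj, lig, list(truth.residues))
        for r, want in truth.true_fractions.items():
            got = sum(1 for s in tl.contacts if r in s) / len(tl.contacts)
            assert got == pytest.approx(want, abs=1e-12)

    def test_hotspot_rule_strict_threshold(self):
        res_in = ResidueRef("A", 1, "X")
        res_out = ResidueRef("A", 2, "Y")
        sets = [frozenset({res_in, res_out})] * 20 + [frozenset({res_in})] + [frozenset()] * 79
        tl = ContactTimeline(np.arange(100, dtype=float), tuple(sets), ContactConfig())
        spots = hotspots(tl)
        # 21/100 passes the strict >20% rule, 20/100 does not
        assert [h.residue for h in spots] == [res_in]
        assert spots[0].fraction == pytest.approx(0.21)

    def test_planted_hotspots_exact_set_and_order(self):
        traj, truth = gen_egress(EgressConfig(contact_fractions=(0.5, 0.25, 0.1)))
        lig = Selection("lig", np.flatnonzero(traj.topology.segment_ids == "LIG"))
        tl = contact_timeline(traj, lig, list(truth.residues))
        spots = hotspots(tl)
        assert [h.residue.residue_number for h in spots] == [1, 2]
        assert [h.fraction for h in spots] == [0.5, 0.25]

    def test_empty_contacts_no_error(self):
        tl = ContactTimeline(np.arange(3, dtype=float), (frozenset(),) * 3, ContactConfig())
        assert hotspots(tl) == []


class TestPathwayReport:
    def make_report(self):
        traj, truth = gen_egress()
        topo = traj.topology
        lig = Selection("lig", np.flatnonzero(topo.segment_ids == "LIG"))
        rec = Selection("rec", np.flatnonzero(topo.segment_ids == "REC"))
        tl = contact_timeline(traj, lig, list(truth.residues))
        spots = hotspots(tl)
        ss = state_series(ccd_series(traj, lig, rec), "binding")
        return pathway_report(tl, spots, ss), truth

    def test_phases_and_hotspots(self):
        report, truth = self.make_report()
        assert set(report["phases"]) == {"bound", "intermediate", "unbound"}
        assert [h["fraction"] for h in report["hotspots"]] == [0.5, 0.25]
        total = sum(p["n_frames"] for p in report["phases"].values())
        assert total == report["n_frames"]

    def test_frame_mismatch_error(self):
        traj, truth = gen_egress()
        lig = Selection("lig", np.flatnonzero(traj.topology.segment_ids == "LIG"))
        tl = contact_timeline(traj, lig, list(truth.residues))
        from trajcouple.states import StateSeries

        short = StateSeries(np.arange(3, dtype=float), np.array(["bound"] * 3), "binding")
        with pytest.raises(AlignmentError):
            pathway_report(tl, [], short)

    def test_residues_from_selection(self):
        traj, _ = gen_egress()
        rec = Selection("rec", np.flatnonzero(traj.topology.segment_ids == "REC"))
        residues = residues_from_selection(traj.topology, rec)
        assert len(residues) == 6  # 3 path residues + 3 mirror beads
        assert residues[0] == ResidueRef("REC", 1, "RES")
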