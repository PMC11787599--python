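"""Ligand–residue contacts along trajectories and hotspot extraction.

A receptor residue is "in contact" with the ligand in a frame when the
minimum heavy-atom–heavy-atom distance between them is at or below the
cutoff (default 4.0 Å, the common heavy-atom contact convention — recorded
in every report because the choice is a convention, not a measurement).

A *hotspot* is a residue in contact for strictly more than a set fraction
(default 20%) of the pathway duration — the rule used to rank residues along
ligand dissociation pathways (e.g. the ECL2/ECL3 residues lining the
norepinephrine egress routes out of the β-adrenergic receptors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AlignmentError, SelectionError, ValidationError
from .states import StateSeries
from .trajio import Selection, Topology, Trajectory

__all__ = [
    "ContactConfig",
    "ResidueRef",
    "ContactTimeline",
    "Hotspot",
    "frame_contacts",
    "contact_timeline",
    "hotspots",
    "pathway_report",
    "residues_from_selection",
]


@dataclass(frozen=True)
class ContactConfig:
    cutoff: float = 4.0  # Å, heavy-atom minimum distance
    hotspot_fraction: float = 0.20
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")
        if not (0.0 < self.hotspot_fraction < 1.0):
            raise ValidationError("hotspot_fraction must be in (0, 1)")


@dataclass(frozen=True, order=True)
class ResidueRef:
    segment_id: str
    residue_number: int
    residue_name: str = ""


@dataclass(frozen=True)
class ContactTimeline:
    times: np.ndarray
    contacts: tuple[frozenset, ...]  # per-frame sets of ResidueRef
    config: ContactConfig

    def __post_init__(self) -> None:
        if len(self.times) != len(self.contacts):
            raise ValidationError("times and contact sets must have equal length")


@dataclass(frozen=True)
class Hotspot:
    residue: ResidueRef
    fraction: float


def residues_from_selection(topology: Topology, selection: Selection) -> list[ResidueRef]:
    """Distinct residues covered by a selection, in topology order."""
    seen: dict[tuple, ResidueRef] = {}
    for i in selection.atom_indices:
        key = (topology.segment_ids[i], int(topology.residue_numbers[i]))
        if key not in seen:
            seen[key] = ResidueRef(key[0], key[1], str(topology.residue_names[i]))
    return list(seen.values())


def _residue_atom_indices(
    topology: Topology, residue: ResidueRef, heavy_only: bool
) -> np.ndarray:
    mask = (topology.segment_ids == residue.segment_id) & (
        topology.residue_numbers == residue.residue_number
    )
    if heavy_only:
        mask &= topology.heavy_mask()
    return np.flatnonzero(mask)


def frame_contacts(
    trajectory: Trajectory,
    frame: int,
    ligand_selection: Selection,
    receptor_residues: list[ResidueRef],
    config: ContactConfig = ContactConfig(),
) -> frozenset:
    """Residues whose minimum distance to any ligand atom is ≤ cutoff in one frame."""
    heavy = not config.include_hydrogens
    lig_idx = ligand_selection.atom_indices
    if heavy:
        lig_idx = lig_idx[trajectory.topology.heavy_mask()[lig_idx]]
    if len(lig_idx) == 0:
        raise SelectionError("ligand selection has no (heavy) atoms")
    lig = trajectory.coordinates[frame, lig_idx]
    out = set()
    for res in receptor_residues:
        idx = _residue_atom_indices(trajectory.topology, res, heavy)
        if len(idx) == 0:
            if len(_residue_atom_indices(trajectory.topology, res, False)) == 0:
                raise SelectionError(f"residue {res} resolves to no atoms")
            continue  # hydrogen-only residue: never in heavy-atom contact
        if cdist(lig, trajectory.coordinates[frame, idx]).min() <= config.cutoff:
            out.add(res)
    return frozenset(out)


def contact_timeline(
    trajectory: Trajectory,
    ligand_selection: Selection,
    receptor_residues: list[ResidueRef],
    config: ContactConfig = ContactConfig(),
) -> ContactTimeline:
    """Per-frame contact sets in frame order."""
    sets = tuple(
        frame_contacts(trajectory, f, ligand_selection, receptor_residues, config)
        for f in range(trajectory.n_frames)
    )
    return ContactTimeline(times=trajectory.times, contacts=sets, config=config)


def hotspots(timeline: ContactTimeline, config: ContactConfig | None = None) -> list[Hotspot]:
    """Residues in contact for strictly more than ``hotspot_fraction`` of all frames.

    Fractions are computed over the full pathway duration (not per binding
    phase) and returned sorted descending, ties broken by residue identity.
    """
    cfg = config or timeline.config
    n = len(timeline.contacts)
    counts: dict[ResidueRef, int] = {}
    for s in timeline.contacts:
        for res in s:
            counts[res] = counts.get(res, 0) + 1
    spots = [
        Hotspot(residue=res, fraction=c / n)
        for res, c in counts.items()
        if c / n > cfg.hotspot_fraction  # strict >
    ]
    spots.sort(key=lambda h: (-h.fraction, h.residue))
    return spots


def pathway_report(
    timeline: ContactTimeline,
    spots: list[Hotspot],
    binding_states: StateSeries | None = None,
) -> dict:
    """Machine-readable dissociation-pathway summary.

    Per-phase (bound/intermediate/unbound) contact summaries are included
    when a binding-state series over the same frames is supplied; hotspot
    fractions always refer to the full timeline.
    """
    n = len(timeline.contacts)
    report: dict = {
        "n_frames": n,
        "config": {
            "cutoff": timeline.config.cutoff,
            "hotspot_fraction": timeline.config.hotspot_fraction,
            "include_hydrogens": timeline.config.include_hydrogens,
        },
        "hotspots": [
            {
                "segment": h.residue.segment_id,
                "residue_number": h.residue.residue_number,
                "residue_name": h.residue.residue_name,
                "fraction": h.fraction,
            }
            for h in spots
        ],
    }
    if binding_states is not None:
        if len(binding_states.states) != n:
            raise AlignmentError("binding states and timeline cover different frames")
        phases = {}
        for phase in np.unique(binding_states.states):
            sel = binding_states.states == phase
            residues = set()
            for s, keep in zip(timeline.contacts, sel):
                if keep:
                    residues |= s
            phases[str(phase)] = {
                "n_frames": int(sel.sum()),
                "residues_contacted": sorted(
                    f"{r.segment_id}:{r.residue_number}" for r in residues
                ),
            }
        report["phases"] = phases
    return report
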