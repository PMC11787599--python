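"""Run configuration for the command-line pipeline.

A single YAML file drives every stage; each subcommand reads its own section
plus the shared keys (``seed``, ``output_dir``, ``log_level``). All effective
parameters are echoed into the run manifest so every threshold is auditable
per run. Defaults equal the documented per-module defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ValidationError
from .trajio import (
    SegmentMap,
    Selection,
    Topology,
    Trajectory,
    load_segment_map,
    load_topology,
    load_trajectory,
    resolve_selection,
)

__all__ = ["RunConfig", "selection_from_spec", "marker_selection", "write_manifest"]


@dataclass
class RunConfig:
    raw: dict
    text: str
    path: Path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise ValidationError(f"config file {p} does not exist")
        text = p.read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValidationError("config must be a YAML mapping")
        return cls(raw=raw, text=text, path=p)

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def output_dir(self) -> Path:
        return Path(self.raw.get("output_dir", "trajcouple_out"))

    def section(self, name: str) -> dict:
        sec = self.raw.get(name)
        if sec is None:
            raise ValidationError(f"config has no {name!r} section")
        if not isinstance(sec, dict):
            raise ValidationError(f"config section {name!r} must be a mapping")
        return sec

    def sha256(self) -> str:
        return hashlib.sha256(self.text.encode()).hexdigest()

    def resolve_path(self, value: str) -> Path:
        """Paths in the config are relative to the config file's directory."""
        p = Path(value)
        return p if p.is_absolute() else self.path.parent / p

    def load_system(self, section: dict) -> tuple[Topology, Trajectory, SegmentMap | None]:
        for key in ("topology", "trajectory"):
            if key not in section:
                raise ValidationError(f"section is missing the {key!r} path")
            if not self.resolve_path(section[key]).exists():
                raise ValidationError(f"{key} file {section[key]!r} does not exist")
        topo = load_topology(self.resolve_path(section["topology"]))
        traj = load_trajectory(topo, self.resolve_path(section["trajectory"]))
        segmap = None
        if section.get("segment_map"):
            mp = self.resolve_path(section["segment_map"])
            if not mp.exists():
                raise ValidationError(f"segment map {section['segment_map']!r} does not exist")
            segmap = load_segment_map(mp)
        return topo, traj, segmap


def selection_from_spec(
    topology: Topology, segmap: SegmentMap | None, spec: str, atom_mode: str = "heavy"
) -> Selection:
    """Resolve a region expression; the label ``ALL`` selects every atom."""
    if spec == "ALL":
        mask = np.ones(topology.n_atoms, dtype=bool)
        if atom_mode == "heavy":
            mask &= topology.heavy_mask()
        elif atom_mode == "calpha":
            mask &= topology.calpha_mask()
        return Selection(label="ALL", atom_indices=np.flatnonzero(mask))
    if segmap is None:
        raise ValidationError(f"selection {spec!r} needs a segment_map")
    return resolve_selection(topology, segmap, spec, atom_mode)


def marker_selection(topology: Topology, segmap: SegmentMap, marker: str) -> Selection:
    """Single-residue marker selection; Cα atom when present, else heavy atoms."""
    if marker not in segmap.marker_residues:
        raise ValidationError(f"unknown marker residue {marker!r}")
    seg, resnum = segmap.marker_residues[marker]
    mask = topology.residue_numbers == resnum
    if seg is not None:
        mask &= topology.segment_ids == seg
    ca = mask & topology.calpha_mask()
    chosen = ca if ca.any() else (mask & topology.heavy_mask())
    if not chosen.any():
        raise ValidationError(f"marker {marker!r} resolves to no atoms")
    return Selection(label=marker, atom_indices=np.flatnonzero(chosen))


def write_manifest(out_dir: Path, config: RunConfig, command: str, parameters: dict, outputs: list[str]) -> Path:
    """Write the reproducibility manifest (config hash, version, seed, parameters).

    Deliberately timestamp-free so repeated runs are byte-identical.
    """
    manifest = {
        "command": command,
        "config_sha256": config.sha256(),
        "package_version": __version__,
        "seed": config.seed,
        "parameters": parameters,
        "outputs": sorted(outputs),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
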