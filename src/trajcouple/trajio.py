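"""Topology, trajectory, and segment-annotation I/O.

Reads fixed-width PDB (v3.3 ATOM/HETATM records), DCD/XTC coordinate files
(via MDAnalysis readers), and a plain frames-table CSV; resolves named
receptor/G-protein regions (TM1–TM7, ICL1–3, ECL1–3, C-terminus, Gα α1/α5,
AHD, RD, ...) into ordered atom selections.

Conventions: lengths Å, times ns; residue numbering follows the source PDB
(1-based, no renumbering); only model 1 of a multi-model PDB defines the
topology while every model defines a frame when the same file is passed as a
trajectory.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import ELEMENT_MASSES
from .errors import DimensionError, ParseError, SelectionError, ValidationError

__all__ = [
    "Topology",
    "SegmentMap",
    "Trajectory",
    "Selection",
    "load_topology",
    "load_trajectory",
    "load_segment_map",
    "resolve_selection",
    "write_frames_table",
    "write_pdb",
    "write_series_csv",
    "read_series_csv",
]

#: Decimal places used when writing coordinates to the frames-table format;
#: round-tripping is exact for coordinates already at this granularity.
FRAMES_TABLE_DECIMALS = 6


@dataclass(frozen=True)
class Topology:
    """Ordered atom records of one molecular system.

    Atom indices are implicit and contiguous from 0; residue numbers are the
    1-based numbers of the source PDB.
    """

    atom_names: np.ndarray  # str
    elements: np.ndarray  # str, upper-case symbols
    residue_numbers: np.ndarray  # int
    residue_names: np.ndarray  # str
    segment_ids: np.ndarray  # str
    masses: np.ndarray  # float, amu

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for name in ("elements", "residue_numbers", "residue_names", "segment_ids", "masses"):
            if len(getattr(self, name)) != n:
                raise DimensionError(f"topology field {name!r} has length != {n}")
        if n == 0:
            raise ValidationError("topology has zero atoms")
        if not np.all(self.masses > 0):
            raise ValidationError("topology masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def calpha_mask(self) -> np.ndarray:
        return self.atom_names == "CA"


@dataclass(frozen=True)
class Trajectory:
    """Frames of coordinates (Å) with per-frame times (ns) over a fixed topology."""

    topology: Topology
    coordinates: np.ndarray  # (n_frames, n_atoms, 3), Å
    times: np.ndarray  # (n_frames,), ns, strictly increasing

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise DimensionError(f"coordinates must be (frames, atoms, 3); got {c.shape}")
        if c.shape[0] < 1:
            raise ValidationError("trajectory needs at least one frame")
        if c.shape[1] != self.topology.n_atoms:
            raise DimensionError(
                f"frame atom count {c.shape[1]} != topology atom count {self.topology.n_atoms}"
            )
        bad = ~np.isfinite(c)
        if bad.any():
            frame = int(np.argwhere(bad)[0, 0])
            raise ValidationError(f"non-finite coordinate in frame {frame}")
        t = np.asarray(self.times, dtype=float)
        if t.shape != (c.shape[0],):
            raise DimensionError("times length must equal frame count")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class Selection:
    """Ordered, distinct 0-based atom indices with a human-readable label."""

    label: str
    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.atom_indices, dtype=int)
        if idx.size == 0:
            raise SelectionError(f"selection {self.label!r} is empty")
        if len(np.unique(idx)) != len(idx):
            raise SelectionError(f"selection {self.label!r} has duplicate indices")

    def __len__(self) -> int:
        return len(self.atom_indices)


@dataclass
class SegmentMap:
    """Named regions and marker residues of a system.

    ``regions`` maps labels like ``"TM3"`` or ``"AHD"`` to
    ``(segment_id or None, (first_residue, last_residue))`` inclusive ranges;
    ``marker_residues`` maps names like ``"AHD_marker"`` (e.g. Gα A161) to
    ``(segment_id or None, residue_number)``.
    Ballesteros-Weinstein labels may be attached as free-form metadata; they
    are never used in computation.
    """

    regions: dict[str, tuple[str | None, tuple[int, int]]]
    marker_residues: dict[str, tuple[str | None, int]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def validate(self, topology: Topology) -> None:
        """Check every region resolves to ≥1 atom and every marker to exactly one residue."""
        for label in self.regions:
            sel = resolve_selection(topology, self, label)
            if len(sel) < 1:  # pragma: no cover - resolve_selection already raises
                raise SelectionError(f"region {label!r} resolves to no atoms")
        for name, (seg, resnum) in self.marker_residues.items():
            mask = topology.residue_numbers == resnum
            if seg is not None:
                mask &= topology.segment_ids == seg
            keys = set(
                zip(topology.segment_ids[mask].tolist(), topology.residue_numbers[mask].tolist())
            )
            if len(keys) != 1:
                raise SelectionError(
                    f"marker {name!r} must resolve to exactly one residue; found {len(keys)}"
                )


# --------------------------------------------------------------------------
# PDB parsing
# --------------------------------------------------------------------------

_NAME_ELEMENT_RE = re.compile(r"[A-Za-z]")


def _element_from_name(atom_name: str) -> str:
    """Infer the element from a PDB atom name.

    Standard convention for protein/ligand atoms: strip digits and primes and
    take the first alphabetic character ("CA" → C, "1HB" → H, "OXT" → O).
    Two-letter elements must be given explicitly in columns 77–78.
    """
    m = _NAME_ELEMENT_RE.search(atom_name)
    if m is None:
        raise ParseError(f"cannot infer element from atom name {atom_name!r}")
    return m.group(0).upper()


def _mass_for(element: str) -> float:
    try:
        return ELEMENT_MASSES[element.upper()]
    except KeyError:
        raise ParseError(f"no mass known for element {element!r}") from None


def _parse_pdb_models(path: str | Path):
    """Yield per-model lists of parsed ATOM/HETATM records.

    Returns (records_per_model, fields) where fields are parallel lists for
    model 1 only. A file without MODEL cards is one model.
    """
    models: list[list[tuple]] = []
    current: list[tuple] = []
    in_model = False
    seen_model_card = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    models.append(current)
                    current = []
                in_model = True
                seen_model_card = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"line {lineno}: truncated ATOM/HETATM record")
                try:
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    resnum = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: malformed fixed-width field ({exc})") from None
                segid = line[72:76].strip() if len(line) > 72 else ""
                if not segid:
                    segid = line[21].strip()  # fall back on the chain id
                element = line[76:78].strip() if len(line) > 76 else ""
                if not element:
                    element = _element_from_name(name)
                current.append((name, element.upper(), resnum, resname, segid, x, y, z))
        if current or (not models and not seen_model_card):
            models.append(current)
    models = [m for m in models if m]
    if not models:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return models


def load_topology(path: str | Path) -> Topology:
    """Build a :class:`Topology` from the first model of a PDB file.

    Elements come from columns 77–78 when present, otherwise from the atom
    name; masses come from a built-in element table.
    """
    model1 = _parse_pdb_models(path)[0]
    names, elements, resnums, resnames, segids = [], [], [], [], []
    for name, element, resnum, resname, segid, *_ in model1:
        names.append(name)
        elements.append(element)
        resnums.append(resnum)
        resnames.append(resname)
        segids.append(segid)
    masses = np.array([_mass_for(e) for e in elements])
    return Topology(
        atom_names=np.array(names),
        elements=np.array(elements),
        residue_numbers=np.array(resnums, dtype=int),
        residue_names=np.array(resnames),
        segment_ids=np.array(segids),
        masses=masses,
    )


# --------------------------------------------------------------------------
# Trajectory loading
# --------------------------------------------------------------------------


def _frames_from_pdb(path: str | Path) -> np.ndarray:
    models = _parse_pdb_models(path)
    n_atoms = len(models[0])
    frames = np.empty((len(models), n_atoms, 3))
    for i, model in enumerate(models):
        if len(model) != n_atoms:
            raise DimensionError(
                f"model {i + 1} has {len(model)} atoms, expected {n_atoms}"
            )
        frames[i] = [(rec[5], rec[6], rec[7]) for rec in model]
    return frames


def _frames_from_table(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    required = {"frame", "atom", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ParseError(f"frames table must have columns {sorted(required)}")
    frames_idx = np.sort(df["frame"].unique())
    atoms_idx = np.sort(df["atom"].unique())
    n_frames, n_atoms = len(frames_idx), len(atoms_idx)
    if len(df) != n_frames * n_atoms:
        raise ParseError("frames table is not a complete frame × atom grid")
    df = df.sort_values(["frame", "atom"], kind="stable")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float).reshape(n_frames, n_atoms, 3)
    return coords


def _frames_from_mdanalysis(path: str | Path, fmt: str):
    """Read DCD/XTC coordinates via MDAnalysis; returns (coords Å, times ns or None)."""
    if fmt == "dcd":
        from MDAnalysis.coordinates.DCD import DCDReader as Reader
    else:
        from MDAnalysis.coordinates.XTC import XTCReader as Reader
    coords, times = [], []
    reader = Reader(str(path))
    try:
        for ts in reader:
            coords.append(ts.positions.copy())  # MDAnalysis positions are Å
            times.append(ts.time)  # ps
    finally:
        reader.close()
    arr = np.asarray(coords, dtype=float)
    t = np.asarray(times, dtype=float) / 1000.0  # ps → ns
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        t = None  # unreliable metadata; caller substitutes frame indices
    return arr, t


def load_trajectory(topology: Topology, path: str | Path) -> Trajectory:
    """Load coordinates from DCD, XTC, multi-model PDB, or frames-table CSV.

    Coordinates are stored in Å regardless of source units (XTC nm values are
    converted); times come from source metadata when trustworthy, else
    0, 1, 2, … ns.
    """
    suffix = Path(path).suffix.lower()
    times = None
    if suffix == ".pdb":
        coords = _frames_from_pdb(path)
    elif suffix in (".csv", ".tsv", ".table"):
        coords = _frames_from_table(path)
    elif suffix == ".dcd":
        coords, times = _frames_from_mdanalysis(path, "dcd")
    elif suffix == ".xtc":
        coords, times = _frames_from_mdanalysis(path, "xtc")
    else:
        raise ValidationError(f"unsupported trajectory format {suffix!r}")
    if coords.shape[1] != topology.n_atoms:
        raise DimensionError(
            f"trajectory atom count {coords.shape[1]} != topology atom count {topology.n_atoms}"
        )
    if times is None:
        times = np.arange(coords.shape[0], dtype=float)
    return Trajectory(topology=topology, coordinates=coords, times=times)


# --------------------------------------------------------------------------
# Selections
# --------------------------------------------------------------------------

_RANGE_TOKEN = re.compile(r"^(\d+)-(\d+)$")


def _region_mask(topology: Topology, map_: SegmentMap, token: str) -> np.ndarray:
    m = _RANGE_TOKEN.match(token)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        return (topology.residue_numbers >= lo) & (topology.residue_numbers <= hi)
    if token not in map_.regions:
        raise SelectionError(f"unknown region label {token!r}")
    segid, (lo, hi) = map_.regions[token]
    mask = (topology.residue_numbers >= lo) & (topology.residue_numbers <= hi)
    if segid is not None:
        mask &= topology.segment_ids == segid
    return mask


def resolve_selection(
    topology: Topology,
    map_: SegmentMap,
    spec: str,
    atom_mode: str = "heavy",
) -> Selection:
    """Resolve a region expression like ``"RECEPTOR - ICL3 - C-term"``.

    The expression is a whitespace-separated sequence of region labels or
    ``lo-hi`` residue ranges joined by ``+`` (union) and ``-`` (difference);
    operators must be surrounded by whitespace so hyphenated labels such as
    ``C-term`` survive. ``atom_mode`` restricts the atoms kept: ``"heavy"``
    (default, element ≠ H), ``"all"``, or ``"calpha"``.
    """
    tokens = spec.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _region_mask(topology, map_, tokens[0])
    i = 1
    while i < len(tokens):
        op = tokens[i]
        if op not in ("+", "-") or i + 1 >= len(tokens):
            raise SelectionError(f"malformed selection expression {spec!r}")
        term = _region_mask(topology, map_, tokens[i + 1])
        mask = (mask | term) if op == "+" else (mask & ~term)
        i += 2
    if atom_mode == "heavy":
        mask &= topology.heavy_mask()
    elif atom_mode == "calpha":
        mask &= topology.calpha_mask()
    elif atom_mode != "all":
        raise SelectionError(f"unknown atom_mode {atom_mode!r}")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {spec!r} resolved to no atoms")
    return Selection(label=spec, atom_indices=idx)


def load_segment_map(path: str | Path) -> SegmentMap:
    """Read a segment map from YAML.

    Schema::

        regions:
          TM3: {segment: REC, residues: [10, 20]}
          C-term: {residues: [270, 282]}
        markers:
          AHD_marker: {segment: GA, residue: 161}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "regions" not in raw:
        raise ParseError(f"{path}: segment map must define a 'regions' mapping")
    regions = {}
    for label, entry in raw["regions"].items():
        lo, hi = entry["residues"]
        regions[str(label)] = (entry.get("segment"), (int(lo), int(hi)))
    markers = {}
    for name, entry in (raw.get("markers") or {}).items():
        markers[str(name)] = (entry.get("segment"), int(entry["residue"]))
    return SegmentMap(regions=regions, marker_residues=markers, metadata=raw.get("metadata", {}))


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------


def write_frames_table(trajectory: Trajectory, path: str | Path) -> None:
    """Write coordinates as the frames-table CSV (frame,atom,x,y,z; header mandatory).

    Coordinates are written with 6 decimal places; loading the file recovers
    them bitwise when they are already at that granularity.
    """
    n_frames, n_atoms, _ = trajectory.coordinates.shape
    frame_col = np.repeat(np.arange(n_frames), n_atoms)
    atom_col = np.tile(np.arange(n_atoms), n_frames)
    flat = trajectory.coordinates.reshape(-1, 3)
    df = pd.DataFrame(
        {"frame": frame_col, "atom": atom_col, "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    )
    df.to_csv(path, index=False, float_format=f"%.{FRAMES_TABLE_DECIMALS}f")


def write_pdb(topology: Topology, coordinates: np.ndarray, path: str | Path) -> None:
    """Write one or more frames as a (multi-)model PDB."""
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    with open(path, "w") as fh:
        for m, frame in enumerate(coords, start=1):
            if coords.shape[0] > 1:
                fh.write(f"MODEL     {m:4d}\n")
            for i in range(topology.n_atoms):
                name = topology.atom_names[i]
                pad = name if len(name) >= 4 else f" {name:<3s}"
                fh.write(
                    "ATOM  {serial:5d} {name:4s} {res:<3s} {chain}{resnum:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}      {seg:<4s}{el:>2s}\n".format(
                        serial=(i % 99999) + 1,
                        name=pad,
                        res=topology.residue_names[i][:3],
                        chain=(topology.segment_ids[i][:1] or "A"),
                        resnum=int(topology.residue_numbers[i]) % 10000,
                        x=frame[i, 0],
                        y=frame[i, 1],
                        z=frame[i, 2],
                        occ=1.0,
                        b=0.0,
                        seg=topology.segment_ids[i][:4],
                        el=topology.elements[i][:2],
                    )
                )
            if coords.shape[0] > 1:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_series_csv(times: np.ndarray, values: np.ndarray, path: str | Path) -> None:
    """Write a time series as CSV with columns time_ns,value."""
    pd.DataFrame({"time_ns": times, "value": values}).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a time_ns,value CSV (or any two-column/one-column numeric CSV)."""
    df = pd.read_csv(path)
    if "time_ns" in df.columns and "value" in df.columns:
        return df["time_ns"].to_numpy(float), df["value"].to_numpy(float)
    if df.shape[1] == 1:
        vals = df.iloc[:, 0].to_numpy(float)
        return np.arange(len(vals), dtype=float), vals
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
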