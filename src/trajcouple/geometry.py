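"""Superposition, RMSD, center-to-center distances, and helix tilt angles.

This is the coordinates-to-series layer: every downstream stage (clustering,
coupling, state classification, free-energy surfaces) consumes the series and
matrices produced here.

The center-to-center distance (CCD) between two atom selections uses
*geometric* (unweighted) centers throughout — e.g. the Gα AHD–RD separation
that defines open/closed states, or the ligand–receptor distance tracked
during dissociation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, DimensionError, SelectionError
from .trajio import Selection, Trajectory

__all__ = [
    "DistanceSeries",
    "RmsdSeries",
    "TiltSeries",
    "geometric_center",
    "ccd_series",
    "kabsch_superpose",
    "rmsd",
    "rmsd_series",
    "pairwise_rmsd_matrix",
    "helix_tilt_series",
]


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame distance (Å) between the geometric centers of two selections."""

    times: np.ndarray
    values: np.ndarray
    label_a: str
    label_b: str

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise DimensionError("times and values must have equal length")


@dataclass(frozen=True)
class RmsdSeries:
    """Per-frame RMSD (Å) to a reference frame after superposition."""

    times: np.ndarray
    values: np.ndarray
    measured_selection: str
    alignment_selection: str
    reference_frame: int


@dataclass(frozen=True)
class TiltSeries:
    """Per-frame angle (degrees, [0, 180]) between a helix axis and its reference orientation."""

    times: np.ndarray
    angle_deg: np.ndarray
    helix: str
    reference_frame: int


def geometric_center(trajectory: Trajectory, frame: int, selection: Selection) -> np.ndarray:
    """Unweighted mean coordinate (Å) of the selected atoms in one frame."""
    return trajectory.coordinates[frame, selection.atom_indices].mean(axis=0)


def ccd_series(trajectory: Trajectory, sel_a: Selection, sel_b: Selection) -> DistanceSeries:
    """Per-frame Euclidean distance between the geometric centers of two selections."""
    ca = trajectory.coordinates[:, sel_a.atom_indices].mean(axis=1)
    cb = trajectory.coordinates[:, sel_b.atom_indices].mean(axis=1)
    values = np.linalg.norm(ca - cb, axis=1)
    return DistanceSeries(times=trajectory.times, values=values, label_a=sel_a.label, label_b=sel_b.label)


def _kabsch_rotation(mobile_c: np.ndarray, reference_c: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (3×3) taking centered mobile onto centered reference.

    Determinant correction flips the smallest singular direction so reflections
    never leak through (degenerate/planar covariance case).
    """
    H = mobile_c.T @ reference_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, fit_selection: Selection | np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of one frame onto another.

    The rotation/translation minimizing the RMSD of the fit atoms is computed
    and applied to *all* atoms of the mobile frame. Returns
    ``(rotation, translation, transformed)`` with
    ``transformed = mobile @ rotation.T + translation``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise DimensionError("mobile and reference must have identical shapes")
    if fit_selection is None:
        fit_idx = np.arange(mobile.shape[0])
    elif isinstance(fit_selection, Selection):
        fit_idx = fit_selection.atom_indices
    else:
        fit_idx = np.asarray(fit_selection, dtype=int)
    if len(fit_idx) < 3:
        raise DegenerateFitError("superposition needs at least 3 fit atoms")
    mob_fit = mobile[fit_idx]
    ref_fit = reference[fit_idx]
    mob_centroid = mob_fit.mean(axis=0)
    ref_centroid = ref_fit.mean(axis=0)
    mob_c = mob_fit - mob_centroid
    # Collinear fit sets leave a rotation about the line undetermined.
    sv = np.linalg.svd(mob_c, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateFitError("fit atoms are collinear; superposition is underdetermined")
    R = _kabsch_rotation(mob_c, ref_fit - ref_centroid)
    t = ref_centroid - R @ mob_centroid
    transformed = mobile @ R.T + t
    return R, t, transformed


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square deviation (Å) between matched coordinate sets; no fitting."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def rmsd_series(
    trajectory: Trajectory,
    reference_frame: int,
    align_selection: Selection,
    measure_selection: Selection,
) -> RmsdSeries:
    """RMSD of ``measure_selection`` per frame after superposing each frame on
    the reference frame via ``align_selection``.

    The reference frame scores exactly 0 when the measured atoms are a subset
    of the alignment atoms.
    """
    coords = trajectory.coordinates
    ref = coords[reference_frame]
    _, values = _batched_aligned_rmsd(coords, ref, align_selection.atom_indices, measure_selection.atom_indices)
    return RmsdSeries(
        times=trajectory.times,
        values=values,
        measured_selection=measure_selection.label,
        alignment_selection=align_selection.label,
        reference_frame=reference_frame,
    )


def _batched_aligned_rmsd(
    frames: np.ndarray, reference: np.ndarray, align_idx: np.ndarray, measure_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame onto ``reference`` via the align atoms (batched
    Kabsch over stacked 3×3 covariances) and return the per-frame RMSD over
    the measure atoms."""
    if len(align_idx) < 3:
        raise DegenerateFitError("superposition needs at least 3 fit atoms")
    mob = frames[:, align_idx]  # (n, m, 3)
    ref = reference[align_idx]
    mob_centroids = mob.mean(axis=1, keepdims=True)
    ref_centroid = ref.mean(axis=0)
    H = np.einsum("nmi,mj->nij", mob - mob_centroids, ref - ref_centroid)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("nij,nkj->nik", Vt.transpose(0, 2, 1), U))
    D = np.repeat(np.eye(3)[None], len(frames), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("nji,njk,nlk->nil", Vt, D, U)  # Vt.T @ D @ U.T per frame
    t = ref_centroid - np.einsum("nij,nj->ni", R, mob_centroids[:, 0])
    measured = np.einsum("nij,nmj->nmi", R, frames[:, measure_idx]) + t[:, None, :]
    diffs = measured - reference[measure_idx]
    values = np.sqrt(np.mean(np.sum(diffs**2, axis=-1), axis=-1))
    return measured, values


def pairwise_rmsd_matrix(
    trajectory: Trajectory, align_selection: Selection, measure_selection: Selection
) -> np.ndarray:
    """Symmetric frame × frame RMSD matrix (Å) with per-pair superposition.

    Entry (i, j) superposes frame j onto frame i via the alignment atoms and
    measures the RMSD of the measured atoms. Per-pair fits break exact
    symmetry at the ~1e-6 Å level, so the matrix is symmetrized by averaging
    with its transpose; the diagonal is exactly zero. The triangle inequality
    is not guaranteed (each pair has its own fit).
    """
    n = trajectory.n_frames
    if n < 2:
        raise DimensionError("pairwise matrix needs at least 2 frames")
    coords = trajectory.coordinates
    M = np.empty((n, n))
    for i in range(n):
        _, M[i] = _batched_aligned_rmsd(
            coords, coords[i], align_selection.atom_indices, measure_selection.atom_indices
        )
    M = 0.5 * (M + M.T)
    np.fill_diagonal(M, 0.0)
    return M


def helix_tilt_series(
    trajectory: Trajectory, helix_selection: Selection, reference_frame: int = 0
) -> TiltSeries:
    """Tilt angle of a helix relative to its orientation in a reference frame.

    The helix axis per frame is the dominant principal axis of its Cα
    coordinates, sign-oriented from the N- to the C-terminal end, so the
    full [0°, 180°] range is meaningful (e.g. the Gα α5 helix tilting away
    from the receptor during uncoupling).
    """
    topo = trajectory.topology
    ca_idx = helix_selection.atom_indices[topo.atom_names[helix_selection.atom_indices] == "CA"]
    if len(ca_idx) < 4:
        raise SelectionError("helix tilt needs at least 4 Cα atoms")

    def axis(frame_coords: np.ndarray) -> np.ndarray:
        ca = frame_coords[ca_idx]
        centered = ca - ca.mean(axis=0)
        _, _, Vt = np.linalg.svd(centered, full_matrices=False)
        a = Vt[0]
        if np.dot(a, ca[-1] - ca[0]) < 0:  # orient N → C
            a = -a
        return a / np.linalg.norm(a)

    ref_axis = axis(trajectory.coordinates[reference_frame])
    angles = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        cosang = np.clip(np.dot(axis(trajectory.coordinates[f]), ref_axis), -1.0, 1.0)
        angles[f] = np.degrees(np.arccos(cosang))
    return TiltSeries(
        times=trajectory.times,
        angle_deg=angles,
        helix=helix_selection.label,
        reference_frame=reference_frame,
    )
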