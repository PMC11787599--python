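"""Toy-system generators with planted ground truth.

Every pipeline stage can be exercised without an MD engine: multi-state bead
ensembles of two coupled components, samples from an analytically known
free-energy landscape, a deterministic ligand-egress trajectory with an
exact residue-contact plan, piecewise CCD schedules, and interaction-energy
series with closed-form entropies.

All generators are deterministic given (parameters, seed) and return their
ground truth alongside the data; no global random state is touched. Toy
topologies use one bead per residue (plus a small multi-bead ligand) so
contact geometry stays exact and cheap — the pipeline's mathematics is
coordinate-generic, so nothing about real βAR geometry is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusterAssignment
from .constants import DEFAULT_TEMPERATURE_K, KB_KCAL_MOL_K
from .contacts import ResidueRef
from .errors import ValidationError
from .geometry import DistanceSeries, kabsch_superpose, rmsd
from .stats import EnergySeries
from .trajio import Topology, Trajectory

__all__ = [
    "PlantedCoupledSystem",
    "PlantedLandscape",
    "PlantedEgress",
    "EgressConfig",
    "ScheduleTruth",
    "bead_topology",
    "gen_coupled",
    "gen_landscape",
    "gen_egress",
    "gen_ccd_schedule",
    "gen_energies",
]


def bead_topology(
    n_residues: int,
    segment_id: str = "A",
    residue_name: str = "BEA",
    atoms_per_residue: int = 1,
) -> Topology:
    """One-bead-per-residue carbon topology (atom name CA so Cα logic applies)."""
    n = n_residues * atoms_per_residue
    names = ["CA" if a == 0 else f"C{a}" for _ in range(n_residues) for a in range(atoms_per_residue)]
    resnums = [r + 1 for r in range(n_residues) for _ in range(atoms_per_residue)]
    return Topology(
        atom_names=np.array(names),
        elements=np.full(n, "C"),
        residue_numbers=np.array(resnums, dtype=int),
        residue_names=np.full(n, residue_name),
        segment_ids=np.full(n, segment_id),
        masses=np.full(n, 12.011),
    )


# --------------------------------------------------------------------------
# Coupled two-component ensembles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedCoupledSystem:
    """Two bead components with planted per-frame states and a joint-state fraction.

    State i of component A couples to state i of component B; B matches A's
    partner state with probability ``coupling_fraction`` and is uniform over
    the other states otherwise.
    """

    trajectory_a: Trajectory
    trajectory_b: Trajectory
    true_labels_a: np.ndarray  # per-frame state ids in 1..k
    true_labels_b: np.ndarray
    coupling_fraction: float
    noise_sigma: float
    templates_a: np.ndarray  # (k, n_beads, 3)
    templates_b: np.ndarray
    seed: int

    def _assignment(self, labels: np.ndarray, component: str) -> ClusterAssignment:
        observed = sorted(set(labels.tolist()))
        remap = {lab: i + 1 for i, lab in enumerate(observed)}
        mapped = np.array([remap[lab] for lab in labels])
        medoids = np.array(
            [int(np.flatnonzero(mapped == c)[0]) for c in range(1, len(observed) + 1)]
        )
        return ClusterAssignment(
            labels=mapped,
            k=len(observed),
            component=component,
            medoids=medoids,
            frame_indices=np.arange(len(labels)),
        )

    def assignment_a(self) -> ClusterAssignment:
        """Ground-truth labels of A packaged as a cluster assignment."""
        return self._assignment(self.true_labels_a, "A")

    def assignment_b(self) -> ClusterAssignment:
        return self._assignment(self.true_labels_b, "B")


def _separated_templates(rng: np.random.Generator, k: int, n_beads: int, min_rmsd: float) -> np.ndarray:
    """Random bead templates rescaled so every pair is ≥ min_rmsd apart after superposition."""
    templates = rng.normal(size=(k, n_beads, 3))
    templates -= templates.mean(axis=1, keepdims=True)
    closest = np.inf
    for i in range(k):
        for j in range(i + 1, k):
            _, _, fitted = kabsch_superpose(templates[j], templates[i])
            closest = min(closest, rmsd(fitted, templates[i]))
    if closest <= 0:
        raise ValidationError("degenerate random templates; change the seed")
    return templates * (min_rmsd / closest)


def gen_coupled(
    states_k: int,
    n_frames: int,
    f: float,
    noise_sigma: float,
    seed: int,
    n_beads: int = 5,
) -> PlantedCoupledSystem:
    """Generate the planted coupled two-component system.

    Component A states are iid uniform over k; with probability ``f`` B takes
    A's partner state, otherwise one of the other k − 1 states uniformly.
    Coordinates are the state template plus isotropic Gaussian noise; the
    templates sit ≥ max(10·noise_sigma, 1 Å) apart in superposed RMSD so the
    planted partition is recoverable whenever separation/noise ≥ 10.
    """
    if states_k < 2:
        raise ValidationError("states_k must be >= 2")
    if not (0.0 <= f <= 1.0):
        raise ValidationError("coupling fraction must be in [0, 1]")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    sep = max(10.0 * noise_sigma, 1.0)
    templates_a = _separated_templates(rng, states_k, n_beads, sep)
    templates_b = _separated_templates(rng, states_k, n_beads, sep)
    labels_a = rng.integers(1, states_k + 1, size=n_frames)
    match = rng.random(n_frames) < f
    other_pick = rng.integers(0, states_k - 1, size=n_frames)
    labels_b = np.where(match, labels_a, 0)
    for i in np.flatnonzero(~match):
        others = [s for s in range(1, states_k + 1) if s != labels_a[i]]
        labels_b[i] = others[other_pick[i]]

    def frames(templates: np.ndarray, labels: np.ndarray) -> np.ndarray:
        base = templates[labels - 1]
        if noise_sigma > 0:
            base = base + rng.normal(scale=noise_sigma, size=base.shape)
        return base

    times = np.arange(n_frames, dtype=float)
    topo_a = bead_topology(n_beads, "A")
    topo_b = bead_topology(n_beads, "B")
    return PlantedCoupledSystem(
        trajectory_a=Trajectory(topo_a, frames(templates_a, labels_a), times),
        trajectory_b=Trajectory(topo_b, frames(templates_b, labels_b), times),
        true_labels_a=labels_a,
        true_labels_b=labels_b,
        coupling_fraction=f,
        noise_sigma=noise_sigma,
        templates_a=templates_a,
        templates_b=templates_b,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Free-energy landscapes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedLandscape:
    """Mixture-of-Gaussian-basins landscape with an analytically known W(x).

    Basin weights are Boltzmann factors of the planted depths, so with equal
    widths the free-energy minima of two basins differ by exactly the depth
    difference. Sampling is direct mixture sampling (not Metropolis), making
    the stationary density exact by construction.
    """

    centers: np.ndarray  # (m, d)
    sigmas: np.ndarray  # (m,), isotropic Å
    depths: np.ndarray  # (m,), kcal/mol; deeper = more populated
    temperature: float = DEFAULT_TEMPERATURE_K
    n_samples: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "sigmas", np.asarray(self.sigmas, dtype=float))
        object.__setattr__(self, "depths", np.asarray(self.depths, dtype=float))
        if not (len(c) == len(self.sigmas) == len(self.depths)):
            raise ValidationError("centers, sigmas, depths must have equal length")
        if np.any(self.sigmas <= 0):
            raise ValidationError("basin widths must be positive")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")

    @property
    def kT(self) -> float:
        return KB_KCAL_MOL_K * self.temperature

    def weights(self) -> np.ndarray:
        w = np.exp(-self.depths / self.kT)
        return w / w.sum()

    def density(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = pts.shape[1]
        p = np.zeros(len(pts))
        for w, c, s in zip(self.weights(), self.centers, self.sigmas):
            sq = np.sum((pts - c) ** 2, axis=1)
            p += w * np.exp(-sq / (2 * s**2)) / ((2 * np.pi * s**2) ** (d / 2))
        return p

    def analytic_free_energy(self, points: np.ndarray) -> np.ndarray:
        """W = −kT ln p at the given points, shifted so the minimum over them is 0."""
        W = -self.kT * np.log(self.density(points))
        return W - W.min()


def gen_landscape(landscape: PlantedLandscape) -> np.ndarray:
    """Draw samples whose exact stationary density is the landscape's mixture."""
    rng = np.random.default_rng(landscape.seed)
    m, d = landscape.centers.shape
    counts = rng.multinomial(landscape.n_samples, landscape.weights())
    parts = [
        rng.normal(loc=landscape.centers[i], scale=landscape.sigmas[i], size=(counts[i], d))
        for i in range(m)
    ]
    samples = np.concatenate(parts, axis=0)
    rng.shuffle(samples, axis=0)
    return samples if d > 1 else samples.ravel()


# --------------------------------------------------------------------------
# Ligand egress with a deterministic contact plan
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EgressConfig:
    """Plan for the deterministic dissociation trajectory.

    The ligand center moves along +x from ``start_ccd`` (< 12 Å, bound) to
    ``end_ccd`` (> 40 Å, unbound) past one residue bead per planned contact
    fraction; receptor dummy beads mirror the path residues so the receptor
    geometric center is pinned at the origin and the ligand–receptor CCD is
    exactly the ligand's x coordinate.
    """

    contact_fractions: tuple[float, ...] = (0.5, 0.25, 0.1)
    n_frames: int = 200
    start_ccd: float = 8.0
    end_ccd: float = 45.0
    cutoff: float = 4.0
    residue_y_offset: float = 3.0
    zone_spacing: float = 8.0

    def __post_init__(self) -> None:
        if not self.contact_fractions or any(not (0 < fr < 1) for fr in self.contact_fractions):
            raise ValidationError("contact fractions must each be in (0, 1)")
        if not (self.start_ccd < 12.0 < 40.0 < self.end_ccd):
            raise ValidationError("path must start bound (< 12 Å) and end unbound (> 40 Å)")
        if self.residue_y_offset >= self.cutoff:
            raise ValidationError("residue offset must be inside the contact cutoff")


@dataclass(frozen=True)
class PlantedEgress:
    """Ground truth of the egress trajectory: exact geometry, no randomness."""

    residues: tuple[ResidueRef, ...]  # path residues, in order passed
    residue_positions: np.ndarray
    true_fractions: dict = field(default_factory=dict)  # ResidueRef -> exact fraction
    ccd_schedule: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_states: np.ndarray = field(default_factory=lambda: np.empty(0))  # bound/intermediate/unbound


def _egress_topology(n_path: int) -> Topology:
    """Receptor path + mirror beads (segment REC) and a two-bead ligand (segment LIG)."""
    n_rec = 2 * n_path
    names = ["CA"] * n_rec + ["C1", "C2"]
    resnums = list(range(1, n_rec + 1)) + [1, 1]
    resnames = ["RES"] * n_path + ["DUM"] * n_path + ["LIG", "LIG"]
    segids = ["REC"] * n_rec + ["LIG", "LIG"]
    return Topology(
        atom_names=np.array(names),
        elements=np.full(n_rec + 2, "C"),
        residue_numbers=np.array(resnums, dtype=int),
        residue_names=np.array(resnames),
        segment_ids=np.array(segids),
        masses=np.full(n_rec + 2, 12.011),
    )


def gen_egress(config: EgressConfig = EgressConfig(), seed: int = 0) -> tuple[Trajectory, PlantedEgress]:
    """Build the dissociation trajectory with an exact residue-contact plan.

    Fully deterministic — contacts are pure geometry, so the planted contact
    fractions are exact up to one-frame rounding of ``fraction × n_frames``.
    The ``seed`` argument is accepted for interface uniformity and unused.
    """
    cfg = config
    m = len(cfg.contact_fractions)
    y = cfg.residue_y_offset
    # contact zone half-width for the ligand beads at z = ±0.5
    half = float(np.sqrt(cfg.cutoff**2 - y**2 - 0.25))
    margin = 0.5
    zone_centers = 14.0 + cfg.zone_spacing * np.arange(m)
    if zone_centers[-1] + half + margin >= cfg.end_ccd:
        raise ValidationError("contact zones do not fit between start and end CCD")
    counts = [int(round(fr * cfg.n_frames)) for fr in cfg.contact_fractions]
    n_gap = cfg.n_frames - sum(counts)
    if n_gap < m + 2:
        raise ValidationError("not enough frames left for the inter-zone gaps")
    # gap intervals: before first zone, between zones, after last zone
    bounds = [(cfg.start_ccd, zone_centers[0] - half - margin)]
    for j in range(m - 1):
        bounds.append((zone_centers[j] + half + margin, zone_centers[j + 1] - half - margin))
    bounds.append((zone_centers[-1] + half + margin, cfg.end_ccd))
    gap_counts = [n_gap // (m + 1)] * (m + 1)
    for j in range(n_gap - sum(gap_counts)):
        gap_counts[j % (m + 1)] += 1
    xs: list[np.ndarray] = []
    for j in range(m + 1):
        lo, hi = bounds[j]
        xs.append(np.linspace(lo, hi, gap_counts[j], endpoint=(j == m)))
        if j < m:
            inner = half - 0.3  # strictly inside the zone
            xs.append(np.linspace(zone_centers[j] - inner, zone_centers[j] + inner, counts[j]))
    x = np.concatenate(xs)
    if not np.all(np.diff(x) > 0):
        raise ValidationError("CCD schedule is not strictly increasing; adjust the plan")

    topo = _egress_topology(m)
    res_pos = np.array([[cx, y, 0.0] for cx in zone_centers] + [[-cx, -y, 0.0] for cx in zone_centers])
    coords = np.empty((cfg.n_frames, topo.n_atoms, 3))
    coords[:, : 2 * m] = res_pos[None]
    coords[:, 2 * m] = np.stack([x, np.zeros_like(x), np.full_like(x, 0.5)], axis=1)
    coords[:, 2 * m + 1] = np.stack([x, np.zeros_like(x), np.full_like(x, -0.5)], axis=1)
    traj = Trajectory(topo, coords, np.arange(cfg.n_frames, dtype=float))

    residues = tuple(ResidueRef("REC", j + 1, "RES") for j in range(m))
    fractions = {res: counts[j] / cfg.n_frames for j, res in enumerate(residues)}
    states = np.where(x < 12.0, "bound", np.where(x > 40.0, "unbound", "intermediate"))
    truth = PlantedEgress(
        residues=residues,
        residue_positions=res_pos[:m],
        true_fractions=fractions,
        ccd_schedule=x,
        true_states=states,
    )
    return traj, truth


# --------------------------------------------------------------------------
# CCD schedules and energy series
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScheduleTruth:
    levels: np.ndarray
    true_level: np.ndarray  # per-frame noiseless mean
    transitions: int


def gen_ccd_schedule(
    levels, frames_per_level: int, noise_sigma: float, seed: int
) -> tuple[DistanceSeries, ScheduleTruth]:
    """Piecewise-constant CCD means with Gaussian noise on top."""
    lv = np.asarray(levels, dtype=float)
    if np.any(lv <= 0):
        raise ValidationError("levels must be positive distances")
    rng = np.random.default_rng(seed)
    mean = np.repeat(lv, frames_per_level)
    values = mean + (rng.normal(scale=noise_sigma, size=mean.shape) if noise_sigma > 0 else 0.0)
    series = DistanceSeries(
        times=np.arange(len(values), dtype=float), values=values, label_a="marker_a", label_b="marker_b"
    )
    return series, ScheduleTruth(levels=lv, true_level=mean, transitions=len(lv) - 1)


def gen_energies(
    distribution: str,
    n: int,
    temperature: float = DEFAULT_TEMPERATURE_K,
    seed: int = 0,
    mu: float = 0.0,
    sigma: float = 1.0,
    a: float = 1.0,
) -> tuple[EnergySeries, float]:
    """Interaction-energy series with the analytic entropy attached.

    ``normal(mu, sigma)`` draws iid Gaussians (analytic −TΔS = σ²/(2·k_B·T));
    ``two_point(±a)`` emits the balanced alternating ±a sequence so the
    closed form k_B·T·ln cosh(a/(k_B·T)) holds exactly for the finite sample.
    """
    if n < 2:
        raise ValidationError("need n >= 2")
    kT = KB_KCAL_MOL_K * temperature
    if distribution == "normal":
        rng = np.random.default_rng(seed)
        values = rng.normal(loc=mu, scale=sigma, size=n)
        analytic = sigma**2 / (2 * kT)
    elif distribution == "two_point":
        if n % 2:
            raise ValidationError("two_point needs an even n for exact balance")
        values = np.where(np.arange(n) % 2 == 0, a, -a).astype(float)
        analytic = kT * np.log(np.cosh(a / kT))
    else:
        raise ValidationError(f"unknown distribution {distribution!r}")
    return EnergySeries(values=values, temperature=temperature), float(analytic)
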