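"""Free-energy surfaces by Boltzmann inversion of coordinate histograms.

The potential of mean force along one or two distance coordinates is
estimated as W = −k_B·T·ln(count / count_max) on a uniform grid (default bin
width 1.0 Å at 310 K), so the best-sampled bin sits at W = 0 and everything
else is reported relative to it. Sparse bins are masked rather than
extrapolated: for 2D surfaces bins holding fewer than ``min_count`` samples
(default 10) carry an infinity sentinel and a False validity flag; for 1D
profiles the cutoff defaults to 1.

No smoothing is applied to the numeric grid — smoothing is a plotting
concern only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K, KB_KCAL_MOL_K
from .errors import DimensionError, EmptyLandscapeError, ValidationError
from .geometry import DistanceSeries

__all__ = ["PMFConfig", "PMFGrid", "histogram", "pmf_from_counts", "pmf1d", "pmf2d", "write_pmf_csv"]


@dataclass(frozen=True)
class PMFConfig:
    temperature: float = DEFAULT_TEMPERATURE_K  # K
    bin_width: float = 1.0  # Å
    min_count: int = 10  # occupancy cutoff, applied to 2D grids
    boltzmann_constant: float = KB_KCAL_MOL_K  # kcal/(mol·K)

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.bin_width <= 0 or self.min_count < 1:
            raise ValidationError("PMFConfig requires temperature > 0, bin_width > 0, min_count >= 1")

    @property
    def kT(self) -> float:
        return self.boltzmann_constant * self.temperature


@dataclass(frozen=True)
class PMFGrid:
    """Binned relative free energies with an occupancy mask.

    ``free_energy`` is in kcal/mol with its minimum over valid bins at 0;
    masked (under-occupied) bins hold ``+inf``.
    """

    edges: tuple[np.ndarray, ...]
    counts: np.ndarray
    free_energy: np.ndarray
    valid: np.ndarray
    config: PMFConfig
    axis_labels: tuple[str, ...] = ()

    @property
    def bin_centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


def _axis_edges(values: np.ndarray, bw: float, bounds=None) -> np.ndarray:
    if bounds is None:
        lo = np.floor(values.min() / bw) * bw
        hi = np.ceil(values.max() / bw) * bw
        if hi <= lo:
            hi = lo + bw
    else:
        lo, hi = bounds
    n_bins = int(round((hi - lo) / bw))
    return lo + bw * np.arange(n_bins + 1)


def histogram(samples: np.ndarray, config: PMFConfig = PMFConfig(), bounds=None):
    """Uniform-bin histogram of 1D samples (shape (n,)) or 2D samples (n, 2).

    Axis ranges default to [floor(min), ceil(max)] aligned to the bin width;
    bins are right-open with the last bin right-closed (numpy convention).
    Returns (counts, edges) with edges a tuple of per-axis edge arrays.
    """
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise ValidationError("need at least one sample")
    if not np.all(np.isfinite(s)):
        raise ValidationError("samples must be finite")
    bw = config.bin_width
    if s.ndim == 1:
        edges = _axis_edges(s, bw, bounds)
        counts, _ = np.histogram(s, bins=edges)
        return counts, (edges,)
    if s.ndim == 2 and s.shape[1] == 2:
        b = bounds or (None, None)
        ex = _axis_edges(s[:, 0], bw, b[0])
        ey = _axis_edges(s[:, 1], bw, b[1])
        counts, _, _ = np.histogram2d(s[:, 0], s[:, 1], bins=(ex, ey))
        return counts.astype(int), (ex, ey)
    raise DimensionError("samples must be shape (n,) or (n, 2)")


def pmf_from_counts(
    counts: np.ndarray,
    config: PMFConfig = PMFConfig(),
    edges: tuple[np.ndarray, ...] = (),
    axis_labels: tuple[str, ...] = (),
    min_count: int | None = None,
) -> PMFGrid:
    """Boltzmann inversion of a counts grid: W = −k_B·T·ln(count / count_max).

    ``min_count`` defaults to ``config.min_count`` for 2D grids and 1 for 1D
    profiles. The maximum-count bin is the W = 0 reference; since it can
    never be below any cutoff another bin passes, the minimum over valid
    bins is 0 by construction.
    """
    c = np.asarray(counts)
    if np.any(c < 0):
        raise ValidationError("counts must be non-negative")
    mc = min_count if min_count is not None else (config.min_count if c.ndim == 2 else 1)
    valid = c >= mc
    if not valid.any():
        raise EmptyLandscapeError(f"every bin holds fewer than {mc} configurations")
    cmax = c.max()
    W = np.full(c.shape, np.inf)
    W[valid] = -config.kT * np.log(c[valid] / cmax)
    if not edges:
        edges = tuple(np.arange(n + 1, dtype=float) for n in c.shape)
    return PMFGrid(
        edges=tuple(edges),
        counts=c,
        free_energy=W,
        valid=valid,
        config=config,
        axis_labels=tuple(axis_labels),
    )


def pmf1d(samples: np.ndarray, config: PMFConfig = PMFConfig(), bounds=None, label: str = "x") -> PMFGrid:
    """1D free-energy profile from raw coordinate samples."""
    counts, edges = histogram(np.asarray(samples, dtype=float).ravel(), config, bounds)
    return pmf_from_counts(counts, config, edges=edges, axis_labels=(label,))


def pmf2d(
    series_x: DistanceSeries | np.ndarray,
    series_y: DistanceSeries | np.ndarray,
    config: PMFConfig = PMFConfig(),
    bounds=None,
) -> PMFGrid:
    """2D free-energy surface over two time-aligned distance series.

    Typical axes: the TM3–TM4 CCD against the ligand–receptor CCD.
    """
    if isinstance(series_x, DistanceSeries):
        x = series_x.values
        lx = f"{series_x.label_a}-{series_x.label_b}"
    else:
        x, lx = np.asarray(series_x, dtype=float), "x"
    if isinstance(series_y, DistanceSeries):
        y = series_y.values
        ly = f"{series_y.label_a}-{series_y.label_b}"
    else:
        y, ly = np.asarray(series_y, dtype=float), "y"
    if len(x) != len(y):
        raise DimensionError("the two coordinate series must have equal length")
    counts, edges = histogram(np.stack([x, y], axis=1), config, bounds)
    return pmf_from_counts(counts, config, edges=edges, axis_labels=(lx, ly))


def write_pmf_csv(grid: PMFGrid, path: str | Path) -> None:
    """Write a grid in long format: bin centers, count, free energy, validity."""
    centers = grid.bin_centers
    rows = []
    if grid.counts.ndim == 1:
        for i, cx in enumerate(centers[0]):
            rows.append((cx, int(grid.counts[i]), grid.free_energy[i], bool(grid.valid[i])))
        cols = ["x_bin_center", "count", "free_energy_kcal_mol", "valid"]
    else:
        for i, cx in enumerate(centers[0]):
            for j, cy in enumerate(centers[1]):
                rows.append((cx, cy, int(grid.counts[i, j]), grid.free_energy[i, j], bool(grid.valid[i, j])))
        cols = ["x_bin_center", "y_bin_center", "count", "free_energy_kcal_mol", "valid"]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False)
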