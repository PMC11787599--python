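"""Conformational-coupling ("key-lock") detection between two components.

Given cluster assignments of two interacting components (e.g. ligand poses
and receptor conformations, or receptor and Gα conformations) over the same
trajectory frames, every cluster-of-A × cluster-of-B pair is scored by the
fraction of frames the two clusters share. A pair sharing strictly more than
half of the common frames is flagged a *strong coupling pair* — the two
conformations fit together like a key and a lock.

The denominator of "fraction of common frames" is ambiguous in everyday
phrasing, so four readings are selectable: ``min`` (|A∩B| / min(|A|, |B|),
the default and the most permissive symmetric choice), ``union``, ``a``, and
``b``. The mode used is recorded in every report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusterAssignment
from .errors import AlignmentError, ValidationError

__all__ = ["CouplingConfig", "CouplingPair", "overlap_fraction", "coupling_pairs", "coupling_report"]

_MODES = ("min", "union", "a", "b")


@dataclass(frozen=True)
class CouplingConfig:
    strong_threshold: float = 0.5
    denominator_mode: str = "min"
    min_cluster_size: int = 1  # no size filter by default

    def __post_init__(self) -> None:
        if not (0.0 < self.strong_threshold < 1.0):
            raise ValidationError("strong_threshold must be in (0, 1)")
        if self.denominator_mode not in _MODES:
            raise ValidationError(f"denominator_mode must be one of {_MODES}")
        if self.min_cluster_size < 1:
            raise ValidationError("min_cluster_size must be >= 1")


@dataclass(frozen=True)
class CouplingPair:
    cluster_a: int
    cluster_b: int
    n_common: int
    overlap_fraction: float
    strong: bool


def overlap_fraction(frames_a, frames_b, mode: str = "min") -> float:
    """|A∩B| over the denominator selected by ``mode``."""
    if mode not in _MODES:
        raise ValidationError(f"mode must be one of {_MODES}")
    a = set(np.asarray(frames_a).tolist())
    b = set(np.asarray(frames_b).tolist())
    if not a or not b:
        raise ValidationError("frame sets must be non-empty")
    inter = len(a & b)
    denom = {
        "min": min(len(a), len(b)),
        "union": len(a | b),
        "a": len(a),
        "b": len(b),
    }[mode]
    return inter / denom


def coupling_pairs(
    assign_a: ClusterAssignment,
    assign_b: ClusterAssignment,
    config: CouplingConfig = CouplingConfig(),
) -> list[CouplingPair]:
    """All cluster pairs with at least one common frame, scored and flagged.

    The two assignments must cover the identical frame universe (differing
    strides are a hard error — a silent intersection would change the
    denominator semantics). Sorted by overlap descending, then (a, b) ids.
    """
    if not np.array_equal(assign_a.frame_indices, assign_b.frame_indices):
        raise AlignmentError("cluster assignments cover different frame universes")
    n = assign_a.n_frames
    sizes_a = np.bincount(assign_a.labels, minlength=assign_a.k + 1)
    sizes_b = np.bincount(assign_b.labels, minlength=assign_b.k + 1)
    # contingency table over shared frames
    table = np.zeros((assign_a.k + 1, assign_b.k + 1), dtype=int)
    np.add.at(table, (assign_a.labels, assign_b.labels), 1)
    pairs: list[CouplingPair] = []
    for a in range(1, assign_a.k + 1):
        if sizes_a[a] < config.min_cluster_size:
            continue
        for b in range(1, assign_b.k + 1):
            if sizes_b[b] < config.min_cluster_size:
                continue
            n_common = int(table[a, b])
            if n_common == 0:
                continue
            denom = {
                "min": min(sizes_a[a], sizes_b[b]),
                "union": sizes_a[a] + sizes_b[b] - n_common,
                "a": sizes_a[a],
                "b": sizes_b[b],
            }[config.denominator_mode]
            frac = float(n_common / denom)
            pairs.append(
                CouplingPair(
                    cluster_a=a,
                    cluster_b=b,
                    n_common=n_common,
                    overlap_fraction=frac,
                    strong=bool(frac > config.strong_threshold),  # strictly "more than"
                )
            )
    pairs.sort(key=lambda p: (-p.overlap_fraction, p.cluster_a, p.cluster_b))
    if config.min_cluster_size == 1:
        assert sum(p.n_common for p in pairs) == n, "frame conservation violated"
    return pairs


def coupling_report(
    pairs: list[CouplingPair],
    component_a: str = "A",
    component_b: str = "B",
    config: CouplingConfig = CouplingConfig(),
) -> dict:
    """Machine-readable summary suitable for comparing conditions (apo vs GTP vs GDP)."""
    return {
        "component_a": component_a,
        "component_b": component_b,
        "config": {
            "strong_threshold": config.strong_threshold,
            "denominator_mode": config.denominator_mode,
            "min_cluster_size": config.min_cluster_size,
        },
        "pairs": [
            {
                "a": p.cluster_a,
                "b": p.cluster_b,
                "n_common": p.n_common,
                "overlap": p.overlap_fraction,
                "strong": p.strong,
            }
            for p in pairs
        ],
        "strong_count": sum(p.strong for p in pairs),
    }
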