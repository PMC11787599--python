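"""Categorical conformational states from center-to-center distance series.

Two classification schemes:

* **Gα open/closed** — the AHD–RD separation (CCD between marker residues,
  e.g. A161 on the α-helical domain and E299 on the Ras-like domain) maps to
  ``open`` (≥ 55 Å), ``semi-open`` ([45, 55) Å), ``semi-closed`` ((35, 45) Å)
  or ``closed`` (≤ 35 Å). The published bin edges overlap at 35/45/55 Å; the
  boundary convention here honors "≥ 55 → open" and "≤ 35 → closed" verbatim
  and sends the interior edge 45 Å to the more open bin, keeping the mapping
  monotone in openness.
* **Ligand binding** — the ligand–receptor CCD maps to ``bound`` (< 12 Å),
  ``unbound`` (> 40 Å) or ``intermediate``.

Two labeling conventions are provided and always named in output metadata:
per-frame occupancy ("dominant state") and classification of the
time-averaged CCD ("mean-CCD state", the convention behind published
per-system labels such as 63.6 Å → open).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ValidationError
from .geometry import DistanceSeries

__all__ = [
    "GalphaThresholds",
    "BindingThresholds",
    "StateSeries",
    "GALPHA_SCHEME",
    "BINDING_SCHEME",
    "classify_galpha",
    "classify_binding",
    "state_series",
    "occupancy_summary",
    "classify_mean_ccd",
]

#: Scheme vocabularies in tie-breaking order (most open / most engaged first).
GALPHA_SCHEME = ("open", "semi-open", "semi-closed", "closed")
BINDING_SCHEME = ("bound", "intermediate", "unbound")


@dataclass(frozen=True)
class GalphaThresholds:
    open_min: float = 55.0
    semi_open_min: float = 45.0
    semi_closed_min: float = 35.0

    def __post_init__(self) -> None:
        if not (self.open_min > self.semi_open_min > self.semi_closed_min > 0):
            raise ValidationError("thresholds must satisfy open_min > semi_open_min > semi_closed_min > 0")


@dataclass(frozen=True)
class BindingThresholds:
    bound_max: float = 12.0
    unbound_min: float = 40.0

    def __post_init__(self) -> None:
        if not (self.unbound_min > self.bound_max > 0):
            raise ValidationError("thresholds must satisfy unbound_min > bound_max > 0")


@dataclass(frozen=True)
class StateSeries:
    times: np.ndarray
    states: np.ndarray  # per-frame labels from the scheme vocabulary
    scheme: str  # "galpha" or "binding"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise DimensionError("times and states must have equal length")


def classify_galpha(ccd: float, thresholds: GalphaThresholds = GalphaThresholds()) -> str:
    """State of the Gα AHD–RD separation for one CCD value (Å)."""
    if not np.isfinite(ccd) or ccd <= 0:
        raise ValidationError(f"CCD must be finite and positive; got {ccd}")
    if ccd >= thresholds.open_min:
        return "open"
    if ccd >= thresholds.semi_open_min:
        return "semi-open"
    if ccd > thresholds.semi_closed_min:
        return "semi-closed"
    return "closed"


def classify_binding(ccd: float, thresholds: BindingThresholds = BindingThresholds()) -> str:
    """Ligand binding state for one ligand–receptor CCD value (Å)."""
    if not np.isfinite(ccd):
        raise ValidationError(f"CCD must be finite; got {ccd}")
    if ccd < thresholds.bound_max:
        return "bound"
    if ccd > thresholds.unbound_min:
        return "unbound"
    return "intermediate"


def state_series(ccd: DistanceSeries, scheme: str, thresholds=None) -> StateSeries:
    """Vectorized per-frame classification of a CCD series."""
    if scheme == "galpha":
        th = thresholds or GalphaThresholds()
        states = np.array([classify_galpha(v, th) for v in ccd.values])
    elif scheme == "binding":
        th = thresholds or BindingThresholds()
        states = np.array([classify_binding(v, th) for v in ccd.values])
    else:
        raise ValidationError(f"unknown scheme {scheme!r}")
    return StateSeries(times=ccd.times, states=states, scheme=scheme)


def _scheme_order(scheme: str) -> tuple[str, ...]:
    return GALPHA_SCHEME if scheme == "galpha" else BINDING_SCHEME


def occupancy_summary(states: StateSeries) -> dict:
    """Per-state occupancy fractions, the dominant state, and the transition count.

    Fractions sum to 1; dominance ties break toward the state listed first in
    the scheme vocabulary; a transition is any adjacent unequal pair.
    """
    if len(states.states) == 0:
        raise ValidationError("state series is empty")
    order = _scheme_order(states.scheme)
    n = len(states.states)
    fractions = {s: float(np.sum(states.states == s)) / n for s in order}
    dominant = max(order, key=lambda s: (fractions[s], -order.index(s)))
    transitions = int(np.sum(states.states[1:] != states.states[:-1]))
    return {
        "scheme": states.scheme,
        "convention": "per-frame occupancy",
        "fractions": fractions,
        "dominant": dominant,
        "transitions": transitions,
        "n_frames": n,
    }


def classify_mean_ccd(ccd: DistanceSeries, scheme: str, thresholds=None) -> dict:
    """Label a whole trajectory by the state of its time-averaged CCD."""
    mean = float(np.mean(ccd.values))
    if scheme == "galpha":
        label = classify_galpha(mean, thresholds or GalphaThresholds())
    elif scheme == "binding":
        label = classify_binding(mean, thresholds or BindingThresholds())
    else:
        raise ValidationError(f"unknown scheme {scheme!r}")
    return {"scheme": scheme, "convention": "mean CCD", "mean_ccd": mean, "state": label}
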