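"""Scalar statistics over per-frame series.

Pearson correlation between motion series (e.g. ligand RMSD vs transmembrane
helix RMSD), block-average standard errors of the mean for correlated MD
series, and the interaction-entropy term of endpoint binding free energies:

    −TΔS = k_B·T · ln ⟨exp(β (E − ⟨E⟩))⟩,   β = 1 / (k_B·T)

evaluated with log-sum-exp so large fluctuations do not overflow. The result
is non-negative by Jensen's inequality and depends only on the fluctuations
of the interaction energy, never its offset. The enthalpy term of a full
MM-PBSA ΔG is outside this package and enters only as a user-supplied number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE_K, KB_KCAL_MOL_K
from .errors import ComputeError, NumericRangeError, ValidationError

__all__ = ["EnergySeries", "BlockSemConfig", "pearson_r", "block_sem", "interaction_entropy"]

#: β·ΔE beyond which exp-average estimates are numerically meaningless even
#: under log-sum-exp (single-sample domination far past float range).
_OVERFLOW_GUARD = 1e4


@dataclass(frozen=True)
class EnergySeries:
    """Per-frame gas-phase interaction energies (kcal/mol) at a temperature (K)."""

    values: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValidationError("energies must be finite")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")


@dataclass(frozen=True)
class BlockSemConfig:
    n_blocks: int = 5

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValidationError("need at least 2 blocks")


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson product-moment correlation coefficient.

    Constant input is an explicit error rather than a silent 0: an undefined
    correlation must not masquerade as "uncorrelated".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be 1D and equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ComputeError("correlation undefined for a constant series")
    xm = x - x.mean()
    ym = y - y.mean()
    return float(np.dot(xm, ym) / np.sqrt(np.dot(xm, xm) * np.dot(ym, ym)))


def block_sem(series: np.ndarray, config: BlockSemConfig = BlockSemConfig()) -> float:
    """Standard error of the mean from contiguous block averages.

    The series is split into ``n_blocks`` equal contiguous blocks (trailing
    remainder frames dropped); the SEM is the sample standard deviation
    (n − 1 denominator) of the block means divided by √n_blocks. Block
    averaging absorbs the serial correlation of MD series that makes the
    naive SEM overconfident.
    """
    s = np.asarray(series, dtype=float)
    nb = config.n_blocks
    if len(s) < nb:
        raise ValidationError(f"need at least {nb} samples for {nb} blocks")
    block_len = len(s) // nb
    means = s[: nb * block_len].reshape(nb, block_len).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(nb))


def interaction_entropy(energies: EnergySeries) -> float:
    """Entropic penalty −TΔS (kcal/mol) from interaction-energy fluctuations.

    Exponential averaging of β·(E − ⟨E⟩) via log-sum-exp; non-negative by
    Jensen's inequality (clamped at 0 against ~1e-16 rounding on
    near-constant input).
    """
    e = np.asarray(energies.values, dtype=float)
    if len(e) < 2:
        raise ValidationError("need at least 2 energy samples")
    kT = KB_KCAL_MOL_K * energies.temperature
    beta_dev = (e - e.mean()) / kT
    max_arg = float(beta_dev.max())
    if max_arg > _OVERFLOW_GUARD:
        raise NumericRangeError(
            f"beta * max(E - <E>) = {max_arg:.3g} exceeds the evaluable range"
        )
    log_mean = logsumexp(beta_dev) - np.log(len(e))
    return max(0.0, float(kT * log_mean))
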