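"""Mastery-probability transforms, cut-off dichotomization, and the
correct-classification statistics (SCCR / PCCR).

Continuous theta scores (true or MIRT EAP) are mapped to the mastery
probability scale by the standard-normal CDF and dichotomized at a
cut-off; a person is a "master" when probability >= cut-off (equality
counts as mastery).  Latent-class states from G-DINA / R-RUM are used
as-is and do not vary with the cut-off.

SCCR_k is the proportion of (person, replication) cells whose estimated
mastery state on subskill k agrees with the true state; PCCR is the
proportion of persons whose whole pattern agrees.  The K-averaged SCCR
(dividing additionally by K) is also provided.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

from .data_io import AbilityMatrix

__all__ = [
    "probability_from_theta",
    "state_from_probability",
    "cutoff_grid",
    "sccr",
    "pccr",
    "mastery_proportion",
    "probability_histogram",
]


def probability_from_theta(theta: AbilityMatrix | np.ndarray) -> np.ndarray:
    """Entrywise standard-normal CDF of theta (mastery-probability scale)."""
    t = theta.theta if isinstance(theta, AbilityMatrix) else np.asarray(theta, float)
    return ndtr(t)


def state_from_probability(p: np.ndarray | float,
                           cutoff: float) -> np.ndarray:
    """Mastery (1) iff probability >= cutoff (boundary counts as mastery)."""
    return (np.asarray(p) >= cutoff).astype(int)


def cutoff_grid() -> np.ndarray:
    """The 81 cut-offs 0.10, 0.11, ..., 0.90 (exact to two decimals)."""
    return np.round(np.linspace(0.10, 0.90, 81), 2)


def _stack(states) -> np.ndarray:
    """Accept one N x K matrix or a sequence of them (replications)."""
    arr = np.asarray(states)
    if arr.ndim == 3:
        arr = arr.reshape(-1, arr.shape[-1])
    return arr


def sccr(estimated, true, per_subskill: bool = True):
    """Subskill correct classification rate, pooled over replications.

    With ``per_subskill`` a length-K vector of agreement rates; otherwise
    the single rate averaged over subskills as well.
    """
    est = _stack(estimated)
    tru = _stack(true)
    if est.shape != tru.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {tru.shape}")
    agree = (est == tru)
    return agree.mean(axis=0) if per_subskill else float(agree.mean())


def pccr(estimated, true) -> float:
    """Pattern correct classification rate: whole-row agreement."""
    est = _stack(estimated)
    tru = _stack(true)
    if est.shape != tru.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {tru.shape}")
    return float((est == tru).all(axis=1).mean())


def mastery_proportion(states) -> np.ndarray:
    """Per-subskill proportion classified as masters."""
    return _stack(states).mean(axis=0)


def probability_histogram(probs: np.ndarray, n_bins: int = 50) -> np.ndarray:
    """K x n_bins frequency counts over equal-width bins on [0, 1].

    Bins are half-open [lo, hi) with the final bin closed, so counts sum
    to N per subskill.
    """
    if n_bins < 2:
        raise ValueError("need at least two bins")
    p = np.atleast_2d(np.asarray(probs, float))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return np.stack([np.histogram(p[:, k], bins=edges)[0]
                     for k in range(p.shape[1])])
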