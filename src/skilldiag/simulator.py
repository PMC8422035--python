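"""Synthetic response-data generator for the simulation study.

Abilities for N examinees are drawn from a K-variate normal with zero
mean, unit variances and a common (equi-)correlation r between all
subskill pairs.  Binary responses follow the compensatory
multidimensional 3PL model

    P(X_ij = 1 | theta_i) = c_j + (1 - c_j) * logistic(a_j . theta_i + d_j)

in the logistic metric (no 1.7 scaling constant), with the item
parameters of the packaged bank as the defaults of the study design
(N = 3,000 examinees, 30 items, r in {0.1, 0.3, 0.5, 0.7, 0.9}, 25
replications per condition).

Replication ``rep`` of a condition uses seed ``base_seed + rep`` for the
ability draw and ``base_seed + rep + 500_000`` for the Bernoulli draw,
so replications are reproducible and mutually independent work units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data_io import AbilityMatrix, MirtItemBank, ResponseMatrix

__all__ = [
    "SimulationCondition",
    "build_equicorrelated_cov",
    "sample_abilities",
    "response_probability",
    "simulate_responses",
    "ability_seed",
    "response_seed",
]

_RESPONSE_SEED_OFFSET = 500_000


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design: a subskill correlation plus sizes."""

    subskill_correlation: float
    n_persons: int = 3000
    n_subskills: int = 3
    n_replications: int = 25
    base_seed: int = 0

    def __post_init__(self):
        if self.n_persons <= 0 or self.n_replications <= 0:
            raise ValueError("n_persons and n_replications must be positive")
        # raises if not positive definite
        build_equicorrelated_cov(self.subskill_correlation, self.n_subskills)


def build_equicorrelated_cov(r: float, k: int) -> np.ndarray:
    """K x K covariance with unit variances and common off-diagonal r.

    Positive definite iff -1/(K-1) < r < 1 (eigenvalues 1 + (K-1)r and
    1 - r).
    """
    if k < 1:
        raise ValueError("need at least one dimension")
    if not (-1.0 / max(k - 1, 1) < r < 1.0):
        raise ValueError(
            f"equicorrelation r={r} is not positive definite for K={k}"
        )
    cov = np.full((k, k), float(r))
    np.fill_diagonal(cov, 1.0)
    return cov


def ability_seed(base_seed: int, replication: int) -> int:
    return int(base_seed) + int(replication)


def response_seed(base_seed: int, replication: int) -> int:
    return int(base_seed) + int(replication) + _RESPONSE_SEED_OFFSET


def sample_abilities(condition: SimulationCondition, seed: int) -> AbilityMatrix:
    """Draw N x K abilities from the condition's equicorrelated multinormal."""
    cov = build_equicorrelated_cov(condition.subskill_correlation,
                                   condition.n_subskills)
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((condition.n_persons, condition.n_subskills))
    return AbilityMatrix(z @ chol.T)


def response_probability(theta: np.ndarray, bank: MirtItemBank) -> np.ndarray:
    """Compensatory 3PL success probabilities.

    ``theta`` may be a single K-vector or an N x K matrix; the result has
    one probability per item (per person).
    """
    arr = np.asarray(theta, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != bank.n_skills:
        raise ValueError(
            f"theta has {arr.shape[1]} columns but the bank expects {bank.n_skills}"
        )
    z = arr @ bank.slopes.T + bank.intercepts
    p = bank.guessing + (1.0 - bank.guessing) * expit(z)
    return p[0] if single else p


def simulate_responses(abilities: AbilityMatrix, bank: MirtItemBank,
                       seed: int) -> ResponseMatrix:
    """Independent Bernoulli draws at the model-implied probabilities."""
    if abilities.n_skills != bank.n_skills:
        raise ValueError("ability and item-bank dimensions do not match")
    p = response_probability(abilities.theta, bank)
    rng = np.random.default_rng(seed)
    return ResponseMatrix((rng.random(p.shape) < p).astype(np.int8))
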