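"""Brute-force oracles and tiny synthetic cases for the test suite.

Everything here is deliberately slow and explicit — dense-grid numeric
integration, full latent-class enumeration, triple loops — and shares no
code with the optimized engines, so engine-vs-oracle agreement is an
independent check rather than a tautology.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import MirtItemBank, QMatrix, ResponseMatrix

__all__ = [
    "ToyCase",
    "oracle_mirt_loglik",
    "oracle_mirt_eap",
    "oracle_cdm_loglik",
    "oracle_sccr",
    "oracle_pccr",
    "random_restart_loglik",
    "make_toy_suite",
]


@dataclass
class ToyCase:
    """A small hand-checkable problem instance."""

    name: str
    qmatrix: QMatrix
    responses: ResponseMatrix
    bank: MirtItemBank | None = None          # MIRT truth, if applicable
    item_probs: list | None = None            # CDM: per item, per class prob
    class_probs: np.ndarray | None = None
    notes: str = ""
    expected: dict = field(default_factory=dict)


def _m3pl(theta_row, slopes, d, c):
    z = float(np.dot(slopes, theta_row)) + d
    return c + (1.0 - c) / (1.0 + math.exp(-z))


def oracle_mirt_loglik(bank: MirtItemBank, responses: ResponseMatrix,
                       n_grid: int = 10001, bound: float = 8.0) -> float:
    """Dense-grid numeric integration of the marginal likelihood (K = 1)."""
    if bank.n_skills != 1:
        raise ValueError("dense-grid oracle only supports one dimension")
    grid = np.linspace(-bound, bound, n_grid)
    dens = np.exp(-0.5 * grid ** 2) / math.sqrt(2 * math.pi)
    total = 0.0
    for row in responses.values:
        integrand = np.ones_like(grid)
        for jj, x in enumerate(row):
            p = np.array([_m3pl([t], bank.slopes[jj], bank.intercepts[jj],
                                bank.guessing[jj]) for t in grid])
            integrand = integrand * (p if x == 1 else (1.0 - p))
        total += math.log(np.trapezoid(integrand * dens, grid))
    return total


def oracle_mirt_eap(bank: MirtItemBank, responses: ResponseMatrix,
                    n_grid: int = 10001, bound: float = 8.0) -> np.ndarray:
    """Dense-grid posterior mean of theta (K = 1)."""
    if bank.n_skills != 1:
        raise ValueError("dense-grid oracle only supports one dimension")
    grid = np.linspace(-bound, bound, n_grid)
    dens = np.exp(-0.5 * grid ** 2) / math.sqrt(2 * math.pi)
    out = []
    for row in responses.values:
        integrand = dens.copy()
        for jj, x in enumerate(row):
            p = np.array([_m3pl([t], bank.slopes[jj], bank.intercepts[jj],
                                bank.guessing[jj]) for t in grid])
            integrand = integrand * (p if x == 1 else (1.0 - p))
        out.append(np.trapezoid(grid * integrand, grid)
                   / np.trapezoid(integrand, grid))
    return np.array(out).reshape(-1, 1)


def oracle_cdm_loglik(item_probs: list, class_probs: np.ndarray,
                      responses: ResponseMatrix) -> float:
    """Exact latent-class likelihood by full enumeration.

    ``item_probs[j][c]`` is the success probability of item j in class c.
    """
    n_class = len(class_probs)
    total = 0.0
    for row in responses.values:
        lik = 0.0
        for c in range(n_class):
            term = class_probs[c]
            for jj, x in enumerate(row):
                p = item_probs[jj][c]
                term *= p if x == 1 else (1.0 - p)
            lik += term
        total += math.log(lik)
    return total


def oracle_sccr(estimated: np.ndarray, true: np.ndarray) -> np.ndarray:
    """Per-subskill agreement rate by explicit loops."""
    n, k = estimated.shape
    out = np.zeros(k)
    for kk in range(k):
        agree = 0
        for i in range(n):
            if estimated[i, kk] == true[i, kk]:
                agree += 1
        out[kk] = agree / n
    return out


def oracle_pccr(estimated: np.ndarray, true: np.ndarray) -> float:
    n = estimated.shape[0]
    agree = 0
    for i in range(n):
        if all(estimated[i, kk] == true[i, kk]
               for kk in range(estimated.shape[1])):
            agree += 1
    return agree / n


def random_restart_loglik(q: QMatrix, responses: ResponseMatrix, model: str,
                          n_draws: int, seed: int) -> float:
    """Best exact likelihood over random parameter draws (lower bound on
    the maximized likelihood; used to sanity-check EM solutions)."""
    from .cdm_engine import attribute_patterns, item_probability

    rng = np.random.default_rng(seed)
    pats = attribute_patterns(q.n_skills)
    best = -np.inf
    for _ in range(n_draws):
        item_probs = []
        for jj in range(q.n_items):
            required = np.flatnonzero(q.entries[jj])
            if model == "gdina":
                params = {"probs": rng.uniform(0.05, 0.95, 2 ** required.size)}
            else:
                params = {"pi_star": rng.uniform(0.5, 0.99),
                          "r_star": rng.uniform(0.05, 0.95, required.size)}
            item_probs.append([item_probability(model, params, p,
                                                q.entries[jj]) for p in pats])
        w = rng.dirichlet(np.ones(len(pats)))
        best = max(best, oracle_cdm_loglik(item_probs, w, responses))
    return best


def make_toy_suite(seed: int = 7) -> list[ToyCase]:
    """Deterministic collection of tiny cases used across the test suite."""
    rng = np.random.default_rng(seed)
    suite = []

    # single-attribute MIRT case, K = 1
    q1 = QMatrix(np.ones((2, 1), dtype=int))
    bank1 = MirtItemBank(slopes=[[1.2], [0.8]], intercepts=[0.3, -0.5],
                         guessing=[0.2, 0.1])
    x1 = ResponseMatrix(np.array([[1, 0], [0, 0], [1, 1]]))
    suite.append(ToyCase("mirt-k1", q1, x1, bank=bank1,
                         notes="dense-grid integration target"))

    # multi-attribute CDM case, K = 2, with a mixed Q-matrix
    q2 = QMatrix(np.array([[1, 0], [0, 1], [1, 1]]))
    probs2 = [[0.2, 0.2, 0.8, 0.8],      # item 1 needs attr 1
              [0.3, 0.7, 0.3, 0.7],      # item 2 needs attr 2
              [0.1, 0.25, 0.25, 0.9]]    # item 3 needs both
    class2 = np.array([0.4, 0.2, 0.2, 0.2])
    x2 = ResponseMatrix(rng.integers(0, 2, size=(6, 3)))
    suite.append(ToyCase("cdm-k2", q2, x2, item_probs=probs2,
                         class_probs=class2,
                         notes="full-enumeration likelihood target"))

    # deliberate MLE tie: one item, flat probability across classes
    q3 = QMatrix(np.ones((1, 1), dtype=int))
    probs3 = [[0.5, 0.5]]
    x3 = ResponseMatrix(np.array([[1], [0]]))
    suite.append(ToyCase("mle-tie", q3, x3, item_probs=probs3,
                         class_probs=np.array([0.5, 0.5]),
                         notes="flat likelihood; canonical tie-break"))

    # degenerate all-correct person
    q4 = QMatrix(np.ones((3, 1), dtype=int))
    bank4 = MirtItemBank(slopes=[[1.0], [1.0], [1.0]],
                         intercepts=[0.0, 0.5, -0.5],
                         guessing=[0.0, 0.0, 0.0])
    x4 = ResponseMatrix(np.array([[1, 1, 1], [0, 0, 0]]))
    suite.append(ToyCase("all-correct", q4, x4, bank=bank4,
                         notes="monotone EAP check"))

    for case in suite:
        assert case.qmatrix.n_items == case.responses.n_items
    return suite
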