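"""Latent-class cognitive diagnosis engines: saturated G-DINA and R-RUM.

Both models place examinees in one of ``2**K`` binary attribute-mastery
patterns (canonical lexicographic order, all-zeros first) and are
estimated by EM with a saturated structural distribution over the
patterns.

G-DINA (identity link, saturated): item ``j`` with ``K_j`` required
attributes carries one success probability per reduced pattern of those
attributes; the M-step is the closed-form posterior-weighted success
proportion per reduced pattern.

R-RUM: ``P_j(alpha) = pi*_j * prod_k r*_jk^(q_jk (1 - alpha_k))`` — a
baseline success probability ``pi*_j`` for examinees mastering all
required attributes, discounted multiplicatively by ``r*_jk`` for each
required-but-missing attribute; the M-step is a bounded quasi-Newton
update on the logit scale.

Classification follows the MLE rule by default (argmax of the response
likelihood over patterns, structural weights excluded); MAP (argmax of
the posterior) is also provided.  Ties are broken toward the earliest
pattern in canonical order and counted.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from .data_io import QMatrix, ResponseMatrix, count_free_parameters

__all__ = [
    "CdmConfig",
    "CdmFit",
    "attribute_patterns",
    "item_probability",
    "fit_cdm_em",
    "posterior_skill_probabilities",
    "classify_patterns",
    "monotonicity_report",
]

_P_EPS = 1e-4
_TIE_TOL = 1e-10


def attribute_patterns(k: int) -> np.ndarray:
    """All 2**K mastery patterns in canonical order ((0,...,0) first)."""
    return np.array(list(itertools.product((0, 1), repeat=k)), dtype=int)


@dataclass(frozen=True)
class CdmConfig:
    max_iter: int = 1000
    tol: float = 1e-4
    gdina_start_range: tuple[float, float] = (0.2, 0.8)
    rrum_start: tuple[float, float] = (0.8, 0.4)   # (pi*, r*)
    mstep_tol: float = 1e-6


@dataclass
class CdmFit:
    """Fitted latent-class diagnosis model."""

    model: str                       # "gdina" | "rrum"
    qmatrix: QMatrix
    item_params: list                # per item: dict with model-specific keys
    class_probs: np.ndarray          # 2**K structural proportions
    posterior: np.ndarray            # N x 2**K
    log_likelihood: float
    n_parameters: int
    n_persons: int
    n_iterations: int
    converged: bool
    final_change: float
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    tie_count: int = 0

    @property
    def patterns(self) -> np.ndarray:
        return attribute_patterns(self.qmatrix.n_skills)

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_likelihood

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.n_parameters

    @property
    def bic(self) -> float:
        return self.deviance + self.n_parameters * np.log(self.n_persons)


# ---------------------------------------------------------------------------
# Item response functions
# ---------------------------------------------------------------------------

def _reduced_index(pattern: np.ndarray, required: np.ndarray) -> int:
    """Index of the reduced pattern of the required attributes (binary MSB-first)."""
    idx = 0
    for a in pattern[required]:
        idx = (idx << 1) | int(a)
    return idx


def item_probability(model: str, params: dict, pattern: np.ndarray,
                     q_row: np.ndarray) -> float:
    """Success probability of one item for one attribute pattern."""
    pattern = np.asarray(pattern, dtype=int)
    q_row = np.asarray(q_row, dtype=int)
    required = np.flatnonzero(q_row)
    if model == "gdina":
        return float(params["probs"][_reduced_index(pattern, required)])
    if model == "rrum":
        miss = (1 - pattern[required]).astype(float)
        return float(params["pi_star"] * np.prod(params["r_star"] ** miss))
    raise ValueError(f"unknown model {model!r}")


def _class_probability_table(model: str, item_params: list,
                             q: QMatrix) -> np.ndarray:
    """2**K x J table of P_j(alpha)."""
    pats = attribute_patterns(q.n_skills)
    table = np.empty((pats.shape[0], q.n_items))
    for jj in range(q.n_items):
        for ci, pat in enumerate(pats):
            table[ci, jj] = item_probability(model, item_params[jj], pat,
                                             q.entries[jj])
    return np.clip(table, _P_EPS, 1.0 - _P_EPS)


def _class_loglik(table: np.ndarray, x: np.ndarray) -> np.ndarray:
    """N x 2**K matrix of log P(x_i | alpha_c)."""
    logp, log1mp = np.log(table), np.log1p(-table)
    return x @ (logp - log1mp).T + log1mp.sum(axis=1)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _start_item_params(model: str, q: QMatrix, cfg: CdmConfig) -> list:
    params = []
    for jj in range(q.n_items):
        required = np.flatnonzero(q.entries[jj])
        kj = required.size
        if model == "gdina":
            lo, hi = cfg.gdina_start_range
            # spaced by number of mastered required attributes
            probs = np.empty(2 ** kj)
            for idx in range(2 ** kj):
                n_mastered = bin(idx).count("1")
                probs[idx] = lo + (hi - lo) * n_mastered / max(kj, 1)
            params.append({"probs": probs})
        else:
            pi0, r0 = cfg.rrum_start
            params.append({"pi_star": pi0, "r_star": np.full(kj, r0)})
    return params


def _mstep_gdina(item_params, q, post, x, reduced_map):
    """Closed-form expected success proportions per reduced pattern."""
    for jj in range(q.n_items):
        groups = reduced_map[jj]          # class index -> reduced index
        n_red = item_params[jj]["probs"].size
        num = np.zeros(n_red)
        den = np.zeros(n_red)
        pc = post.sum(axis=0)             # expected class counts
        rc = post.T @ x[:, jj]            # expected successes per class
        for ci in range(post.shape[1]):
            num[groups[ci]] += rc[ci]
            den[groups[ci]] += pc[ci]
        probs = item_params[jj]["probs"].copy()
        ok = den > 1e-10
        if not ok.all():
            warnings.warn(f"item {jj + 1}: empty expected count for a reduced "
                          "pattern; parameter held at previous value",
                          stacklevel=3)
        probs[ok] = np.clip(num[ok] / den[ok], _P_EPS, 1.0 - _P_EPS)
        item_params[jj]["probs"] = probs


def _rrum_negll(u, miss, rc, nc):
    """Expected complete-data negative log-likelihood for one R-RUM item.

    ``u = (logit pi*, logit r*_1..)``; ``miss[c, m]`` = 1 when required
    attribute m is missing in class c.
    """
    pi = expit(u[0])
    r = expit(u[1:])
    logp = np.log(pi) + miss @ np.log(r)
    p = np.clip(np.exp(logp), _P_EPS, 1.0 - _P_EPS)
    return -(rc * np.log(p) + (nc - rc) * np.log1p(-p)).sum()


def _mstep_rrum(item_params, q, post, x, cfg):
    pc = post.sum(axis=0)
    pats = attribute_patterns(q.n_skills)
    for jj in range(q.n_items):
        required = np.flatnonzero(q.entries[jj])
        miss = (1 - pats[:, required]).astype(float)
        rc = post.T @ x[:, jj]
        u0 = np.concatenate([[logit(np.clip(item_params[jj]["pi_star"],
                                            _P_EPS, 1 - _P_EPS))],
                             logit(np.clip(item_params[jj]["r_star"],
                                           _P_EPS, 1 - _P_EPS))])
        res = optimize.minimize(
            _rrum_negll, u0, args=(miss, rc, pc), method="L-BFGS-B",
            bounds=[(-9.0, 9.0)] * u0.size,
            options={"ftol": cfg.mstep_tol, "maxiter": 60},
        )
        item_params[jj]["pi_star"] = float(expit(res.x[0]))
        item_params[jj]["r_star"] = expit(res.x[1:])


def _pack(model, item_params, class_probs):
    parts = [class_probs]
    for p in item_params:
        if model == "gdina":
            parts.append(p["probs"])
        else:
            parts.append(np.concatenate([[p["pi_star"]], p["r_star"]]))
    return np.concatenate(parts)


def fit_cdm_em(responses: ResponseMatrix, q: QMatrix, model: str,
               config: CdmConfig | None = None) -> CdmFit:
    """Fit G-DINA or R-RUM by EM over the 2**K latent classes.

    The structural distribution is saturated: class proportions are the
    mean posterior at each cycle.
    """
    model = model.strip().lower().replace("-", "")
    if model not in ("gdina", "rrum"):
        raise ValueError(f"unknown model {model!r}")
    cfg = config or CdmConfig()
    x = responses.values.astype(float)
    n = x.shape[0]
    k = q.n_skills
    n_class = 2 ** k
    pats = attribute_patterns(k)
    reduced_map = []
    for jj in range(q.n_items):
        required = np.flatnonzero(q.entries[jj])
        reduced_map.append(np.array([_reduced_index(p, required) for p in pats]))

    item_params = _start_item_params(model, q, cfg)
    class_probs = np.full(n_class, 1.0 / n_class)

    prev = _pack(model, item_params, class_probs)
    trace = []
    converged = False
    delta = np.inf
    it = 0
    for it in range(1, cfg.max_iter + 1):
        table = _class_probability_table(model, item_params, q)
        ll = _class_loglik(table, x) + np.log(class_probs)
        m = ll.max(axis=1, keepdims=True)
        e = np.exp(ll - m)
        s = e.sum(axis=1, keepdims=True)
        loglik = float((m.ravel() + np.log(s.ravel())).sum())
        trace.append(loglik)
        post = e / s
        class_probs = post.mean(axis=0)
        class_probs = class_probs / class_probs.sum()
        if model == "gdina":
            _mstep_gdina(item_params, q, post, x, reduced_map)
        else:
            _mstep_rrum(item_params, q, post, x, cfg)
        cur = _pack(model, item_params, class_probs)
        delta = float(np.abs(cur - prev).max())
        prev = cur
        if delta < cfg.tol:
            converged = True
            break

    table = _class_probability_table(model, item_params, q)
    ll = _class_loglik(table, x) + np.log(class_probs)
    m = ll.max(axis=1, keepdims=True)
    e = np.exp(ll - m)
    s = e.sum(axis=1, keepdims=True)
    loglik = float((m.ravel() + np.log(s.ravel())).sum())
    post = e / s
    if not converged:
        warnings.warn(f"EM did not converge in {cfg.max_iter} iterations "
                      f"(last max change {delta:.2e})", stacklevel=2)
    return CdmFit(
        model=model, qmatrix=q, item_params=item_params,
        class_probs=class_probs, posterior=post, log_likelihood=loglik,
        n_parameters=count_free_parameters(model, q), n_persons=n,
        n_iterations=it, converged=converged, final_change=delta,
        objective_trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# Scoring and classification
# ---------------------------------------------------------------------------

def posterior_skill_probabilities(fit: CdmFit) -> np.ndarray:
    """N x K posterior mastery probability: sum of posterior over patterns
    with the attribute mastered."""
    return fit.posterior @ fit.patterns


def classify_patterns(fit: CdmFit, responses: ResponseMatrix,
                      rule: str = "MLE") -> np.ndarray:
    """N x K binary mastery states under the MLE or MAP rule.

    MLE maximizes the response likelihood over patterns (structural
    proportions excluded); MAP maximizes the posterior.  Ties go to the
    earliest pattern in canonical order; the tie count is recorded on the
    fit.
    """
    rule = rule.upper()
    x = responses.values.astype(float)
    table = _class_probability_table(fit.model, fit.item_params, fit.qmatrix)
    score = _class_loglik(table, x)
    if rule == "MAP":
        score = score + np.log(fit.class_probs)
    elif rule != "MLE":
        raise ValueError(f"unknown rule {rule!r}")
    best = score.max(axis=1, keepdims=True)
    ties = int(((score >= best - _TIE_TOL).sum(axis=1) > 1).sum())
    if ties:
        warnings.warn(f"{ties} persons had tied {rule} patterns; earliest "
                      "canonical pattern used", stacklevel=2)
    fit.tie_count = ties
    idx = score.argmax(axis=1)
    return fit.patterns[idx]


def monotonicity_report(fit: CdmFit) -> list[tuple[int, int, int]]:
    """Post-hoc check: (item, pattern-pair) triples where mastering more
    required attributes lowers the modeled success probability."""
    violations = []
    pats = attribute_patterns(fit.qmatrix.n_skills)
    for jj in range(fit.qmatrix.n_items):
        q_row = fit.qmatrix.entries[jj]
        probs = [item_probability(fit.model, fit.item_params[jj], p, q_row)
                 for p in pats]
        for a in range(len(pats)):
            for b in range(len(pats)):
                if (pats[a] >= pats[b]).all() and not (pats[a] == pats[b]).all():
                    if probs[a] < probs[b] - 1e-12:
                        violations.append((jj, a, b))
    return violations
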