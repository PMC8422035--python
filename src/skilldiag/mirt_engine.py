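"""Confirmatory compensatory 3PL MIRT calibration.

Marginal maximum likelihood via EM on a fixed rectangular quadrature
grid.  The E-step computes each person's posterior over the grid under
the current item parameters and latent density; the M-step maximizes the
expected complete-data log-likelihood item by item (bounded
quasi-Newton with analytic gradients).  Slopes are constrained to the
Q-matrix sparsity pattern and kept non-negative; guessing parameters are
estimated on the logit scale under a weak normal prior (mean logit 0.2,
sd 1.0) because unpenalized 3PL lower asymptotes are notoriously
unstable.

Three latent-density modes are supported:

``identity``
    fixed standard multinormal prior (the parameter count then equals
    nnz(Q) + 2J, e.g. 99 for the packaged 30-item instrument);
``fixed``
    a user-supplied correlation matrix, not counted as free parameters;
``estimated``
    unit variances with the K(K-1)/2 correlations re-estimated from the
    posterior second moments each EM cycle (adds K(K-1)/2 parameters).

Scoring is EAP (posterior mean over the grid).  Goodness of fit is
reported as -2LL, AIC, BIC and the limited-information M2 statistic on
first- and second-order margins with its RMSEA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import chi2

from .data_io import (AbilityMatrix, MirtItemBank, QMatrix, ResponseMatrix,
                      count_free_parameters)

__all__ = [
    "MirtConfig",
    "MirtFit",
    "M2Result",
    "fit_mirt_em",
    "marginal_log_likelihood",
    "eap_scores",
    "m2_statistic",
    "rmsea_from_m2",
    "make_quadrature",
]

_P_FLOOR = 1e-9


@dataclass(frozen=True)
class MirtConfig:
    """Tuning knobs for the EM calibration."""

    quad_points: int = 15          # per dimension, equally spaced
    quad_bound: float = 5.0        # grid spans [-bound, bound]
    latent: str = "identity"       # identity | fixed | estimated
    latent_cov: np.ndarray | None = None   # used when latent == "fixed"
    estimate_guessing: bool = True
    fixed_guessing: float | np.ndarray = 0.15
    guess_prior_mean: float = float(logit(0.2))
    guess_prior_sd: float = 1.0
    max_iter: int = 300
    tol: float = 1e-4              # max |parameter change|
    mstep_maxiter: int = 40

    def __post_init__(self):
        if self.quad_points < 2:
            raise ValueError("quadrature needs more than one point per dimension")
        if self.latent not in ("identity", "fixed", "estimated"):
            raise ValueError(f"unknown latent mode {self.latent!r}")


@dataclass
class M2Result:
    """Limited-information goodness of fit on uni- and bivariate margins."""

    statistic: float
    df: int
    p_value: float
    rmsea: float
    regularized: bool = False


@dataclass
class MirtFit:
    """Result of an EM calibration run."""

    bank: MirtItemBank
    qmatrix: QMatrix
    latent_mode: str
    latent_cov: np.ndarray
    quad_points: int
    quad_bound: float
    log_likelihood: float
    n_parameters: int
    n_persons: int
    n_iterations: int
    converged: bool
    final_change: float
    guessing_estimated: bool = True
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

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
# Quadrature
# ---------------------------------------------------------------------------

def make_quadrature(k: int, points: int, bound: float = 5.0) -> np.ndarray:
    """Cartesian grid of ``points**k`` nodes on [-bound, bound]^k."""
    if points < 2:
        raise ValueError("quadrature needs more than one point per dimension")
    axis = np.linspace(-bound, bound, points)
    mesh = np.meshgrid(*([axis] * k), indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def quadrature_weights(nodes: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Multinormal density at the nodes, normalized to sum to one.

    Computed from the quadratic form directly (the normalizing constant
    cancels), with a tiny jitter so strongly correlated latent densities
    near the singular boundary remain usable.
    """
    cov = np.asarray(cov, dtype=float)
    jitter = 1e-10 * np.eye(cov.shape[0])
    quad_form = (nodes * np.linalg.solve(cov + jitter, nodes.T).T).sum(axis=1)
    logw = -0.5 * (quad_form - quad_form.min())
    w = np.exp(logw)
    return w / w.sum()


def _grid_probabilities(bank: MirtItemBank, nodes: np.ndarray) -> np.ndarray:
    z = nodes @ bank.slopes.T + bank.intercepts
    p = bank.guessing + (1.0 - bank.guessing) * expit(z)
    return np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)


def _person_loglik(bank: MirtItemBank, x: np.ndarray,
                   nodes: np.ndarray) -> np.ndarray:
    """N x G matrix of log P(x_i | theta_g)."""
    p = _grid_probabilities(bank, nodes)
    logp, log1mp = np.log(p), np.log1p(-p)
    return x @ (logp - log1mp).T + log1mp.sum(axis=1)


def _posterior(bank: MirtItemBank, x: np.ndarray, nodes: np.ndarray,
               weights: np.ndarray):
    """Posterior over grid nodes plus the observed-data log-likelihood."""
    ll = _person_loglik(bank, x, nodes) + np.log(np.maximum(weights, 1e-300))
    m = ll.max(axis=1, keepdims=True)
    e = np.exp(ll - m)
    s = e.sum(axis=1, keepdims=True)
    loglik = float((m.ravel() + np.log(s.ravel())).sum())
    return e / s, loglik


def marginal_log_likelihood(bank: MirtItemBank, responses: ResponseMatrix,
                            latent_cov: np.ndarray | None = None,
                            quad_points: int = 15,
                            quad_bound: float = 5.0) -> float:
    """Observed-data log-likelihood on the quadrature grid.

    ``sum_i log sum_g w_g prod_j P_j(theta_g)^x_ij (1-P_j)^(1-x_ij)``.
    """
    k = bank.n_skills
    if latent_cov is None:
        latent_cov = np.eye(k)
    nodes = make_quadrature(k, quad_points, quad_bound)
    weights = quadrature_weights(nodes, latent_cov)
    x = responses.values.astype(float)
    _, loglik = _posterior(bank, x, nodes, weights)
    return loglik


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

def _item_objective(params, a_nodes, n_g, r_g, cfg: MirtConfig, fix_gamma):
    """Negative expected complete-data log-likelihood for one item (+prior)."""
    m = a_nodes.shape[1]
    a = params[:m]
    d = params[m]
    gamma = fix_gamma if fix_gamma is not None else params[m + 1]
    z = a_nodes @ a + d
    s = expit(z)
    c = expit(gamma)
    p = np.clip(c + (1.0 - c) * s, _P_FLOOR, 1.0 - _P_FLOOR)
    f = -(r_g * np.log(p) + (n_g - r_g) * np.log1p(-p)).sum()
    dfdp = -(r_g / p - (n_g - r_g) / (1.0 - p))
    dpdz = (1.0 - c) * s * (1.0 - s)
    common = dfdp * dpdz
    grad_a = common @ a_nodes
    grad_d = common.sum()
    if fix_gamma is None:
        resid = (gamma - cfg.guess_prior_mean) / cfg.guess_prior_sd
        f += 0.5 * resid * resid
        grad_gamma = (dfdp * (1.0 - s)).sum() * c * (1.0 - c) \
            + resid / cfg.guess_prior_sd
        return f, np.concatenate([grad_a, [grad_d, grad_gamma]])
    return f, np.concatenate([grad_a, [grad_d]])


def _maximize_item(a_start, d_start, gamma_start, a_nodes, n_g, r_g,
                   cfg: MirtConfig, estimate_guessing: bool):
    m = a_nodes.shape[1]
    if estimate_guessing:
        x0 = np.concatenate([a_start, [d_start, gamma_start]])
        bounds = [(0.0, 8.0)] * m + [(-20.0, 20.0), (-8.0, 1.5)]
        fix_gamma = None
    else:
        x0 = np.concatenate([a_start, [d_start]])
        bounds = [(0.0, 8.0)] * m + [(-20.0, 20.0)]
        fix_gamma = gamma_start
    res = optimize.minimize(
        _item_objective, x0, args=(a_nodes, n_g, r_g, cfg, fix_gamma),
        method="L-BFGS-B", jac=True, bounds=bounds,
        options={"maxiter": cfg.mstep_maxiter, "ftol": 1e-10, "gtol": 1e-7},
    )
    a = res.x[:m]
    d = res.x[m]
    gamma = res.x[m + 1] if estimate_guessing else gamma_start
    return a, d, gamma


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

def _start_values(responses: ResponseMatrix, q: QMatrix, cfg: MirtConfig):
    """Slopes 1 on the Q support, intercepts from item logits, guessing 0.15."""
    x = responses.values
    phat = np.clip(x.mean(axis=0), 0.01, 0.99)
    slopes = q.entries.astype(float).copy()
    intercepts = logit(phat)
    if cfg.estimate_guessing:
        guessing = np.full(q.n_items, 0.15)
    else:
        guessing = np.broadcast_to(
            np.asarray(cfg.fixed_guessing, dtype=float), (q.n_items,)
        ).copy()
    return slopes, intercepts, guessing


def _corr_from_moments(nodes: np.ndarray, n_g: np.ndarray) -> np.ndarray:
    s = nodes.T @ (n_g[:, None] * nodes) / n_g.sum()
    d = np.sqrt(np.diag(s))
    r = s / np.outer(d, d)
    r = np.clip(r, -0.99, 0.99)   # keep the latent density non-singular
    np.fill_diagonal(r, 1.0)
    return r


def fit_mirt_em(responses: ResponseMatrix, q: QMatrix,
                config: MirtConfig | None = None) -> MirtFit:
    """Calibrate the confirmatory compensatory 3PL MIRT model by EM.

    Returns a flagged (``converged=False``) fit rather than raising when
    the parameter change has not dropped below tolerance within
    ``max_iter`` cycles.
    """
    cfg = config or MirtConfig()
    x = responses.values.astype(float)
    n, j = x.shape
    k = q.n_skills
    means = x.mean(axis=0)
    if (means == 0).any() or (means == 1).any():
        warnings.warn("some items have all-0 or all-1 responses; their "
                      "parameters are weakly identified", stacklevel=2)

    nodes = make_quadrature(k, cfg.quad_points, cfg.quad_bound)
    if cfg.latent == "fixed":
        if cfg.latent_cov is None:
            raise ValueError("latent='fixed' requires latent_cov")
        cov = np.asarray(cfg.latent_cov, dtype=float)
    else:
        cov = np.eye(k)
    weights = quadrature_weights(nodes, cov)

    slopes, intercepts, guessing = _start_values(responses, q, cfg)
    gammas = logit(np.clip(guessing, 1e-4, 0.99))
    q_rows = [np.flatnonzero(q.entries[jj]) for jj in range(j)]
    a_nodes_per_item = [nodes[:, idx] for idx in q_rows]
    mask = q.entries.astype(bool)

    n_params = count_free_parameters(
        "mirt", q, estimate_correlations=(cfg.latent == "estimated"))
    if not cfg.estimate_guessing:
        n_params -= j        # fixed lower asymptotes are not free

    def prior_term():
        if not cfg.estimate_guessing:
            return 0.0
        resid = (gammas - cfg.guess_prior_mean) / cfg.guess_prior_sd
        return -0.5 * float(resid @ resid)

    def pack():
        parts = [slopes[mask], intercepts, expit(gammas)]
        if cfg.latent == "estimated":
            parts.append(cov[np.triu_indices(k, 1)])
        return np.concatenate(parts)

    trace = []
    converged = False
    delta = np.inf
    prev = pack()
    it = 0
    loglik = -np.inf
    for it in range(1, cfg.max_iter + 1):
        bank = MirtItemBank(slopes, intercepts, expit(gammas))
        post, loglik = _posterior(bank, x, nodes, weights)
        trace.append(loglik + prior_term())
        n_g = post.sum(axis=0)
        r_gj = post.T @ x
        for jj in range(j):
            idx = q_rows[jj]
            a, d, g = _maximize_item(
                slopes[jj, idx], intercepts[jj], gammas[jj],
                a_nodes_per_item[jj], n_g, r_gj[:, jj], cfg,
                cfg.estimate_guessing)
            slopes[jj, idx] = a
            intercepts[jj] = d
            gammas[jj] = g
        if cfg.latent == "estimated":
            cov = _corr_from_moments(nodes, n_g)
            weights = quadrature_weights(nodes, cov)
        cur = pack()
        delta = float(np.abs(cur - prev).max())
        prev = cur
        if delta < cfg.tol:
            converged = True
            break

    bank = MirtItemBank(slopes, intercepts, expit(gammas))
    _, loglik = _posterior(bank, x, nodes, weights)
    if not converged:
        warnings.warn(f"EM did not converge in {cfg.max_iter} iterations "
                      f"(last max change {delta:.2e})", stacklevel=2)
    return MirtFit(
        bank=bank, qmatrix=q, latent_mode=cfg.latent, latent_cov=cov,
        quad_points=cfg.quad_points, quad_bound=cfg.quad_bound,
        log_likelihood=loglik, n_parameters=n_params, n_persons=n,
        n_iterations=it, converged=converged, final_change=delta,
        guessing_estimated=cfg.estimate_guessing,
        objective_trace=np.asarray(trace),
    )


def eap_scores(fit: MirtFit, responses: ResponseMatrix) -> AbilityMatrix:
    """Posterior-mean theta per person under the fit's latent density."""
    nodes = make_quadrature(fit.qmatrix.n_skills, fit.quad_points,
                            fit.quad_bound)
    weights = quadrature_weights(nodes, fit.latent_cov)
    post, _ = _posterior(fit.bank, responses.values.astype(float),
                         nodes, weights)
    return AbilityMatrix(post @ nodes)


# ---------------------------------------------------------------------------
# Limited-information goodness of fit (M2 / RMSEA)
# ---------------------------------------------------------------------------

def rmsea_from_m2(statistic: float, df: int, n: int) -> float:
    """RMSEA = sqrt(max(M2 - df, 0) / (df * N))."""
    return float(np.sqrt(max(statistic - df, 0.0) / (df * n)))


def m2_degrees_of_freedom(n_items: int, n_parameters: int) -> int:
    """df of M2: univariate plus bivariate margins minus free parameters."""
    df = n_items + n_items * (n_items - 1) // 2 - n_parameters
    if df <= 0:
        raise ValueError("model has as many parameters as low-order margins")
    return df


def _model_margins(bank: MirtItemBank, nodes, weights, pairs):
    p = _grid_probabilities(bank, nodes)
    pi1 = weights @ p
    pp = p[:, pairs[:, 0]] * p[:, pairs[:, 1]]
    pi2 = weights @ pp
    return pi1, pi2, p, pp


def _free_param_views(fit: MirtFit):
    """(get, set) closures over the fit's free parameters, FD-perturbable."""
    q = fit.qmatrix
    mask = q.entries.astype(bool)
    with_guess = fit.guessing_estimated

    def get():
        parts = [fit.bank.slopes[mask], fit.bank.intercepts]
        if with_guess:
            parts.append(fit.bank.guessing)
        if fit.latent_mode == "estimated":
            parts.append(fit.latent_cov[np.triu_indices(q.n_skills, 1)])
        return np.concatenate(parts)

    def build(vec):
        nnz = int(mask.sum())
        j, k = q.entries.shape
        slopes = np.zeros((j, k))
        slopes[mask] = vec[:nnz]
        intercepts = vec[nnz:nnz + j]
        pos = nnz + j
        if with_guess:
            guessing = np.clip(vec[pos:pos + j], 0.0, 0.999)
            pos += j
        else:
            guessing = fit.bank.guessing
        bank = MirtItemBank(slopes, intercepts, guessing)
        cov = fit.latent_cov
        if fit.latent_mode == "estimated":
            cov = np.eye(k)
            iu = np.triu_indices(k, 1)
            cov[iu] = vec[pos:]
            cov = cov + cov.T - np.diag(np.diag(cov))
            np.fill_diagonal(cov, 1.0)
        return bank, cov

    return get, build


def m2_statistic(fit: MirtFit, responses: ResponseMatrix,
                 ridge: float = 0.0) -> M2Result:
    """M2 on univariate and bivariate margins with the reduced weight matrix.

    The statistic is ``N e' C e`` with ``e`` the residual between sample
    and model-implied margins and ``C = Xi^-1 - Xi^-1 D (D' Xi^-1 D)^-1
    D' Xi^-1`` where ``Xi`` is the asymptotic covariance of the sample
    margins under the model and ``D`` the Jacobian of the margins with
    respect to the free parameters.  A singular ``Xi`` triggers a flagged
    ridge fallback.
    """
    x = responses.values.astype(float)
    n, j = x.shape
    k = fit.qmatrix.n_skills
    nodes = make_quadrature(k, fit.quad_points, fit.quad_bound)
    pairs = np.array([(a, b) for a in range(j) for b in range(a + 1, j)])

    get, build = _free_param_views(fit)

    def margins_at(vec):
        bank, cov = build(vec)
        weights = quadrature_weights(nodes, cov)
        pi1, pi2, _, _ = _model_margins(bank, nodes, weights, pairs)
        return np.concatenate([pi1, pi2])

    theta0 = get()
    weights = quadrature_weights(nodes, fit.latent_cov)
    pi1, pi2, p, pp = _model_margins(fit.bank, nodes, weights, pairs)
    pi = np.concatenate([pi1, pi2])

    # sample margins
    s1 = x.mean(axis=0)
    s2 = (x[:, pairs[:, 0]] * x[:, pairs[:, 1]]).mean(axis=0)
    resid = np.concatenate([s1, s2]) - pi

    xi = _margin_covariance(p, pp, weights, pairs, pi1, pi2)

    # Jacobian by central finite differences
    delta = np.zeros((pi.size, theta0.size))
    h = 1e-5
    for t in range(theta0.size):
        up = theta0.copy(); up[t] += h
        dn = theta0.copy(); dn[t] -= h
        delta[:, t] = (margins_at(up) - margins_at(dn)) / (2 * h)

    regularized = False
    if ridge:
        xi = xi + ridge * np.eye(xi.shape[0])
        regularized = True
    try:
        xi_inv_r = np.linalg.solve(xi, resid)
        xi_inv_d = np.linalg.solve(xi, delta)
    except np.linalg.LinAlgError:
        warnings.warn("margin covariance is singular; applying ridge "
                      "regularization", stacklevel=2)
        regularized = True
        xi = xi + 1e-8 * np.eye(xi.shape[0])
        xi_inv_r = np.linalg.solve(xi, resid)
        xi_inv_d = np.linalg.solve(xi, delta)
    middle = delta.T @ xi_inv_d
    rhs = delta.T @ xi_inv_r
    stat = float(n * (resid @ xi_inv_r - rhs @ np.linalg.solve(middle, rhs)))
    stat = max(stat, 0.0)
    df = j + j * (j - 1) // 2 - fit.n_parameters
    if df <= 0:
        raise ValueError("M2 degrees of freedom are not positive for this model")
    return M2Result(
        statistic=stat, df=df, p_value=float(chi2.sf(stat, df)),
        rmsea=rmsea_from_m2(stat, df, n), regularized=regularized,
    )


def _margin_covariance(p, pp, weights, pairs, pi1, pi2):
    """Asymptotic covariance of (univariate, bivariate) sample margins."""
    j = p.shape[1]
    npairs = pairs.shape[0]
    wp = weights[:, None] * p                       # G x J
    # unions: pi over triples T3[j, pair] = sum_g w p_j p_a p_b (j not in pair)
    t3 = wp.T @ pp                                  # J x npairs
    # 4-way products (squares corrected below)
    wpp = weights[:, None] * pp
    m4 = pp.T @ wpp                                 # npairs x npairs

    pair_index = {(int(a), int(b)): i for i, (a, b) in enumerate(pairs)}

    # block (1,1)
    b11 = np.empty((j, j))
    for a in range(j):
        for b in range(j):
            if a == b:
                b11[a, b] = pi1[a] * (1 - pi1[a])
            else:
                key = (a, b) if a < b else (b, a)
                b11[a, b] = pi2[pair_index[key]] - pi1[a] * pi1[b]

    # block (1,2): Cov(x_j, x_a x_b) = pi_{union(j,a,b)} - pi_j pi_ab
    b12 = t3 - np.outer(pi1, pi2)
    for (a, b), idx in pair_index.items():
        b12[a, idx] = pi2[idx] - pi1[a] * pi2[idx]
        b12[b, idx] = pi2[idx] - pi1[b] * pi2[idx]

    # block (2,2): Cov(x_a x_b, x_c x_d) = pi_union - pi_ab pi_cd.  The
    # naive 4-way product matrix squares any shared item, so entries for
    # pairs that overlap in one item are replaced with the triple
    # probability of the union, and the diagonal with the pair variance.
    b22 = m4 - np.outer(pi2, pi2)
    for i1, (a, b) in enumerate(pairs):
        b22[i1, i1] = pi2[i1] * (1 - pi2[i1])
        for c in range(j):
            if c in (a, b):
                continue
            for s in (a, b):
                key = (s, c) if s < c else (c, s)
                i2 = pair_index[key]
                u, v, w = sorted({a, b, c})
                tri = t3[u, pair_index[(v, w)]]
                val = tri - pi2[i1] * pi2[i2]
                b22[i1, i2] = val
                b22[i2, i1] = val

    top = np.hstack([b11, b12])
    bottom = np.hstack([b12.T, b22])
    return np.vstack([top, bottom])
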