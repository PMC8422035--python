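import numpy as np
import pytest

from skilldiag.data_io import (AbilityMatrix, MirtItemBank, QMatrix,
                               ResponseMatrix)
from skilldiag.mirt_engine import (MirtConfig, MirtFit, eap_scores,
                                   fit_mirt_em, m2_degrees_of_freedom,
                                   m2_statistic, make_quadrature,
                                   marginal_log_likelihood, rmsea_from_m2)
from skilldiag.oracles import oracle_mirt_eap, oracle_mirt_loglik
from skilldiag.simulator import (SimulationCondition, sample_abilities,
                                 simulate_responses)


def _truth_fit(bank, q, quad_points=301, bound=8.0):
    """Wrap a known bank in a MirtFit so scoring helpers can run on it."""
    return MirtFit(
        bank=bank, qmatrix=q, latent_mode="identity",
        latent_cov=np.eye(q.n_skills), quad_points=quad_points,
        quad_bound=bound, log_likelihood=0.0, n_parameters=0, n_persons=0,
        n_iterations=0, converged=True, final_change=0.0,
    )


class TestMarginalLikelihood:
    def test_constant_probability_item(self):
        # d = 0, zero slope -> every response has probability 1/2
        q = QMatrix(np.array([[1]]))
        bank = MirtItemBank([[0.0]], [0.0], [0.0])
        x = ResponseMatrix(np.array([[1], [0], [1]]))
        ll = marginal_log_likelihood(bank, x, quad_points=21)
        assert ll == pytest.approx(3 * np.log(0.5), abs=1e-10)

    def test_matches_dense_grid_oracle(self, toy_suite):
        case = toy_suite["mirt-k1"]
        engine = marginal_log_likelihood(case.bank, case.responses,
                                         quad_points=301, quad_bound=8.0)
        oracle = oracle_mirt_loglik(case.bank, case.responses)
        assert engine == pytest.approx(oracle, abs=1e-6)

    def test_duplicated_person_doubles_contribution(self, toy_suite):
        case = toy_suite["mirt-k1"]
        x = case.responses.values
        doubled = ResponseMatrix(np.vstack([x, x[:1]]))
        base = marginal_log_likelihood(case.bank, case.responses,
                                       quad_points=101)
        extra = marginal_log_likelihood(case.bank, doubled, quad_points=101)
        single = marginal_log_likelihood(case.bank, ResponseMatrix(x[:1]),
                                         quad_points=101)
        assert extra == pytest.approx(base + single, abs=1e-9)

    def test_degenerate_quadrature_rejected(self, toy_suite):
        case = toy_suite["mirt-k1"]
        with pytest.raises(ValueError):
            marginal_log_likelihood(case.bank, case.responses, quad_points=1)


class TestEap:
    def test_matches_dense_grid_oracle(self, toy_suite):
        case = toy_suite["mirt-k1"]
        fit = _truth_fit(case.bank, case.qmatrix)
        engine = eap_scores(fit, case.responses).theta
        oracle = oracle_mirt_eap(case.bank, case.responses)
        np.testing.assert_allclose(engine, oracle, atol=1e-4)

    def test_uninformative_dimension_scores_at_prior_mean(self):
        # two skills, but every item loads only on the first
        q = QMatrix(np.array([[1, 0], [1, 1]]))  # placeholder valid Q
        bank = MirtItemBank([[1.0, 0.0], [1.2, 0.0]], [0.0, 0.3], [0.0, 0.0])
        x = ResponseMatrix(np.array([[1, 1], [0, 0]]))
        fit = _truth_fit(bank, q, quad_points=61, bound=5.0)
        eap = eap_scores(fit, x).theta
        np.testing.assert_allclose(eap[:, 1], 0.0, atol=1e-10)

    def test_all_correct_dominates_all_incorrect(self, toy_suite):
        case = toy_suite["all-correct"]
        fit = _truth_fit(case.bank, case.qmatrix, quad_points=61)
        eap = eap_scores(fit, case.responses).theta
        assert (eap[0] > eap[1]).all()


@pytest.fixture(scope="module")
def small_fit():
    rng = np.random.default_rng(17)
    j, n = 8, 2500
    q = QMatrix(np.ones((j, 1), dtype=int))
    bank = MirtItemBank(rng.uniform(0.5, 2.0, (j, 1)),
                        rng.uniform(-1, 1, j), np.zeros(j))
    theta = AbilityMatrix(rng.standard_normal((n, 1)))
    from skilldiag.simulator import response_probability
    p = response_probability(theta.theta, bank)
    x = ResponseMatrix((rng.random(p.shape) < p).astype(int))
    cfg = MirtConfig(quad_points=31, latent="identity",
                     estimate_guessing=False, fixed_guessing=0.0)
    return q, bank, x, fit_mirt_em(x, q, cfg)


class TestEmFit:
    def test_objective_monotone_nondecreasing(self, small_fit):
        trace = small_fit[3].objective_trace
        assert (np.diff(trace) > -1e-6).all()

    def test_parameter_count_excludes_fixed_guessing(self, small_fit):
        q, _, _, fit = small_fit
        assert fit.n_parameters == q.nnz + q.n_items

    def test_information_criteria_formulas(self, small_fit):
        _, _, x, fit = small_fit
        assert fit.aic == pytest.approx(fit.deviance + 2 * fit.n_parameters)
        assert fit.bic == pytest.approx(
            fit.deviance + fit.n_parameters * np.log(x.n_persons))
        assert fit.bic - fit.deviance > fit.aic - fit.deviance  # ln N > 2

    def test_recovers_generating_parameters(self, small_fit):
        q, bank, _, fit = small_fit
        assert np.corrcoef(bank.slopes.ravel(),
                           fit.bank.slopes.ravel())[0, 1] > 0.9
        np.testing.assert_allclose(fit.bank.intercepts, bank.intercepts,
                                   atol=0.25)

    def test_zero_slope_data_reaches_independence_limit(self):
        """Responses independent of theta: the fitted likelihood sits at
        the Bernoulli entropy bound (plus at most the usual overfit of
        roughly half a unit per free parameter), and a typical slope is
        near zero."""
        rng = np.random.default_rng(3)
        j, n = 8, 4000
        q = QMatrix(np.ones((j, 1), dtype=int))
        x = ResponseMatrix((rng.random((n, j)) < 0.6).astype(int))
        cfg = MirtConfig(quad_points=21, latent="identity",
                         estimate_guessing=False, fixed_guessing=0.0,
                         max_iter=1000, tol=1e-5)
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_mirt_em(x, q, cfg)
        phat = x.values.mean(axis=0)
        bernoulli = n * (phat * np.log(phat)
                         + (1 - phat) * np.log(1 - phat)).sum()
        assert bernoulli <= fit.log_likelihood <= bernoulli + 2 * q.nnz
        assert np.median(fit.bank.slopes) < 0.3

    def test_nonconvergence_is_flagged_not_raised(self, toy_suite):
        case = toy_suite["mirt-k1"]
        cfg = MirtConfig(quad_points=11, max_iter=2, latent="identity")
        with pytest.warns(UserWarning, match="did not converge"):
            fit = fit_mirt_em(case.responses, case.qmatrix, cfg)
        assert not fit.converged


class TestM2:
    def test_df_bookkeeping_for_reference_instrument(self, qmatrix):
        from skilldiag.data_io import count_free_parameters
        p = count_free_parameters("mirt", qmatrix)
        assert m2_degrees_of_freedom(qmatrix.n_items, p) == 366

    def test_rmsea_formula_and_clamp(self):
        assert rmsea_from_m2(2042.59, 366, 3077) == pytest.approx(0.0386,
                                                                  abs=5e-4)
        assert rmsea_from_m2(300.0, 366, 3077) == 0.0

    def test_null_calibration_on_small_model(self):
        """Fitting the generating model, M2 behaves like chi-square(df):
        moderate values, non-vanishing p-values."""
        rng = np.random.default_rng(5)
        j, n = 8, 1000
        q = QMatrix(np.ones((j, 1), dtype=int))
        bank = MirtItemBank(rng.uniform(0.8, 1.6, (j, 1)),
                            rng.uniform(-1, 1, j), np.zeros(j))
        stats = []
        for rep in range(4):
            theta = rng.standard_normal((n, 1))
            from skilldiag.simulator import response_probability
            p = response_probability(theta, bank)
            x = ResponseMatrix((rng.random(p.shape) < p).astype(int))
            cfg = MirtConfig(quad_points=31, latent="identity",
                             estimate_guessing=False, fixed_guessing=0.0)
            res = m2_statistic(fit_mirt_em(x, q, cfg), x)
            assert res.df == j + j * (j - 1) // 2 - 2 * j
            stats.append(res)
        mean_m2 = np.mean([r.statistic for r in stats])
        df = stats[0].df
        assert abs(mean_m2 - df) < 3 * np.sqrt(2 * df / len(stats)) + 3
        assert min(r.p_value for r in stats) > 1e-4
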