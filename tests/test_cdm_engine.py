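import numpy as np
import pytest

from skilldiag.cdm_engine import (CdmConfig, CdmFit, attribute_patterns,
                                  classify_patterns, fit_cdm_em,
                                  item_probability,
                                  posterior_skill_probabilities)
from skilldiag.data_io import QMatrix, ResponseMatrix
from skilldiag.oracles import oracle_cdm_loglik, random_restart_loglik


def _fit_shell(model, q, item_params, class_probs, posterior=None):
    """CdmFit wrapper around known parameters (no EM run)."""
    n_class = len(class_probs)
    if posterior is None:
        posterior = np.full((1, n_class), 1.0 / n_class)
    return CdmFit(model=model, qmatrix=q, item_params=item_params,
                  class_probs=np.asarray(class_probs), posterior=posterior,
                  log_likelihood=0.0, n_parameters=0, n_persons=1,
                  n_iterations=0, converged=True, final_change=0.0)


class TestItemProbability:
    def test_rrum_all_required_mastered_is_baseline(self):
        params = {"pi_star": 0.9, "r_star": np.array([0.5, 0.6])}
        p = item_probability("rrum", params, np.array([1, 1, 0]),
                             np.array([1, 1, 0]))
        assert p == pytest.approx(0.9)

    def test_rrum_single_missing_attribute_penalty(self):
        params = {"pi_star": 0.9, "r_star": np.array([0.5])}
        p = item_probability("rrum", params, np.array([0]), np.array([1]))
        assert p == pytest.approx(0.45)

    def test_gdina_single_attribute_item_has_two_levels(self):
        params = {"probs": np.array([0.2, 0.8])}
        q_row = np.array([0, 1, 0])
        values = {item_probability("gdina", params, p, q_row)
                  for p in attribute_patterns(3)}
        assert values == {0.2, 0.8}


class TestEmFit:
    def test_gdina_recovers_generating_probabilities(self):
        """J = 10, K = 2, N = 5,000 data from a known saturated truth."""
        rng = np.random.default_rng(23)
        j, n = 10, 5000
        entries = np.array([[1, 0]] * 4 + [[0, 1]] * 4 + [[1, 1]] * 2)
        q = QMatrix(entries)
        pats = attribute_patterns(2)
        true_params = []
        for row in entries:
            if row.sum() == 1:
                probs = np.array([rng.uniform(0.08, 0.25),
                                  rng.uniform(0.72, 0.92)])
            else:
                probs = np.array([rng.uniform(0.05, 0.15),
                                  rng.uniform(0.3, 0.45),
                                  rng.uniform(0.5, 0.65),
                                  rng.uniform(0.8, 0.95)])
            true_params.append({"probs": probs})
        class_probs = np.array([0.3, 0.2, 0.2, 0.3])
        classes = rng.choice(4, size=n, p=class_probs)
        p_table = np.array(
            [[item_probability("gdina", true_params[jj], pats[c], entries[jj])
              for jj in range(j)] for c in range(4)])
        x = ResponseMatrix((rng.random((n, j)) < p_table[classes]).astype(int))

        fit = fit_cdm_em(x, q, "gdina", CdmConfig(max_iter=3000))
        assert fit.converged
        for jj in range(j):
            np.testing.assert_allclose(fit.item_params[jj]["probs"],
                                       true_params[jj]["probs"], atol=0.03)
        np.testing.assert_allclose(fit.class_probs, class_probs, atol=0.03)

    @pytest.mark.parametrize("model", ["gdina", "rrum"])
    def test_toy_em_beats_random_restarts(self, model):
        q = QMatrix(np.ones((2, 1), dtype=int))
        x = ResponseMatrix(np.array([[1, 1], [1, 0], [0, 1], [0, 0]]))
        fit = fit_cdm_em(x, q, model)
        best_random = random_restart_loglik(q, x, model, n_draws=1000, seed=1)
        assert fit.log_likelihood >= best_random - 1e-6

    @pytest.mark.parametrize("model", ["gdina", "rrum"])
    def test_likelihood_equals_enumeration_oracle(self, model, toy_suite):
        case = toy_suite["cdm-k2"]
        fit = fit_cdm_em(case.responses, case.qmatrix, model)
        pats = attribute_patterns(2)
        item_probs = [
            [np.clip(item_probability(model, fit.item_params[jj], p,
                                      case.qmatrix.entries[jj]), 1e-4, 1 - 1e-4)
             for p in pats] for jj in range(case.qmatrix.n_items)]
        oracle = oracle_cdm_loglik(item_probs, fit.class_probs, case.responses)
        assert fit.log_likelihood == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("model", ["gdina", "rrum"])
    def test_objective_monotone_and_probs_normalized(self, model, toy_suite):
        case = toy_suite["cdm-k2"]
        fit = fit_cdm_em(case.responses, case.qmatrix, model)
        assert (np.diff(fit.objective_trace) > -1e-8).all()
        assert fit.class_probs.sum() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-10)

    def test_unknown_model_rejected(self, toy_suite):
        case = toy_suite["cdm-k2"]
        with pytest.raises(ValueError):
            fit_cdm_em(case.responses, case.qmatrix, "dina")


class TestScoring:
    def test_posterior_concentrated_on_one_pattern(self):
        q = QMatrix(np.ones((2, 3), dtype=int))
        post = np.zeros((1, 8))
        post[0, 5] = 1.0        # canonical index 5 = (1, 0, 1)
        fit = _fit_shell("gdina", q, [{"probs": np.full(8, 0.5)}] * 2,
                         np.full(8, 1 / 8), post)
        np.testing.assert_allclose(posterior_skill_probabilities(fit),
                                   [[1.0, 0.0, 1.0]])

    def test_uniform_posterior_gives_half(self):
        q = QMatrix(np.ones((2, 3), dtype=int))
        fit = _fit_shell("gdina", q, [{"probs": np.full(8, 0.5)}] * 2,
                         np.full(8, 1 / 8))
        np.testing.assert_allclose(posterior_skill_probabilities(fit),
                                   [[0.5, 0.5, 0.5]])

    def test_posterior_matches_hand_summed_enumeration(self, toy_suite):
        case = toy_suite["cdm-k2"]
        fit = fit_cdm_em(case.responses, case.qmatrix, "gdina")
        pats = attribute_patterns(2)
        expected = np.zeros((case.responses.n_persons, 2))
        for i in range(case.responses.n_persons):
            for c, pat in enumerate(pats):
                for k in range(2):
                    if pat[k] == 1:
                        expected[i, k] += fit.posterior[i, c]
        np.testing.assert_allclose(posterior_skill_probabilities(fit),
                                   expected, atol=1e-12)


class TestClassification:
    def test_mle_picks_likelihood_maximizer(self):
        q = QMatrix(np.ones((2, 2), dtype=int))
        # success probability highest for pattern (1, 1) on item 1,
        # constructed so (1, 0) wins for response (1, 0)
        params = [{"probs": np.array([0.1, 0.2, 0.9, 0.3])},
                  {"probs": np.array([0.1, 0.9, 0.2, 0.3])}]
        fit = _fit_shell("gdina", q, params, np.full(4, 0.25))
        x = ResponseMatrix(np.array([[1, 0]]))
        states = classify_patterns(fit, x, rule="MLE")
        np.testing.assert_array_equal(states, [[1, 0]])

    def test_flat_likelihood_ties_break_to_first_pattern(self, toy_suite):
        case = toy_suite["mle-tie"]
        fit = _fit_shell("gdina", case.qmatrix, [{"probs": np.array([0.5, 0.5])}],
                         np.array([0.3, 0.7]))
        with pytest.warns(UserWarning, match="tied"):
            states = classify_patterns(fit, case.responses, rule="MLE")
        np.testing.assert_array_equal(states, [[0], [0]])
        assert fit.tie_count == 2

    def test_map_and_mle_differ_under_extreme_structure(self):
        """Weakly informative items with a lopsided structural
        distribution: MAP follows the prior, MLE follows the data."""
        q = QMatrix(np.ones((2, 1), dtype=int))
        params = [{"probs": np.array([0.4, 0.6])},
                  {"probs": np.array([0.4, 0.6])}]
        fit = _fit_shell("gdina", q, params, np.array([0.99, 0.01]))
        x = ResponseMatrix(np.array([[1, 1]]))
        mle = classify_patterns(fit, x, rule="MLE")
        map_ = classify_patterns(fit, x, rule="MAP")
        np.testing.assert_array_equal(mle, [[1]])
        np.testing.assert_array_equal(map_, [[0]])

    def test_mastery_labels_mean_higher_success(self):
        """On strongly discriminating data the estimated 'mastery' class
        must be the high-success one (no label flip)."""
        rng = np.random.default_rng(31)
        j, n = 8, 2000
        q = QMatrix(np.ones((j, 1), dtype=int))
        masters = rng.random(n) < 0.5
        p = np.where(masters[:, None], 0.85, 0.15)
        x = ResponseMatrix((rng.random((n, j)) < p).astype(int))
        fit = fit_cdm_em(x, q, "gdina")
        for jj in range(j):
            probs = fit.item_params[jj]["probs"]
            assert probs[1] > probs[0]
        states = classify_patterns(fit, x, rule="MLE")
        assert (states.ravel() == masters).mean() > 0.95
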