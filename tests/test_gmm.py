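"""Gaussian mixture fitting, responsibilities, code lengths and the SDMS
candidate/transition machinery."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from mixcomplex import (
    CriterionConfig,
    FittingError,
    GMMParams,
    candidates,
    change_code_length,
    fit_gmm,
    hard_assign,
    model_code_length,
    posterior,
    sdms_step,
)
from mixcomplex.gmm import _free_params, log_likelihoods


@pytest.fixture
def two_blobs(rng):
    return np.vstack(
        [rng.normal(size=(250, 2)) + [-5, 0], rng.normal(size=(250, 2)) + [5, 0]]
    )


def random_params(rng, k=3, d=2):
    a = rng.normal(size=(k, d, d))
    covs = np.einsum("kij,klj->kil", a, a) + 0.5 * np.eye(d)
    return GMMParams(
        proportions=rng.dirichlet(np.ones(k)),
        means=rng.normal(scale=3, size=(k, d)),
        covariances=covs,
    )


class TestPosterior:
    def test_midpoint_between_equal_components_is_half(self):
        params = GMMParams(
            proportions=[0.5, 0.5],
            means=[[-1.0, 0.0], [1.0, 0.0]],
            covariances=np.stack([np.eye(2)] * 2),
        )
        gamma = posterior(params, np.array([[0.0, 0.0]]))
        np.testing.assert_allclose(gamma, [[0.5, 0.5]])

    def test_zero_proportion_gives_zero_column(self):
        params = GMMParams(
            proportions=[1.0, 0.0],
            means=[[0.0], [1.0]],
            covariances=np.stack([np.eye(1)] * 2),
        )
        gamma = posterior(params, np.linspace(-2, 2, 9)[:, None])
        np.testing.assert_array_equal(gamma[:, 1], 0.0)
        np.testing.assert_array_equal(gamma[:, 0], 1.0)

    def test_matches_direct_density_ratio(self, rng):
        params = random_params(rng)
        data = rng.normal(scale=3, size=(20, 2))
        dens = np.column_stack(
            [
                p * multivariate_normal(m, c).pdf(data)
                for p, m, c in zip(
                    params.proportions, params.means, params.covariances
                )
            ]
        )
        expected = dens / dens.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(posterior(params, data), expected, atol=1e-12)

    def test_singular_covariance_names_component(self):
        params = GMMParams(
            proportions=[0.5, 0.5],
            means=[[0.0, 0.0], [1.0, 1.0]],
            covariances=np.stack([np.eye(2), np.zeros((2, 2))]),
        )
        with pytest.raises(np.linalg.LinAlgError, match="component 2"):
            posterior(params, np.zeros((3, 2)))


class TestHardAssign:
    @pytest.mark.parametrize(
        "gamma, expected",
        [
            ([[0.9, 0.1]], [1]),
            ([[0.5, 0.5]], [1]),  # ties break to the lowest index
            ([[1, 0, 0], [0, 0, 1], [0, 1, 0]], [1, 3, 2]),
        ],
    )
    def test_map_labels_one_based(self, gamma, expected):
        np.testing.assert_array_equal(hard_assign(np.asarray(gamma, float)), expected)


class TestCodeLengths:
    def test_k1_observed_equals_complete(self, rng):
        data = rng.normal(size=(30, 2))
        params = GMMParams(
            proportions=[1.0],
            means=data.mean(0, keepdims=True),
            covariances=np.cov(data.T, bias=True)[None],
        )
        aic = model_code_length(data, params, CriterionConfig(criterion="AIC"))
        aic_c = model_code_length(data, params, CriterionConfig(criterion="AIC+comp"))
        assert aic == pytest.approx(aic_c)

    def test_bic_minus_aic_is_the_penalty_gap(self, rng):
        data = rng.normal(size=(64, 2))
        params = random_params(rng, k=2, d=2)
        n, d = data.shape
        dd = _free_params(2, d, "standard")
        gap = dd * (np.log(n) / 2 - 1)
        bic = model_code_length(data, params, CriterionConfig(criterion="BIC"))
        aic = model_code_length(data, params, CriterionConfig(criterion="AIC"))
        assert bic - aic == pytest.approx(gap, abs=1e-9)

    def test_tiny_fixture_matches_hand_computation(self):
        # 6 points in 1-D, fixed two-component model: score = -L + penalty
        data = np.array([-1.1, -0.9, -1.0, 0.9, 1.1, 1.0])[:, None]
        params = GMMParams(
            proportions=[0.5, 0.5],
            means=[[-1.0], [1.0]],
            covariances=np.stack([[[0.25]], [[0.25]]]),
        )
        dens = np.column_stack(
            [
                0.5 * multivariate_normal([-1.0], [[0.25]]).pdf(data),
                0.5 * multivariate_normal([1.0], [[0.25]]).pdf(data),
            ]
        )
        l_obs = np.log(dens.sum(axis=1)).sum()
        l_comp = np.log(dens.max(axis=1)).sum()  # MAP component per point
        got_obs, got_comp = log_likelihoods(params, data)
        assert got_obs == pytest.approx(l_obs, abs=1e-10)
        assert got_comp == pytest.approx(l_comp, abs=1e-10)
        d_std = (2 - 1) + 2 * 1 * (1 + 3) / 2  # K=2, d=1
        cfg = CriterionConfig(criterion="BIC")
        assert model_code_length(data, params, cfg) == pytest.approx(
            -l_obs + d_std / 2 * np.log(6), abs=1e-10
        )
        cfg_p = CriterionConfig(criterion="AIC+comp", param_count_mode="as_printed")
        assert model_code_length(data, params, cfg_p) == pytest.approx(
            -l_comp + ((2 - 1) + 1 * (1 + 3) / 2), abs=1e-10
        )

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError, match="criterion"):
            CriterionConfig(criterion="MDL")

    def test_config_from_key_value_file(self, tmp_path):
        p = tmp_path / "run.cfg"
        p.write_text(
            "criterion = NML   # complete-likelihood NML\n"
            "k_max = 6\n"
            "seed: 42\n"
            "nml_r = 1e3\n"
            "nml_lambda_min = 0.1\n"
        )
        cfg = CriterionConfig.from_file(p)
        assert cfg.criterion == "NML" and cfg.k_max == 6 and cfg.seed == 42
        assert cfg.nml_hyperparams.r == 1e3
        assert cfg.nml_hyperparams.lambda_min == 0.1
        p.write_text("mystery = 3\n")
        with pytest.raises(ValueError, match="mystery"):
            CriterionConfig.from_file(p)


class TestFit:
    def test_k1_recovers_sample_moments(self, rng):
        data = rng.normal(loc=[2, -3], scale=[1.5, 0.5], size=(200, 2))
        params = fit_gmm(data, 1, CriterionConfig(n_init=1, seed=0))
        np.testing.assert_allclose(params.means[0], data.mean(0), atol=1e-6)
        np.testing.assert_allclose(
            params.covariances[0], np.cov(data.T, bias=True), atol=1e-4
        )

    def test_two_blobs_recovered(self, two_blobs):
        params = fit_gmm(two_blobs, 2, CriterionConfig(n_init=3, seed=0))
        centers = params.means[np.argsort(params.means[:, 0])]
        np.testing.assert_allclose(centers[:, 0], [-5, 5], atol=0.2)

    def test_deterministic_given_seed(self, two_blobs):
        cfg = CriterionConfig(n_init=3, seed=42)
        p1 = fit_gmm(two_blobs, 2, cfg)
        p2 = fit_gmm(two_blobs, 2, cfg)
        np.testing.assert_array_equal(p1.means, p2.means)
        np.testing.assert_array_equal(p1.covariances, p2.covariances)

    def test_too_few_points_rejected(self):
        with pytest.raises(FittingError):
            fit_gmm(np.zeros((3, 2)), 3, CriterionConfig())


class TestCandidatesAndChangeCode:
    @pytest.mark.parametrize(
        "k_prev, k_max, expected",
        [
            (None, 10, list(range(1, 11))),
            (1, 10, [1, 2]),
            (10, 10, [9, 10]),
            (5, 10, [4, 5, 6]),
            (1, 1, [1]),
        ],
    )
    def test_candidate_sets(self, k_prev, k_max, expected):
        assert candidates(k_prev, k_max) == expected

    def test_staying_costs_one_bit(self):
        assert change_code_length(5, 5, 10) == pytest.approx(np.log(2))

    def test_single_candidate_is_free(self):
        assert change_code_length(1, 1, 1) == 0.0

    def test_transition_probabilities_normalize(self):
        for k_prev in (1, 4, 10):
            cands = candidates(k_prev, 10)
            total = sum(np.exp(-change_code_length(k, k_prev, 10)) for k in cands)
            assert total == pytest.approx(1.0)

    def test_inadmissible_transition_rejected(self):
        with pytest.raises(ValueError):
            change_code_length(7, 4, 10)


class TestSDMSStep:
    def test_single_blob_selects_one(self, rng):
        data = rng.normal(size=(300, 2))
        sel = sdms_step(data, None, CriterionConfig(n_init=3, seed=0, k_max=5))
        assert sel.k_hat == 1
        assert sel.score == sel.candidate_scores[1] == min(sel.candidate_scores.values())

    def test_three_blobs_selects_three(self, rng):
        data = np.vstack(
            [rng.normal(size=(200, 3)) + [c, 0, 0] for c in (0, 10, 20)]
        )
        sel = sdms_step(data, None, CriterionConfig(n_init=3, seed=1, k_max=10))
        assert sel.k_hat == 3

    def test_candidates_restricted_by_previous_size(self, two_blobs):
        sel = sdms_step(two_blobs, 1, CriterionConfig(n_init=2, seed=3, k_max=10))
        assert set(sel.candidate_scores) <= {1, 2}
        assert 1 <= sel.k_hat <= 2

    def test_deterministic(self, two_blobs):
        cfg = CriterionConfig(n_init=2, seed=9)
        s1 = sdms_step(two_blobs, None, cfg)
        s2 = sdms_step(two_blobs, None, cfg)
        assert s1.k_hat == s2.k_hat
        np.testing.assert_array_equal(s1.params.means, s2.params.means)
        assert s1.candidate_scores == s2.candidate_scores
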