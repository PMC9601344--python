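"""Stream tracking: sequential selection + MC, the weighted fuzzy c-means,
and the per-step decomposition of the tracked MC."""

import numpy as np
import pytest

from mixcomplex import (
    CriterionConfig,
    MixtureTracker,
    track_mc,
    track_mc_decomposed,
    weighted_fcm,
)


@pytest.fixture(scope="module")
def small_stream():
    """8 steps of two well-separated blobs (cheap stand-in for a stream)."""
    rng = np.random.default_rng(5)
    return [
        np.vstack(
            [rng.normal(size=(60, 2)) + [-4, 0], rng.normal(size=(60, 2)) + [4, 0]]
        )
        for _ in range(8)
    ]


@pytest.fixture(scope="module")
def small_cfg():
    return CriterionConfig(criterion="BIC", k_max=4, n_init=2, seed=11)


class TestWeightedFCM:
    def test_single_cluster_center_is_weighted_mean(self, rng):
        pts = rng.normal(size=(30, 3))
        w = rng.uniform(0.1, 2.0, 30)
        state = weighted_fcm(pts, w, 1, m=1.5, seed=0)
        np.testing.assert_allclose(state.centers[0], w @ pts / w.sum(), atol=1e-8)
        np.testing.assert_allclose(state.memberships, 1.0)

    def test_two_tight_groups_recovered(self, rng):
        pts = np.vstack(
            [
                rng.normal(scale=0.05, size=(20, 2)) + [-10, 0],
                rng.normal(scale=0.05, size=(20, 2)) + [10, 0],
            ]
        )
        w = rng.uniform(0.5, 1.5, 40)
        state = weighted_fcm(pts, w, 2, m=1.5, seed=4)
        order = np.argsort(state.centers[:, 0])
        for side, l in zip((slice(0, 20), slice(20, 40)), order):
            group_mean = w[side] @ pts[side] / w[side].sum()
            assert np.linalg.norm(state.centers[l] - group_mean) < 0.1
            assert state.memberships[side, l].min() > 0.99

    def test_loss_nonincreasing(self, rng):
        pts = rng.normal(size=(50, 2))
        state = weighted_fcm(pts, np.ones(50), 3, m=2.0, seed=1)
        assert np.all(np.diff(state.loss_history) <= 1e-9)

    def test_point_on_center_splits_membership(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 0.0]])
        state = weighted_fcm(pts, np.ones(3), 2, m=1.5, seed=2)
        rows = state.memberships
        np.testing.assert_allclose(rows.sum(axis=1), 1.0)
        assert np.all(rows >= 0)

    def test_needs_enough_distinct_points(self):
        with pytest.raises(ValueError, match="distinct"):
            weighted_fcm(np.zeros((5, 2)), np.ones(5), 2)


class TestTrackMC:
    def test_single_blob_stream_is_flat_zero(self):
        rng = np.random.default_rng(0)
        stream = [rng.normal(size=(80, 2)) for _ in range(6)]
        res = track_mc(stream, CriterionConfig(k_max=3, n_init=2, seed=2))
        np.testing.assert_array_equal(res.k_hat_, 1.0)
        np.testing.assert_allclose(res.mc_, 0.0, atol=1e-9)

    def test_exp_mc_bounded_by_k_hat(self, small_stream, small_cfg):
        res = track_mc(small_stream, small_cfg)
        assert np.all(res.exp_mc_ <= res.k_hat_ + 1e-9)
        assert res.failed_steps == []

    def test_rerun_is_bit_identical(self, small_stream, small_cfg):
        r1 = track_mc(small_stream, small_cfg)
        r2 = track_mc(small_stream, small_cfg)
        np.testing.assert_array_equal(r1.mc_, r2.mc_)
        np.testing.assert_array_equal(r1.k_hat_, r2.k_hat_)

    def test_candidate_scores_recorded(self, small_stream, small_cfg):
        res = track_mc(small_stream, small_cfg)
        assert len(res.candidate_scores_) == len(small_stream)
        for t, scores in enumerate(res.candidate_scores_):
            k = int(res.k_hat_[t])
            assert scores[k] == min(scores.values())
            if t > 0:  # later steps only look at the previous K's neighbours
                prev = int(res.k_hat_[t - 1])
                assert set(scores) <= {prev - 1, prev, prev + 1}

    def test_summary_and_frame(self, small_stream, small_cfg):
        res = track_mc(small_stream, small_cfg)
        df = res.to_frame()
        assert list(df.index) == list(range(1, 9))
        assert {"k_hat", "mc", "exp_mc"} <= set(df.columns)
        assert "criterion: BIC" in res.summary()

    def test_ragged_feature_count_rejected(self):
        with pytest.raises(ValueError, match="step 2"):
            MixtureTracker([np.zeros((5, 2)), np.zeros((5, 3))])


class TestTrackDecomposed:
    def test_single_upper_component_is_all_within(self, small_stream, small_cfg):
        res = track_mc_decomposed(small_stream, small_cfg, n_upper=1)
        np.testing.assert_allclose(res.interaction_, 0.0, atol=1e-10)
        np.testing.assert_allclose(res.component_mcs_[:, 0], res.mc_, atol=1e-8)

    def test_split_identity_holds_at_every_step(self, small_stream, small_cfg):
        res = track_mc_decomposed(small_stream, small_cfg, n_upper=2, m=1.5)
        recon = res.interaction_ + (res.weights_ * res.component_mcs_).sum(axis=1)
        np.testing.assert_allclose(recon, res.mc_, atol=1e-8)
        np.testing.assert_allclose(res.weights_.sum(axis=1), 1.0, atol=1e-9)
        df = res.to_frame()
        assert "interaction" in df.columns and "contribution_2" in df.columns
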