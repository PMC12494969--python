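"""Factorized k-means, model selection, shuffle controls and map labeling."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from mecmap import maps
from tests.conftest import make_two_map_tensor


class TestFactorizedKMeans:
    def test_recovers_ground_truth_assignments(self):
        for seed in range(10):
            X, labels, _ = make_two_map_tensor(seed=seed, noise_sd=0.1)
            model = maps.FactorizedKMeans(n_maps=2, n_restarts=10,
                                          random_state=seed).fit(X)
            assert adjusted_rand_score(labels, model.labels_) == 1.0

    def test_k1_centroid_is_grand_mean(self, rng):
        X = rng.uniform(size=(12, 8, 3))
        model = maps.FactorizedKMeans(n_maps=1).fit(X)
        np.testing.assert_allclose(
            model.centroid_maps_[0], X.mean(axis=0), atol=1e-12
        )

    def test_reconstruction_is_assigned_centroid(self):
        X, _, _ = make_two_map_tensor(seed=1)
        model = maps.FactorizedKMeans(n_maps=2, n_restarts=5, random_state=0).fit(X)
        recon = model.reconstruct()
        for i, lab in enumerate(model.labels_):
            np.testing.assert_allclose(recon[i], model.centroid_maps_[lab])

    def test_matches_sklearn_kmeans_inertia(self):
        # independent cross-check: same objective optimum as library k-means
        X, _, _ = make_two_map_tensor(seed=3, noise_sd=0.15)
        M = X.reshape(X.shape[0], -1)
        ours = maps.FactorizedKMeans(n_maps=2, n_restarts=20, random_state=0).fit(M)
        ref = KMeans(n_clusters=2, n_init=20, random_state=0).fit(M)
        assert ours.inertia_ == pytest.approx(ref.inertia_, rel=1e-6)

    def test_k_exceeding_trials_raises(self, rng):
        with pytest.raises(ValueError):
            maps.FactorizedKMeans(n_maps=5).fit(rng.uniform(size=(4, 6)))

    def test_predict_assigns_nearest_centroid(self):
        X, labels, centroids = make_two_map_tensor(seed=5, noise_sd=0.05)
        model = maps.FactorizedKMeans(n_maps=2, n_restarts=5, random_state=0).fit(X)
        pred = model.predict(X)
        np.testing.assert_array_equal(pred, model.labels_)

    def test_sklearn_param_protocol(self):
        model = maps.FactorizedKMeans(n_maps=3, n_restarts=7)
        params = model.get_params()
        assert params["n_maps"] == 3 and params["n_restarts"] == 7
        model.set_params(n_maps=2)
        assert model.n_maps == 2


class TestSelectK:
    @pytest.mark.parametrize("true_k", [2, 3])
    def test_recovers_map_count(self, true_k):
        X, _, _ = make_two_map_tensor(
            n_trials=36, n_maps=true_k, noise_sd=0.08, seed=42
        )
        k_star, diag = maps.select_k(X, k_max=4, reps=3, restarts=10, seed=0)
        assert k_star == true_k
        assert set(diag.silhouette["k"]) == {2, 3, 4}


class TestSpeckledCV:
    def test_mask_holds_out_ten_percent(self, rng):
        masks = maps._speckle_masks((20, 50), 0.10, 5, rng)
        for m in masks:
            assert abs((~m).sum() - 100) <= 1

    def test_noise_free_two_map_r2_near_one(self):
        X, _, _ = make_two_map_tensor(noise_sd=0.0, seed=6)
        scores = maps.speckled_cv(X, rank=2, replicates=5, seed=0)
        assert scores.min() > 0.99

    def test_pure_noise_r2_near_zero(self, rng):
        X = rng.normal(size=(30, 20, 6))
        scores = maps.speckled_cv(X, rank=2, replicates=5, seed=0)
        assert abs(scores.mean()) < 0.15


class TestRotationShuffle:
    def test_norm_preserved(self, rng):
        X = rng.uniform(size=(15, 10, 4))
        Y = maps.rotation_shuffle(X, seed=0)
        assert np.linalg.norm(Y) == pytest.approx(np.linalg.norm(X), rel=1e-8)

    def test_bin_cell_gram_matrix_preserved(self, rng):
        # correlations between neurons/position bins live in X^T X, which is
        # invariant under an orthogonal rotation across trials
        X = rng.uniform(size=(15, 10, 4))
        M = X.reshape(15, -1)
        Y = maps.rotation_shuffle(X, seed=1).reshape(15, -1)
        np.testing.assert_allclose(Y.T @ Y, M.T @ M, atol=1e-8)

    def test_destroys_cluster_structure(self):
        X, _, _ = make_two_map_tensor(noise_sd=0.02, seed=9)
        real = maps.speckled_cv(X, rank=2, replicates=5, seed=3)
        shuf = maps.speckled_cv(
            maps.rotation_shuffle(X, seed=4), rank=2, replicates=5, seed=3
        )
        assert real.mean() > shuf.mean() + 0.1


class TestOneMapDetection:
    def test_two_map_data_not_flagged(self):
        X, _, _ = make_two_map_tensor(noise_sd=0.05, seed=10)
        masks = maps._speckle_masks(
            (X.shape[0], X.shape[1] * X.shape[2]), 0.1, 8, np.random.default_rng(0)
        )
        real = maps.speckled_cv(X, 2, masks=masks, seed=1)
        shuf = maps.speckled_cv(maps.rotation_shuffle(X, seed=2), 2, masks=masks, seed=1)
        one_map, p = maps.detect_one_map(real, shuf)
        assert not one_map and p < 0.05

    def test_identical_scores_flag_one_map(self):
        scores = np.full(10, 0.5)
        one_map, p = maps.detect_one_map(scores, scores)
        assert one_map and p == 1.0

    def test_underpowered_warning(self):
        with pytest.warns(UserWarning, match="underpowered"):
            maps.detect_one_map(np.array([0.5, 0.4]), np.array([0.3, 0.2]))


class TestTSVD:
    def test_rank1_recovers_exact_rank1_matrix(self, rng):
        # SVD oracle: a truly rank-1 matrix with censored entries is
        # reconstructed (nearly) perfectly by the rank-1 EM-imputed tSVD
        M = np.outer(rng.uniform(1.0, 2.0, 12), rng.uniform(1.0, 2.0, 30))
        masks = maps._speckle_masks(M.shape, 0.1, 3, np.random.default_rng(0))
        scores = maps.tsvd_comparison(M, 1, masks=masks, n_em_iter=300)
        assert scores.min() > 0.999

    def test_tsvd_bounds_kmeans_on_noise_free_data(self):
        X, _, _ = make_two_map_tensor(noise_sd=0.0, seed=12)
        M = X.reshape(X.shape[0], -1)
        masks = maps._speckle_masks(M.shape, 0.1, 5, np.random.default_rng(3))
        km = maps.speckled_cv(X, 2, masks=masks, seed=0)
        ts = maps.tsvd_comparison(X, 2, masks=masks)
        assert ts.mean() >= km.mean() - 1e-6

    def test_discrete_two_map_scores_agree(self):
        X, _, _ = make_two_map_tensor(noise_sd=0.05, seed=13)
        masks = maps._speckle_masks(
            (X.shape[0], X.shape[1] * X.shape[2]), 0.1, 5, np.random.default_rng(4)
        )
        km = maps.speckled_cv(X, 2, masks=masks, seed=0)
        ts = maps.tsvd_comparison(X, 2, masks=masks)
        assert abs(km.mean() - ts.mean()) < 0.05


def _stub_model(labels, k):
    m = maps.FactorizedKMeans(n_maps=k)
    m.labels_ = np.asarray(labels)
    m.centroids_ = np.zeros((k, 4))
    m._shape3 = (len(labels), 4)
    return m


def _meta(phases, contexts=None):
    n = len(phases)
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "context": contexts if contexts is not None else ["A"] * n,
            "phase": phases,
        }
    )


class TestRelabeling:
    def test_sm_k2_most_block_a_becomes_map1(self):
        phases = ["blockA"] * 6 + ["blockB"] * 4
        raw = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]  # raw 1 dominates Block A
        lab = maps.relabel_maps(_stub_model(raw, 2), "SM", _meta(phases))
        assert lab.mapping == {1: 1, 0: 2}
        assert lab.labels.tolist() == [1, 1, 1, 1, 1, 2, 2, 2, 2, 2]

    def test_sm_tie_breaks_to_lowest_raw_id(self):
        phases = ["blockA"] * 4 + ["blockB"] * 2
        raw = [0, 1, 0, 1, 0, 1]  # 2 Block-A trials each
        lab = maps.relabel_maps(_stub_model(raw, 2), "SM", _meta(phases))
        assert lab.mapping[0] == 1

    def test_sm_k4_midpoint_rule(self):
        phases = ["blockA"] * 3 + ["blockB"] * 3 + ["alt"] * 8
        raw = [0, 0, 0, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3]
        lab = maps.relabel_maps(_stub_model(raw, 4), "SM", _meta(phases))
        # raw 2 occupies the early alternation half -> map 3
        assert lab.mapping == {0: 1, 1: 2, 2: 3, 3: 4}

    def test_rf_orders_by_mean_running_speed(self):
        raw = [0, 0, 1, 1]
        speeds = np.array([50.0, 52.0, 20.0, 22.0])
        lab = maps.relabel_maps(
            _stub_model(raw, 2), "RF", mean_speeds=speeds
        )
        assert lab.mapping == {1: 1, 0: 2}  # slower map becomes map 1


class TestContextIdentity:
    def test_k2_identities_are_a_and_b(self):
        phases = ["blockA"] * 3 + ["blockB"] * 3
        lab = maps.MapLabeling(
            labels=np.array([1, 1, 1, 2, 2, 2]), mapping={0: 1, 1: 2}
        )
        net = np.eye(6)
        lab = maps.assign_context_identity(lab, net, _meta(phases))
        assert lab.context_of_map == {1: "A", 2: "B"}

    def test_extra_map_assigned_by_similarity(self):
        phases = ["blockA"] * 3 + ["blockB"] * 3 + ["alt"] * 3
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        net = np.zeros((9, 9))
        net[6:, :3] = 0.8  # map-3 trials resemble Block A
        net[6:, 3:6] = 0.1
        lab = maps.MapLabeling(labels=labels, mapping={})
        lab = maps.assign_context_identity(lab, net, _meta(phases))
        assert lab.context_of_map[3] == "A"
        assert not lab.tie_warning

    def test_similarity_tie_goes_to_a_with_warning(self):
        phases = ["blockA"] * 2 + ["blockB"] * 2 + ["alt"] * 2
        labels = np.array([1, 1, 2, 2, 3, 3])
        lab = maps.MapLabeling(labels=labels, mapping={})
        lab = maps.assign_context_identity(lab, np.ones((6, 6)), _meta(phases))
        assert lab.context_of_map[3] == "A" and lab.tie_warning


class TestRemapsAndAlignment:
    def test_constant_labels_zero_frequency(self):
        assert maps.remap_frequency(np.ones(10)) == 0.0

    def test_strict_alternation_frequency(self):
        labels = np.tile([1, 2], 5)
        assert maps.detect_remaps(labels).sum() == 9
        assert maps.remap_frequency(labels) == pytest.approx(0.9)

    def test_phase_remap_counts_are_consistent(self, rng):
        labels = rng.integers(1, 3, size=30)
        total = maps.detect_remaps(labels).sum()
        assert total == maps.detect_remaps(labels[:15]).sum() + maps.detect_remaps(
            labels[14:]
        ).sum()

    def test_alignment_identities(self):
        ctx = np.array(["A", "B", "A", "B"], dtype=object)
        aligned, frac = maps.context_alignment(ctx.copy(), ctx)
        assert frac == 1.0 and aligned.all()
        anti = np.array(["B", "A", "B", "A"], dtype=object)
        _, frac0 = maps.context_alignment(anti, ctx)
        assert frac0 == 0.0

    def test_downstream_stats_invariant_to_raw_label_permutation(self):
        phases = ["blockA"] * 5 + ["blockB"] * 5
        raw = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 0])
        lab1 = maps.relabel_maps(_stub_model(raw, 2), "SM", _meta(phases))
        lab2 = maps.relabel_maps(_stub_model(1 - raw, 2), "SM", _meta(phases))
        np.testing.assert_array_equal(lab1.labels, lab2.labels)
        assert maps.remap_frequency(lab1.labels) == maps.remap_frequency(lab2.labels)
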