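"""Tensor normalisation, cross-trial correlation and similarity statistics."""

import numpy as np
import pandas as pd
import pytest

from mecmap import similarity
from mecmap.tuning import TrialRateMatrix


def _matrix(values, trials=None):
    values = np.asarray(values, dtype=float)
    return TrialRateMatrix(
        values=values,
        occupancy=np.full_like(values, 0.1),
        trials=np.arange(values.shape[0]) if trials is None else np.asarray(trials),
        smoothing_sd=5.0,
    )


def _trial_info(n_dark=0, n_a=3, n_b=3, n_alt=0, n_gain=0, rng=None):
    ctx, tt = [], []
    ctx += ["dark"] * n_dark
    tt += ["dark"] * n_dark
    ctx += ["A"] * n_a + ["B"] * n_b
    tt += ["vr"] * (n_a + n_b)
    if n_alt:
        r = rng or np.random.default_rng(0)
        ctx += ["A" if x == 0 else "B" for x in r.integers(0, 2, n_alt)]
        tt += ["vr"] * n_alt
    ctx += ["B"] * n_gain
    tt += ["gain"] * n_gain
    return pd.DataFrame(
        {"trial": np.arange(len(ctx)), "context": ctx, "trial_type": tt}
    )


class TestNormalizeTensor:
    def test_minmax_formula(self):
        values = np.array([[2.0, 4.0], [6.0, 3.0]])
        t = similarity.normalize_tensor([_matrix(values)], _trial_info(n_a=1, n_b=1))
        np.testing.assert_allclose(t.X[..., 0], (values - 2.0) / 4.0)

    def test_silent_cell_stays_zero(self):
        t = similarity.normalize_tensor(
            [_matrix(np.full((4, 6), 3.0))], _trial_info(n_a=2, n_b=2)
        )
        np.testing.assert_allclose(t.X, 0.0)

    def test_dark_and_gain_trials_omitted(self):
        info = _trial_info(n_dark=2, n_a=2, n_b=2, n_gain=2)
        t = similarity.normalize_tensor(
            [_matrix(np.random.default_rng(0).uniform(size=(8, 6)))], info
        )
        assert t.n_trials == 4
        assert set(t.trial_meta["trial"]) == {2, 3, 4, 5}

    def test_back_half_bin_partition(self):
        m = _matrix(np.random.default_rng(0).uniform(size=(4, 200)))
        info = _trial_info(n_a=2, n_b=2)
        full = similarity.normalize_tensor([m], info, half="full")
        front = similarity.normalize_tensor([m], info, half="front")
        back = similarity.normalize_tensor([m], info, half="back")
        assert front.X.shape[1] == 100 and back.X.shape[1] == 100
        assert front.X.shape[1] + back.X.shape[1] == full.X.shape[1]

    def test_alternation_context_sort_is_stable(self):
        rng = np.random.default_rng(3)
        info = _trial_info(n_a=2, n_b=2, n_alt=6, rng=rng)
        m = _matrix(rng.uniform(size=(10, 6)))
        t = similarity.normalize_tensor([m], info, sort_alternation=True)
        meta = t.trial_meta
        alt = meta[meta["phase"] == "alt"]
        a_trials = alt.loc[alt["context"] == "A", "trial"].to_numpy()
        b_trials = alt.loc[alt["context"] == "B", "trial"].to_numpy()
        # A' block comes before B', chronological within each
        assert (np.diff(a_trials) > 0).all() and (np.diff(b_trials) > 0).all()
        if a_trials.size and b_trials.size:
            idx_a = alt.index[alt["context"] == "A"]
            idx_b = alt.index[alt["context"] == "B"]
            assert idx_a.max() < idx_b.min()


class TestCrossTrialMatrix:
    def test_identical_trials_all_ones(self):
        V = np.tile(np.array([1.0, 3.0, 2.0, 5.0]), (4, 1))
        R = similarity.cross_trial_matrix(V)
        np.testing.assert_allclose(R, 1.0)

    def test_matches_brute_force_pearson(self, rng):
        V = rng.uniform(size=(6, 10))
        R = similarity.cross_trial_matrix(V)
        for i in range(6):
            for j in range(6):
                expected = np.corrcoef(V[i], V[j])[0, 1]
                assert R[i, j] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(R, R.T, atol=1e-12)

    def test_zero_variance_trial_is_missing(self):
        V = np.vstack([np.full(5, 2.0), np.arange(5.0)])
        R = similarity.cross_trial_matrix(V)
        assert np.isnan(R[0, 1]) and np.isnan(R[0, 0])
        assert R[1, 1] == 1.0


class TestTrialStability:
    def test_identical_trials_give_one(self):
        R = np.ones((8, 8))
        assert similarity.trial_stability(R) == pytest.approx(1.0)

    def test_matches_windowed_brute_force(self, rng):
        V = rng.uniform(size=(9, 12))
        R = similarity.cross_trial_matrix(V)
        got = similarity.trial_stability(R)
        per_trial = []
        for i in range(9):
            neigh = sorted(
                (j for j in range(9) if j != i), key=lambda j: (abs(j - i), j)
            )[:5]
            per_trial.append(np.mean([R[i, j] for j in neigh]))
        assert got == pytest.approx(np.mean(per_trial), abs=1e-12)

    def test_invariant_to_additive_rate_offset(self, rng):
        V = rng.uniform(size=(7, 10))
        s1 = similarity.trial_stability(similarity.cross_trial_matrix(V))
        s2 = similarity.trial_stability(similarity.cross_trial_matrix(V + 5.0))
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_fewer_than_two_trials_undefined(self):
        assert np.isnan(similarity.trial_stability(np.ones((1, 1))))


class TestWithinMapStability:
    def test_single_map_equals_trial_stability(self, rng):
        V = rng.uniform(size=(8, 10))
        R = similarity.cross_trial_matrix(V)
        assert similarity.within_map_stability(
            R, np.zeros(8, dtype=int)
        ) == pytest.approx(similarity.trial_stability(R))

    def test_two_pure_maps_give_one(self):
        a = np.array([1.0, 0.0, 2.0, 0.0])
        b = np.array([0.0, 3.0, 0.0, 1.0])
        V = np.vstack([a, b, a, b, a, b])
        labels = np.array([0, 1, 0, 1, 0, 1])
        R = similarity.cross_trial_matrix(V)
        assert similarity.within_map_stability(R, labels) == pytest.approx(1.0)

    def test_true_labels_beat_random_labels(self, rng):
        from tests.conftest import make_two_map_tensor

        X, labels, _ = make_two_map_tensor(n_trials=30, noise_sd=0.1, seed=4)
        R = similarity.cross_trial_matrix(X.reshape(30, -1))
        true_s = similarity.within_map_stability(R, labels)
        rand_s = similarity.within_map_stability(R, rng.permutation(labels))
        assert true_s > rand_s


class TestSimilarityRatios:
    def _groups(self, n_a=4, n_b=4, n_ap=0, n_bp=0):
        idx = np.arange(n_a + n_b + n_ap + n_bp)
        return {
            "A": idx[:n_a],
            "B": idx[n_a:n_a + n_b],
            "A'": idx[n_a + n_b:n_a + n_b + n_ap],
            "B'": idx[n_a + n_b + n_ap:],
        }

    def test_identical_tuning_gives_exactly_one(self):
        V = np.tile(np.array([0.1, 0.9, 0.4, 0.2, 0.7]), (8, 1))
        R = similarity.cross_trial_matrix(V)
        assert similarity.similarity_ratio_block(R, self._groups()) == 1.0

    def test_orthogonal_maps_give_large_ratio(self, rng):
        a = np.concatenate([rng.uniform(1, 2, 5), np.zeros(5)])
        b = np.concatenate([np.zeros(5), rng.uniform(1, 2, 5)])
        V = np.vstack([a + rng.normal(0, 0.01, 10) for _ in range(4)]
                      + [b + rng.normal(0, 0.01, 10) for _ in range(4)])
        R = similarity.cross_trial_matrix(V)
        ratio = similarity.similarity_ratio_block(R, self._groups())
        # mismatched-pair similarity is near zero or negative -> huge or NaN
        assert np.isnan(ratio) or ratio > 5.0

    def test_block_ratio_invariant_to_context_swap(self, rng):
        V = rng.uniform(size=(8, 12))
        R = similarity.cross_trial_matrix(V)
        g = self._groups()
        swapped = {"A": g["B"], "B": g["A"], "A'": g["B'"], "B'": g["A'"]}
        assert similarity.similarity_ratio_block(R, g) == pytest.approx(
            similarity.similarity_ratio_block(R, swapped)
        )

    def test_alt_ratio_matches_hand_computation(self, rng):
        V = rng.uniform(size=(8, 12))
        R = similarity.cross_trial_matrix(V)
        g = self._groups(2, 2, 2, 2)
        got = similarity.similarity_ratio_alt(R, g)
        def pm(r1, r2):
            return np.mean([R[i, j] for i in r1 for j in r2 if i != j])
        expected = np.mean([pm(g["A"], g["A'"]), pm(g["B"], g["B'"])]) / np.mean(
            [pm(g["A"], g["B'"]), pm(g["B"], g["A'"])]
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_exchangeable_trials_permutation_null_centres_on_one(self):
        rng = np.random.default_rng(11)
        # exchangeable trials: one shared spatial map plus trial noise
        template = rng.uniform(size=40)
        V = template[None, :] + rng.normal(0.0, 0.2, size=(16, 40))
        R = similarity.cross_trial_matrix(V)
        ratios = []
        for _ in range(200):
            perm = rng.permutation(16)
            g = {"A": perm[:8], "B": perm[8:], "A'": np.array([], int),
                 "B'": np.array([], int)}
            ratios.append(similarity.similarity_ratio_block(R, g))
        med = np.nanmedian(ratios)
        assert 0.9 <= med <= 1.1


class TestRemappingMeasures:
    def test_rate_remapping_identical_blocks_zero(self, rng):
        V = np.tile(rng.uniform(size=12), (6, 1))
        assert similarity.rate_remapping_pct(
            V, np.arange(3), np.arange(3, 6)
        ) == pytest.approx(0.0)

    def test_rate_remapping_doubling_peak(self):
        a = np.array([0.1, 0.5, 0.2])
        b = np.array([0.1, 1.0, 0.2])
        V = np.vstack([a, a, b, b])
        val = similarity.rate_remapping_pct(V, [0, 1], [2, 3])
        assert val == pytest.approx(100.0)
        rev = similarity.rate_remapping_pct(V, [2, 3], [0, 1])
        assert rev == pytest.approx(-50.0)

    def test_dissimilarity_identities(self, rng):
        v = rng.uniform(size=10)
        V = np.vstack([v, v])
        assert similarity.spatial_dissimilarity(V, [0], [1]) == pytest.approx(0.0)
        one_hot = np.vstack([np.eye(10)[0], np.eye(10)[5]])
        assert similarity.spatial_dissimilarity(one_hot, [0], [1]) == pytest.approx(1.0)

    def test_dissimilarity_matches_brute_force(self, rng):
        V = rng.uniform(size=(4, 8))
        got = similarity.spatial_dissimilarity(V, [0, 1], [2, 3])
        a, b = V[:2].mean(axis=0), V[2:].mean(axis=0)
        expected = 1.0 - a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert got == pytest.approx(expected, abs=1e-12)


class TestNetworkMatrix:
    def test_single_cell_reduces_to_cell_matrix(self, rng):
        X = rng.uniform(size=(6, 10, 1))
        t = similarity.RateTensor(
            X=X,
            trial_meta=pd.DataFrame(
                {"trial": range(6), "context": "A", "phase": "blockA"}
            ),
        )
        np.testing.assert_allclose(
            similarity.network_similarity_matrix(t),
            similarity.cross_trial_matrix(X[..., 0]),
            atol=1e-12,
        )

    def test_two_map_block_structure(self):
        from tests.conftest import make_two_map_tensor

        X, labels, _ = make_two_map_tensor(noise_sd=0.1, seed=2)
        t = similarity.RateTensor(
            X=X,
            trial_meta=pd.DataFrame(
                {"trial": range(len(labels)), "context": "A", "phase": "blockA"}
            ),
        )
        R = similarity.network_similarity_matrix(t)
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(len(labels), 1)
        within = R[iu][same[iu]].mean()
        across = R[iu][~same[iu]].mean()
        assert within > across

    def test_cell_count_gate(self, rng):
        X = rng.uniform(size=(6, 10, 5))
        t = similarity.RateTensor(
            X=X,
            trial_meta=pd.DataFrame(
                {"trial": range(6), "context": "A", "phase": "blockA"}
            ),
        )
        with pytest.raises(ValueError, match="ineligible"):
            similarity.network_similarity_matrix(t, min_cells=10)


class TestRemappingCoordination:
    def test_shared_map_sequence_high_coordination(self):
        from tests.conftest import make_two_map_tensor

        X, labels, _ = make_two_map_tensor(n_cells=6, noise_sd=0.05, seed=8)
        unit = similarity.cross_trial_matrix(X[..., 0])
        network = similarity.cross_trial_matrix(X[..., 1:].reshape(X.shape[0], -1))
        assert similarity.remapping_coordination(unit, network) > 0.7

    def test_independent_unit_near_zero(self, rng):
        from tests.conftest import make_two_map_tensor

        X, labels, _ = make_two_map_tensor(n_cells=6, noise_sd=0.05, seed=8)
        vals = []
        for seed in range(10):
            Xi, _, _ = make_two_map_tensor(
                n_trials=X.shape[0], n_cells=1, noise_sd=0.05, seed=100 + seed
            )
            unit = similarity.cross_trial_matrix(Xi[..., 0])
            network = similarity.cross_trial_matrix(X.reshape(X.shape[0], -1))
            vals.append(similarity.remapping_coordination(unit, network))
        assert abs(np.mean(vals)) < 0.2


class TestGainResponse:
    def test_no_change_gives_zero(self):
        V = np.tile(np.array([0.2, 0.8, 0.5]), (8, 1))
        R = similarity.cross_trial_matrix(V)
        val = similarity.gain_response_magnitude(R, np.arange(6), np.arange(6, 8))
        assert val == pytest.approx(0.0)

    def test_orthogonal_post_gain_map_matches_oracle(self, rng):
        pre = np.concatenate([rng.uniform(1, 2, 5), np.zeros(5)])
        post = np.concatenate([np.zeros(5), rng.uniform(1, 2, 5)])
        V = np.vstack([pre + rng.normal(0, 0.01, 10) for _ in range(5)]
                      + [post + rng.normal(0, 0.01, 10) for _ in range(3)])
        R = similarity.cross_trial_matrix(V)
        got = similarity.gain_response_magnitude(R, np.arange(5), np.arange(5, 8))
        # trial-count matching: baseline = last 3 pre-gain trials
        base = [R[i, j] for i in (2, 3, 4) for j in (2, 3, 4) if i < j]
        across = [R[i, j] for i in (2, 3, 4) for j in (5, 6, 7)]
        assert got == pytest.approx(np.mean(base) - np.mean(across), abs=1e-12)
        assert got > 0.5
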