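"""Reliability computation, mixture-based voxel selection, PLS decoding."""
import numpy as np
import pytest

from actfast import (
    DimensionTimeSeries,
    action_pattern_matrix,
    cronbach_alpha,
    decode,
    fit_pls,
    select_voxels,
)
from actfast.neural import DegenerateMixtureError, _fit_single


def alpha_oracle(matrix):
    """Spreadsheet-style Cronbach's alpha: rows = items, columns = observations."""
    import statistics

    k = len(matrix)
    item_vars = [statistics.variance(row) for row in matrix]
    totals = [sum(col) for col in zip(*matrix)]
    total_var = statistics.variance(totals)
    return k / (k - 1) * (1 - sum(item_vars) / total_var)


class TestActionPatterns:
    def test_one_hot_weights_give_plain_means(self, rng):
        data = rng.standard_normal((6, 3))
        probs = np.zeros((6, 2))
        probs[:3, 0] = 1.0
        probs[3:, 1] = 1.0
        patterns, mass = action_pattern_matrix(data, probs)
        np.testing.assert_allclose(patterns[0], data[:3].mean(axis=0))
        np.testing.assert_allclose(patterns[1], data[3:].mean(axis=0))
        np.testing.assert_array_equal(mass, [3, 3])

    def test_zero_mass_action_flagged(self, rng):
        data = rng.standard_normal((4, 2))
        probs = np.zeros((4, 2))
        probs[:, 0] = 1.0
        patterns, mass = action_pattern_matrix(data, probs)
        assert mass[1] == 0
        assert np.isnan(patterns[1]).all()
        assert np.isfinite(patterns[0]).all()

    def test_weighted_mean_hand_computed(self):
        data = np.array([[1.0], [2.0], [3.0]])
        probs = np.array([[0.5], [0.3], [0.2]])
        patterns, _ = action_pattern_matrix(data, probs)
        assert patterns[0, 0] == pytest.approx(1.7)


class TestCronbachAlpha:
    def test_identical_participants_give_alpha_one(self):
        base = np.array([[1.0], [2.0], [3.0]])  # 3 actions x 1 voxel
        patterns = np.stack([base, base])
        np.testing.assert_allclose(cronbach_alpha(patterns), 1.0)

    def test_two_by_three_fixture_matches_oracle(self):
        p1 = [1.0, 2.0, 3.0]
        p2 = [1.0, 3.0, 2.0]
        patterns = np.array([p1, p2])[:, :, None]
        expected = alpha_oracle([p1, p2])
        np.testing.assert_allclose(cronbach_alpha(patterns)[0], expected, atol=1e-12)

    def test_random_fixtures_match_oracle(self, rng):
        for _ in range(1000):
            m = rng.standard_normal((3, 5))
            got = cronbach_alpha(m[:, :, None])[0]
            np.testing.assert_allclose(got, alpha_oracle(m.tolist()), atol=1e-10)

    def test_independent_noise_gives_near_zero_alpha(self, rng):
        patterns = rng.standard_normal((3, 200, 1000))
        alphas = cronbach_alpha(patterns)
        assert abs(alphas.mean()) < 0.05

    def test_items_orientation_flag(self, rng):
        m = rng.standard_normal((3, 5, 1))
        swapped = cronbach_alpha(m, items="actions")
        direct = cronbach_alpha(np.transpose(m, (1, 0, 2)))
        np.testing.assert_allclose(swapped, direct, atol=1e-12)

    def test_zero_variance_voxel_flagged(self):
        patterns = np.zeros((2, 4, 1))
        assert np.isnan(cronbach_alpha(patterns)[0])


class TestVoxelSelection:
    def test_planted_clusters_recovered(self, rng):
        lo = rng.normal(0.0, 0.05, 500)
        hi = rng.normal(0.8, 0.05, 500)
        alphas = np.concatenate([lo, hi])
        relmap = select_voxels(alphas, seed=0)
        assert relmap.selected[500:].mean() >= 0.99
        assert relmap.selected[:500].mean() <= 0.01
        assert relmap.means[1] > relmap.means[0]

    def test_equal_alphas_degenerate(self):
        with pytest.raises(DegenerateMixtureError):
            select_voxels(np.full(100, 0.5), seed=0)

    def test_selection_invariant_to_voxel_order(self, rng):
        alphas = np.concatenate(
            [rng.normal(0.0, 0.1, 200), rng.normal(0.7, 0.1, 200)]
        )
        perm = rng.permutation(len(alphas))
        a = select_voxels(alphas, seed=3).selected
        b = select_voxels(alphas[perm], seed=3).selected
        np.testing.assert_array_equal(a[perm], b)

    def test_nan_alphas_never_selected(self, rng):
        alphas = np.concatenate(
            [rng.normal(0.0, 0.05, 50), rng.normal(0.8, 0.05, 50), [np.nan]]
        )
        relmap = select_voxels(alphas, seed=0)
        assert not relmap.selected[-1]


class TestPLS:
    def test_exact_linear_target_recovered(self, rng):
        # rank-6 features (a 6-D latent signal seen through 30 channels)
        # carrying an exact linear target: recovery to numerical precision
        Z = rng.standard_normal((200, 6))
        X = Z @ rng.standard_normal((6, 30))
        Y = Z @ rng.standard_normal((6, 6))
        model = fit_pls(X, Y, max_components=6)
        pred = decode(model, X)
        np.testing.assert_allclose(pred.values, Y, atol=1e-6)
        best = model.cv_scores[np.arange(6), model.n_components - 1]
        assert np.all(best >= 0.999)

    def test_pure_noise_target_scores_near_zero(self, rng):
        X = rng.standard_normal((2000, 20))
        Y = rng.standard_normal((2000, 1))
        model = fit_pls(X, Y, max_components=5)
        chosen_score = model.cv_scores[0, model.n_components[0] - 1]
        assert abs(chosen_score) < 0.1

    def test_full_rank_pls_equals_least_squares(self, rng):
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        coef, intercept = _fit_single(X, y, c=6)
        ones = np.column_stack([X, np.ones(40)])
        beta, *_ = np.linalg.lstsq(ones, y, rcond=None)
        np.testing.assert_allclose(X @ coef + intercept, ones @ beta, atol=1e-8)

    def test_max_components_beyond_rank_rejected(self, rng):
        X = rng.standard_normal((50, 4))
        X = np.column_stack([X, X[:, 0]])  # rank 4, 5 columns
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, rng.standard_normal((50, 1)), max_components=5)

    def test_decode_requires_matching_columns(self, rng):
        X = rng.standard_normal((60, 10))
        model = fit_pls(X, rng.standard_normal((60, 2)), max_components=3)
        with pytest.raises(ValueError, match="selected voxels"):
            decode(model, X[:, :5])

    def test_zero_input_returns_intercepts(self, rng):
        X = rng.standard_normal((60, 10))
        model = fit_pls(X, rng.standard_normal((60, 2)), max_components=3)
        out = decode(model, np.zeros((1, 10)))
        np.testing.assert_allclose(out.values[0], model.intercepts)


class TestDecodingOnSyntheticData:
    def test_decoded_series_tracks_truth_at_moderate_noise(self, small_world):
        """At voxel noise 0.3, held-out decoding correlates strongly with the
        planted coordinate trajectory on every dimension."""
        from actfast import coordinate_time_series

        world, ann, voxels = small_world
        coords = world.coordinates()
        dims = coordinate_time_series(ann, coords)
        half = ann.n_trs // 2
        X_train = np.vstack([v.data[:half] for v in voxels[:2]])
        Y_train = np.tile(dims.values[:half], (2, 1))
        model = fit_pls(X_train, Y_train, max_components=8)
        decoded = decode(model, voxels[2].data[half:])
        truth = dims.values[half:]
        for d in range(6):
            r = np.corrcoef(decoded.values[:, d], truth[:, d])[0, 1]
            assert r > 0.8

    def test_accuracy_degrades_with_noise(self):
        """Average decoding correlation is non-increasing in voxel noise."""
        from actfast import coordinate_time_series, generate_voxel_data
        from actfast.synthetic import build_world

        mean_r = []
        for noise in (0.0, 0.5, 1.0, 2.0):
            rs = []
            for seed in range(20):
                world, ann, _ = build_world(
                    n_actions=30, n_trs=160, n_participants=1, n_voxels=24,
                    n_reliable=24, noise_sd=noise, temperature=3.0,
                    seed=100 + seed,
                )
                dims = coordinate_time_series(ann, world.coordinates())
                idx = {a: i for i, a in enumerate(world.action_ids)}
                tr_actions = np.repeat(
                    [idx[a] for a, _ in world.sequence],
                    [d for _, d in world.sequence],
                )
                true_dims = world.true_coords[tr_actions]
                voxels, _ = generate_voxel_data(
                    DimensionTimeSeries(true_dims), 1, 24, 24, noise,
                    seed=200 + seed,
                )
                model = fit_pls(
                    voxels[0].data[:80], dims.values[:80], max_components=6
                )
                decoded = decode(model, voxels[0].data[80:])
                r = [
                    np.corrcoef(decoded.values[:, d], true_dims[80:, d])[0, 1]
                    for d in range(6)
                ]
                rs.append(np.mean(r))
            mean_r.append(np.mean(rs))
        assert all(a >= b - 1e-9 for a, b in zip(mean_r, mean_r[1:]))
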