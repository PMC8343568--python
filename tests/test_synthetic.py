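"""Generator invariants: planted structure must be exactly recoverable."""
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from actfast import (
    DimensionTimeSeries,
    generate_action_sequence,
    generate_action_space,
    generate_annotations,
    generate_ratings,
    generate_voxel_data,
)
from actfast.neural import action_pattern_matrix, cronbach_alpha
from actfast.synthetic import _transition_matrix


class TestActionSpace:
    def test_columns_are_zscored(self):
        coords = generate_action_space(332, 6, seed=1).coords
        assert coords.shape == (332, 6)
        np.testing.assert_allclose(coords.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(coords.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_seed_determinism(self):
        a = generate_action_space(10, 6, seed=7).coords
        b = generate_action_space(10, 6, seed=7).coords
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("n_actions", [1, 5])
    def test_too_few_actions_rejected(self, n_actions):
        with pytest.raises(ValueError):
            generate_action_space(n_actions, 6, seed=0)


class TestActionSequence:
    def test_tiny_temperature_walks_to_nearest_neighbour(self):
        coords = generate_action_space(20, 6, seed=3)
        d = np.sqrt(
            ((coords.coords[:, None] - coords.coords[None]) ** 2).sum(-1)
        )
        np.fill_diagonal(d, np.inf)
        nearest = d.argmin(axis=1)
        seq = generate_action_sequence(coords, 500, temperature=1e-4, seed=5)
        idx = [coords.action_ids.index(a) for a in seq]
        for cur, nxt in zip(idx[:-1], idx[1:]):
            assert nxt == nearest[cur]

    def test_infinite_temperature_is_uniform(self):
        coords = generate_action_space(8, 6, seed=2)
        seq = generate_action_sequence(coords, 50_000, temperature=math.inf, seed=9)
        idx = np.array([coords.action_ids.index(a) for a in seq])
        counts = np.zeros((8, 8))
        for cur, nxt in zip(idx[:-1], idx[1:]):
            counts[cur, nxt] += 1
        assert np.all(np.diag(counts) == 0)
        # chi-square against uniform over j != i, pooled across rows
        obs = counts[~np.eye(8, dtype=bool)]
        expected = np.repeat(counts.sum(axis=1) / 7.0, 7)
        p = chisquare(obs, expected).pvalue
        assert p > 0.01

    def test_transition_frequencies_match_softmax_oracle(self):
        # 4 actions at hand-set positions; brute-force softmax of -distance
        pts = np.array(
            [[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 1.0]], dtype=float
        )
        from actfast.types import ActionCoordinates

        coords = ActionCoordinates(
            ["a", "b", "c", "d"], pts, dimensions=("x", "y")
        )
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        expected = np.exp(-d / 1.0)
        np.fill_diagonal(expected, 0.0)
        expected /= expected.sum(axis=1, keepdims=True)

        seq = generate_action_sequence(coords, 100_000, temperature=1.0, seed=11)
        idx = np.array([coords.action_ids.index(a) for a in seq])
        counts = np.zeros((4, 4))
        for cur, nxt in zip(idx[:-1], idx[1:]):
            counts[cur, nxt] += 1
        empirical = counts / counts.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(empirical, expected, atol=0.01)

    def test_transition_matrix_rows_are_stochastic(self):
        coords = generate_action_space(12, 6, seed=0)
        P = _transition_matrix(coords.coords, 0.5)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diag(P) == 0)

    def test_nonpositive_temperature_rejected(self):
        coords = generate_action_space(8, 6, seed=0)
        with pytest.raises(ValueError):
            generate_action_sequence(coords, 10, temperature=0.0, seed=0)


class TestAnnotations:
    def test_one_hot_at_full_concentration(self):
        seq = [("a", 2), ("b", 3), ("a", 1)]
        ann = generate_annotations(seq, ["a", "b", "c"], concentration=1.0, seed=0)
        assert ann.probs.shape == (6, 3)
        np.testing.assert_array_equal(np.sort(ann.probs, axis=1)[:, :-1], 0)
        winners = np.argmax(ann.probs, axis=1)
        np.testing.assert_array_equal(winners, [0, 0, 1, 1, 1, 0])

    def test_majority_mass_preserves_argmax(self):
        seq = [("a", 3), ("c", 4), ("b", 2)]
        ann = generate_annotations(seq, ["a", "b", "c"], concentration=0.51, seed=4)
        truth = np.repeat([0, 2, 1], [3, 4, 2])
        np.testing.assert_array_equal(np.argmax(ann.probs, axis=1), truth)

    def test_rows_normalised(self):
        ids = [f"a{i}" for i in range(332)]
        seq = [(ids[i % 332], 1) for i in range(200)]
        # consecutive duplicates are fine for the annotation generator itself
        ann = generate_annotations(seq, ids, concentration=0.6, seed=1)
        np.testing.assert_allclose(ann.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            generate_annotations([], ["a"], concentration=1.0)


class TestVoxelData:
    @staticmethod
    def _dims(n_trs=120, seed=0):
        rng = np.random.default_rng(seed)
        return DimensionTimeSeries(rng.standard_normal((n_trs, 6)))

    def test_noiseless_reliable_voxels_are_rank_six(self):
        dims = self._dims()
        voxels, info = generate_voxel_data(dims, 2, 30, 20, noise_sd=0.0, seed=3)
        rel = voxels[0].data[:, info["reliable_mask"]]
        centered = rel - rel.mean(axis=0)
        assert np.linalg.matrix_rank(centered, tol=1e-8) <= 6

    def test_voxels_are_zscored_over_time(self):
        dims = self._dims()
        voxels, _ = generate_voxel_data(dims, 3, 25, 10, noise_sd=0.7, seed=5)
        for v in voxels:
            np.testing.assert_allclose(v.data.mean(axis=0), 0, atol=1e-10)
            np.testing.assert_allclose(v.data.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_planted_reliable_voxels_have_higher_alpha(self):
        """Cross-participant reliability separates planted reliable voxels,
        cross-checked with a spreadsheet-style alpha oracle on one voxel."""
        dims = self._dims(n_trs=300, seed=8)
        voxels, info = generate_voxel_data(dims, 4, 60, 30, noise_sd=0.5, seed=8)
        # one-hot "annotations": each TR is its own action
        probs = np.eye(300)
        patterns = np.stack(
            [action_pattern_matrix(v.data, probs)[0] for v in voxels]
        )
        alpha = cronbach_alpha(patterns)
        rel, unrel = alpha[info["reliable_mask"]], alpha[~info["reliable_mask"]]
        assert (rel > unrel.max()).mean() >= 0.99

        # independent oracle on the first reliable voxel
        vx = int(np.nonzero(info["reliable_mask"])[0][0])
        cols = patterns[:, :, vx]  # (participants, actions)
        k = cols.shape[0]
        item_vars = sum(np.var(cols[i], ddof=1) for i in range(k))
        total_var = np.var(cols.sum(axis=0), ddof=1)
        oracle = k / (k - 1) * (1 - item_vars / total_var)
        np.testing.assert_allclose(alpha[vx], oracle, atol=1e-10)

    def test_reliable_count_validation(self):
        with pytest.raises(ValueError):
            generate_voxel_data(self._dims(), 2, 10, 11, noise_sd=0.1)


class TestRatings:
    def test_noiseless_ratings_recover_coordinates(self):
        coords = generate_action_space(40, 6, seed=2)
        table = generate_ratings(
            coords, n_raters_per_dim=4, rater_noise_sd=0.0,
            n_degenerate=0, seed=0, bias_sd=0.0, discretize=False,
        )
        from actfast import aggregate_ratings

        agg = aggregate_ratings(table, coords.action_ids)
        np.testing.assert_allclose(agg.coords, coords.coords, atol=1e-10)

    def test_noisy_ratings_correlate_with_truth(self):
        coords = generate_action_space(100, 6, seed=5)
        table = generate_ratings(
            coords, n_raters_per_dim=20, rater_noise_sd=1.0, n_degenerate=0, seed=5
        )
        from actfast import aggregate_ratings

        agg = aggregate_ratings(table, coords.action_ids)
        for d in range(6):
            r = np.corrcoef(agg.coords[:, d], coords.coords[:, d])[0, 1]
            assert r > 0.9

    def test_degenerate_raters_emit_few_unique_values(self):
        coords = generate_action_space(50, 6, seed=1)
        table = generate_ratings(
            coords, n_raters_per_dim=3, rater_noise_sd=1.0, n_degenerate=3, seed=1
        )
        nunique = table.groupby("rater_id")["rating"].nunique()
        assert (nunique <= 10).sum() == 3

    def test_too_few_raters_rejected(self):
        coords = generate_action_space(10, 6, seed=0)
        with pytest.raises(ValueError):
            generate_ratings(coords, n_raters_per_dim=1, rater_noise_sd=0.1)


class TestDeterminism:
    def test_build_world_is_bit_reproducible(self):
        from actfast import build_world

        kw = dict(
            n_actions=30, n_trs=80, n_participants=2, n_voxels=20,
            n_reliable=10, seed=42,
        )
        w1, a1, v1 = build_world(**kw)
        w2, a2, v2 = build_world(**kw)
        assert w1.sequence == w2.sequence
        np.testing.assert_array_equal(w1.true_coords, w2.true_coords)
        np.testing.assert_array_equal(a1.probs, a2.probs)
        for x, y in zip(v1, v2):
            np.testing.assert_array_equal(x.data, y.data)

    def test_world_sequence_tiles_requested_trs(self, small_world):
        world, ann, voxels = small_world
        assert world.n_trs == ann.n_trs == voxels[0].n_trs == 400
        assert all(d >= 1 for _, d in world.sequence)
        assert all(
            a != b for (a, _), (b, _) in zip(world.sequence, world.sequence[1:])
        )
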