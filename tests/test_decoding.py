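"""Fold normalization, LORO decoding, cross-classification, interaction,
searchlight and univariate contrasts."""

import numpy as np
import pytest

import betadecode as bd
from betadecode.decoding import (
    _decision_libsvm,
    _decision_svc,
    cross_classify,
    interaction_score,
    loro_decode,
    roi_univariate_contrast,
    searchlight_map,
    zscore_fold,
)

from conftest import balanced_labels, simulate_betas


class TestZscoreFold:
    def test_transform_uses_train_statistics(self):
        train = np.array([[0.0], [4.0]])  # mean 2, sd 2
        test = np.array([[4.0]])
        _, test_z = zscore_fold(train, test)
        assert test_z[0, 0] == pytest.approx(1.0)

    def test_train_standardized(self):
        rng = np.random.default_rng(0)
        train = rng.normal(3, 5, size=(20, 7))
        train_z, _ = zscore_fold(train, train)
        np.testing.assert_allclose(train_z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(train_z.std(axis=0), 1.0, atol=1e-12)

    def test_zero_variance_column_zeroed(self):
        train = np.array([[2.0, 1.0], [2.0, 3.0]])
        test = np.array([[5.0, 2.0]])
        train_z, test_z = zscore_fold(train, test)
        assert np.all(train_z[:, 0] == 0.0) and test_z[0, 0] == 0.0

    def test_no_leakage_from_test_rows(self):
        """Perturbing test rows must not change the train transform."""
        rng = np.random.default_rng(1)
        train = rng.normal(size=(10, 4))
        t1, _ = zscore_fold(train, rng.normal(size=(5, 4)))
        t2, _ = zscore_fold(train, rng.normal(size=(5, 4)) + 100.0)
        np.testing.assert_array_equal(t1, t2)


class TestLoroDecode:
    def test_separable_is_100(self):
        cond, run = balanced_labels(4)
        rng = np.random.default_rng(2)
        X = rng.normal(0, 0.05, size=(len(cond), 5))
        X[:, 0] += np.where(np.char.startswith(cond.astype(str), "endo"), 3.0, -3.0)
        res = loro_decode(X, cond, run, "endo_vs_exo")
        assert res.mean_accuracy == 100.0
        assert res.n_folds == 4

    def test_ten_runs_ten_folds(self):
        cond, run = balanced_labels(10)
        X = np.random.default_rng(3).normal(size=(len(cond), 6))
        assert loro_decode(X, cond, run, "endo_vs_exo").n_folds == 10

    def test_null_centered_on_chance(self):
        """Pure-noise features: seed-averaged accuracy within 50 +/- 2."""
        cond, run = balanced_labels(6)
        rng = np.random.default_rng(4)
        accs = [
            loro_decode(
                rng.normal(size=(len(cond), 8)), cond, run, "endo_vs_exo"
            ).mean_accuracy
            for _ in range(200)
        ]
        assert abs(np.mean(accs) - 50.0) < 2.0

    def test_missing_class_in_run_errors(self):
        cond, run = balanced_labels(3)
        cond = cond.copy()
        cond[(run == 1) & (cond == "endo_self")] = "exo_self"
        cond[(run == 1) & (cond == "endo_other")] = "exo_other"
        X = np.zeros((len(cond), 3))
        with pytest.raises(ValueError, match="run 1"):
            loro_decode(X, cond, run, "endo_vs_exo")

    def test_single_run_errors(self):
        cond, run = balanced_labels(1)
        with pytest.raises(ValueError):
            loro_decode(np.zeros((len(cond), 3)), cond, run, "endo_vs_exo")

    def test_fast_svm_path_matches_svc(self):
        """Low-level libsvm decision values equal the SVC estimator's."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(8, 30))
            p = int(rng.integers(2, 15))
            X = rng.normal(size=(n, p))
            y = np.where(rng.random(n) > 0.5, 1, -1)
            if len(np.unique(y)) < 2:
                continue
            Xt = rng.normal(size=(4, p))
            np.testing.assert_allclose(
                _decision_libsvm(X, y, Xt, 1.0),
                _decision_svc(X, y, Xt, 1.0),
                atol=1e-6,
            )


def _factorial_patterns(
    rng, n_runs, n_vox, self_axis, other_axis, scale=3.0, noise=0.3
):
    """Attention signal along a per-agent axis; balanced 4-condition runs."""
    cond, run = balanced_labels(n_runs, bd.SOCIAL_CONDITIONS)
    X = rng.normal(0, noise, size=(len(cond), n_vox))
    attn = np.where(np.char.startswith(cond.astype(str), "endo"), 1.0, -1.0)
    is_self = np.char.endswith(cond.astype(str), "_self")
    X[is_self] += scale * np.outer(attn[is_self], self_axis)
    X[~is_self] += scale * np.outer(attn[~is_self], other_axis)
    return X, cond, run


class TestCrossClassify:
    def test_shared_axis_generalizes(self):
        rng = np.random.default_rng(6)
        axis = rng.standard_normal(10)
        axis /= np.linalg.norm(axis)
        X, cond, run = _factorial_patterns(rng, 5, 10, axis, axis)
        within = loro_decode(X, cond, run, "endo_vs_exo").mean_accuracy
        cross = cross_classify(X, cond, run).mean_accuracy
        assert cross == pytest.approx(within, abs=5.0)
        assert cross > 90.0

    def test_orthogonal_axis_at_chance(self):
        rng = np.random.default_rng(7)
        a = np.zeros(10)
        a[0] = 1.0
        b = np.zeros(10)
        b[1] = 1.0
        accs = []
        for seed in range(10):
            X, cond, run = _factorial_patterns(
                np.random.default_rng(seed), 5, 10, a, b
            )
            accs.append(cross_classify(X, cond, run).mean_accuracy)
        assert abs(np.mean(accs) - 50.0) < 10.0

    def test_negated_axis_below_chance(self):
        rng = np.random.default_rng(8)
        axis = rng.standard_normal(10)
        X, cond, run = _factorial_patterns(rng, 5, 10, axis, -axis)
        assert cross_classify(X, cond, run).mean_accuracy < 50.0

    def test_missing_condition_errors(self):
        cond, run = balanced_labels(3, bd.SOCIAL_CONDITIONS)
        cond[cond == "endo_other"] = "endo_self"
        with pytest.raises(ValueError, match="missing"):
            cross_classify(np.zeros((len(cond), 3)), cond, run)


class TestInteractionScore:
    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(9)
        X, cond, run = _factorial_patterns(
            rng, 4, 8, rng.standard_normal(8), np.zeros(8)
        )
        swapped = cond.copy()
        for a, b in [("endo_self", "endo_other"), ("exo_self", "exo_other")]:
            swapped[cond == a] = b
            swapped[cond == b] = a
        s1 = interaction_score(X, cond, run)
        s2 = interaction_score(X, swapped, run)
        assert s1 == pytest.approx(-s2)

    def test_self_only_signal_positive(self):
        rng = np.random.default_rng(10)
        X, cond, run = _factorial_patterns(
            rng, 5, 8, rng.standard_normal(8), np.zeros(8)
        )
        assert interaction_score(X, cond, run) > 0

    def test_identical_agents_near_zero(self):
        """Same attention axis for both agents: score averages ~0."""
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            axis = rng.standard_normal(8)
            X, cond, run = _factorial_patterns(rng, 5, 8, axis, axis, noise=1.0)
            scores.append(interaction_score(X, cond, run))
        assert abs(np.mean(scores)) < 2.0


class TestSearchlight:
    def _null_betas(self, grid, n_runs=4, seed=0):
        rng = np.random.default_rng(seed)
        mask = bd.VoxelMask(np.argwhere(np.ones(grid.shape)), grid)
        cond, run = balanced_labels(n_runs)
        return (
            bd.BetaSeries(
                rng.normal(size=(len(cond), mask.n_voxels)), cond, run, mask
            ),
            mask,
        )

    def test_signal_cluster_found(self):
        grid = bd.demo_grid((6, 6, 2))
        bs, mask = self._null_betas(grid, seed=1)
        attn = np.where(np.char.startswith(bs.condition.astype(str), "endo"), 1.0, -1.0)
        cluster = [(2, 2, 0), (3, 2, 0), (2, 3, 0), (3, 3, 0), (2, 2, 1)]
        cols = [np.flatnonzero((bs.mask.indices == c).all(axis=1))[0] for c in cluster]
        bs.betas[:, cols] += 5.0 * attn[:, None]
        mp = searchlight_map(bs, mask, "endo_vs_exo", radius_vox=1)
        peak = np.unravel_index(np.nanargmax(mp), mp.shape)
        dists = [np.linalg.norm(np.subtract(peak, c)) for c in cluster]
        assert min(dists) <= 1.5  # in or adjacent to the cluster

    def test_pure_noise_map_near_chance(self):
        grid = bd.demo_grid((5, 5, 2))
        means = []
        for seed in range(8):
            bs, mask = self._null_betas(grid, n_runs=6, seed=seed)
            mp = searchlight_map(bs, mask, "endo_vs_exo", radius_vox=1)
            means.append(np.nanmean(mp))
        assert abs(np.mean(means) - 50.0) < 2.0

    def test_single_voxel_neighborhood(self):
        grid = bd.demo_grid((3, 3, 1))
        bs, mask = self._null_betas(grid, seed=3)
        attn = np.where(np.char.startswith(bs.condition.astype(str), "endo"), 1.0, -1.0)
        bs.betas[:, 4] = 10.0 * attn
        mp = searchlight_map(bs, mask, "endo_vs_exo", radius_vox=0)
        center = tuple(bs.mask.indices[4])
        assert mp[center] == 100.0

    def test_empty_mask_errors(self):
        grid = bd.demo_grid((3, 3, 1))
        bs, _ = self._null_betas(grid)
        empty = bd.VoxelMask(np.empty((0, 3), int), grid)
        with pytest.raises(ValueError):
            searchlight_map(bs, empty, "endo_vs_exo")


class TestUnivariateContrast:
    def _betas(self, grid, seed=0):
        rng = np.random.default_rng(seed)
        mask = bd.VoxelMask(np.argwhere(np.ones(grid.shape)), grid)
        cond, run = balanced_labels(4)
        return bd.BetaSeries(
            rng.normal(size=(len(cond), mask.n_voxels)), cond, run, mask
        )

    def test_constant_offset_recovered(self):
        grid = bd.demo_grid((3, 3, 1))
        bs = self._betas(grid)
        bs.betas[:] = 1.0
        endo = np.char.startswith(bs.condition.astype(str), "endo")
        bs.betas[endo] += 0.75
        c = roi_univariate_contrast(bs, bs.mask, "endo_vs_exo")
        assert c == pytest.approx(0.75)

    def test_antisymmetry(self):
        grid = bd.demo_grid((3, 3, 1))
        bs = self._betas(grid, seed=5)
        a = roi_univariate_contrast(bs, bs.mask, "endo_vs_exo")
        swapped = bs.condition.copy()
        for x, y in [("endo_self", "exo_self"), ("endo_other", "exo_other")]:
            swapped[bs.condition == x] = y
            swapped[bs.condition == y] = x
        bs2 = bd.BetaSeries(bs.betas, swapped, bs.run, bs.mask)
        b = roi_univariate_contrast(bs2, bs2.mask, "endo_vs_exo")
        assert a == pytest.approx(-b)


def test_accuracy_monotone_in_separation(small_grid, small_masks):
    """Seed-averaged decoding accuracy is non-decreasing in the generator's
    pattern separation (end-to-end through the GLM)."""
    seps = [0.0, 0.05, 0.1, 0.5]
    means = []
    for sep in seps:
        accs = []
        for seed in range(8):
            pats = simulate_betas(sep, 300 + seed, small_grid, small_masks)
            p = pats["roi_1"]
            accs.append(
                loro_decode(p.betas, p.condition, p.run, "endo_vs_exo").mean_accuracy
            )
        means.append(np.mean(accs))
    assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))
    assert means[-1] > means[0]
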