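"""Blink cleaning, smoothing, gaze-grid featurization and eye decoding."""

import numpy as np
import pandas as pd
import pytest

import betadecode as bd
from betadecode.eyetracking import (
    GazeGrid,
    clean_blinks,
    condition_run_average,
    eye_decode,
    grid_featurize,
    grid_from_geometry,
    smooth,
    trial_features,
)
from betadecode.simulate import DisplayGeometry, EyeStream, GazeModel


def make_stream(n=1000, x=None, y=None, pupil=None):
    return EyeStream(
        time_ms=np.arange(n, dtype=float),
        x=np.full(n, 500.0) if x is None else x,
        y=np.full(n, 500.0) if y is None else y,
        pupil=np.full(n, 900.0) if pupil is None else pupil,
    )


GRID = GazeGrid(bounds=(0.0, 0.0, 800.0, 400.0))


class TestCleanBlinks:
    def test_no_blinks_all_valid(self):
        s = clean_blinks(make_stream())
        assert s.valid.all()

    def test_blink_padding_exact(self):
        """100 ms of missing pupil with 50 ms padding: exactly 200 ms invalid."""
        pupil = np.full(1000, 900.0)
        pupil[400:500] = np.nan
        s = clean_blinks(make_stream(pupil=pupil), pad_ms=50)
        assert (~s.valid).sum() == 200
        assert not s.valid[350:550].any()

    def test_negative_pad_errors(self):
        with pytest.raises(ValueError):
            clean_blinks(make_stream(), pad_ms=-1)


class TestSmooth:
    def test_constant_unchanged(self):
        s = smooth(clean_blinks(make_stream()))
        np.testing.assert_allclose(s.x, 500.0)

    def test_step_becomes_ramp(self):
        """A unit step smoothed by a w-sample centered mean equals the
        brute-force window average at every sample."""
        x = np.r_[np.zeros(500), np.ones(500)]
        s = smooth(clean_blinks(make_stream(x=x)), window_ms=20)
        w = 20
        lo, hi = w // 2, w - w // 2  # np.convolve 'same' window split
        brute = np.array(
            [x[max(0, i - (w - hi)) : i + hi].mean() for i in range(1000)]
        )
        # interior samples (edges differ by the truncated window)
        np.testing.assert_allclose(s.x[50:950], brute[50:950], atol=1e-12)
        ramp = s.x[495:505]
        assert np.all(np.diff(ramp) >= 0) and ramp[0] < 0.5 < ramp[-1]

    def test_isolated_valid_sample_unchanged(self):
        pupil = np.full(100, 900.0)
        pupil[:49] = np.nan
        pupil[50:] = np.nan
        x = np.arange(100, dtype=float)
        s = smooth(clean_blinks(make_stream(n=100, x=x, pupil=pupil), pad_ms=0))
        assert s.x[49] == 49.0

    def test_bad_window_errors(self):
        with pytest.raises(ValueError):
            smooth(make_stream(), window_ms=0)

    def test_invalid_stay_invalid(self):
        pupil = np.full(200, 900.0)
        pupil[80:120] = np.nan
        s = smooth(clean_blinks(make_stream(n=200, pupil=pupil), pad_ms=10))
        assert not s.valid[70:130].all()
        assert (~s.valid).sum() == 60


class TestGazeGrid:
    def test_cell_count(self):
        assert GRID.n_cells == 32

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_point_in_rectangle_scan(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-100, 900, 500)
        y = rng.uniform(-100, 500, 500)
        cells = GRID.cell_of(x, y)
        x0, y0, x1, y1 = GRID.bounds
        cw, ch = (x1 - x0) / 8, (y1 - y0) / 4
        for xi, yi, ci in zip(x, y, cells):
            hit = -1
            for row in range(4):
                for col in range(8):
                    lox, loy = x0 + col * cw, y0 + row * ch
                    hix = lox + cw if col < 7 else x1
                    hiy = loy + ch if row < 3 else y1
                    right = xi < hix or (col == 7 and xi == x1)
                    top = yi < hiy or (row == 3 and yi == y1)
                    if lox <= xi and right and loy <= yi and top:
                        hit = row * 8 + col
            assert ci == hit


class TestGridFeaturize:
    def test_single_cell_dwell(self):
        n = 100
        f = grid_featurize(np.full(n, 10.0), np.full(n, 10.0), np.ones(n, bool), GRID)
        assert f[0] == 1.0
        assert f[1:32].sum() == 0.0
        assert f[32:].sum() == 0.0

    def test_alternation_hand_count(self):
        """A,B,A,B: 3 transitions, A->B twice, B->A once; dwell 50/50."""
        xa, xb = 10.0, 110.0  # cells 0 and 1
        x = np.array([xa, xb, xa, xb])
        y = np.full(4, 10.0)
        f = grid_featurize(x, y, np.ones(4, bool), GRID)
        assert f[0] == pytest.approx(0.5) and f[1] == pytest.approx(0.5)
        trans = f[32:].reshape(32, 32)
        assert trans[0, 1] == pytest.approx(2 / 3)
        assert trans[1, 0] == pytest.approx(1 / 3)
        assert trans.sum() == pytest.approx(1.0)

    def test_feature_length(self):
        f = grid_featurize(np.full(5, 10.0), np.full(5, 10.0), np.ones(5, bool), GRID)
        assert f.size == 1056

    def test_no_valid_samples_errors(self):
        with pytest.raises(ValueError):
            grid_featurize(np.zeros(5), np.zeros(5), np.zeros(5, bool), GRID)

    def test_off_grid_excluded(self):
        x = np.array([-50.0, 10.0, 10.0])
        y = np.array([10.0, 10.0, 10.0])
        f = grid_featurize(x, y, np.ones(3, bool), GRID)
        assert f[0] == 1.0  # only in-grid samples count

    def test_transition_not_counted_across_blink(self):
        x = np.array([10.0, 110.0, 110.0])
        valid = np.array([True, False, True])
        f = grid_featurize(x, np.full(3, 10.0), valid, GRID)
        assert f[32:].sum() == 0.0

    def test_fixation_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        f = grid_featurize(
            rng.uniform(0, 800, 200), rng.uniform(0, 400, 200),
            np.ones(200, bool), GRID,
        )
        assert f[:32].sum() == pytest.approx(1.0, abs=1e-12)
        assert f[32:].sum() == pytest.approx(1.0, abs=1e-12)


class TestConditionRunAverage:
    def _features(self, n_runs=10):
        rows = []
        rng = np.random.default_rng(1)
        for r in range(n_runs):
            for c in bd.SOCIAL_CONDITIONS + ("nonsocial",):
                for _ in range(2):
                    rows.append([c, r, *rng.uniform(size=3)])
        return pd.DataFrame(rows, columns=["condition", "run", "f0", "f1", "f2"])

    def test_forty_vectors_default_design(self):
        out = condition_run_average(self._features())
        assert len(out) == 40  # 4 social conditions x 10 runs

    def test_mean_of_two_vectors(self):
        df = pd.DataFrame(
            [["endo_self", 0, 1.0], ["endo_self", 0, 3.0]],
            columns=["condition", "run", "f0"],
        )
        out = condition_run_average(df, conditions=("endo_self",))
        assert out["f0"].iloc[0] == 2.0

    def test_empty_cell_errors(self):
        df = self._features(n_runs=2)
        df = df[~((df.condition == "exo_self") & (df.run == 1))]
        with pytest.raises(ValueError, match="exo_self.*run 1"):
            condition_run_average(df)


class TestEyeDecode:
    def _subject(self, rng, biased, n_runs=6):
        rows = []
        for r in range(n_runs):
            for c in bd.SOCIAL_CONDITIONS:
                v = rng.normal(0, 1.0, 4)
                if biased and c.startswith("endo"):
                    v[0] += 4.0
                rows.append([c, r, *v])
        return pd.DataFrame(
            rows, columns=["condition", "run", "f0", "f1", "f2", "f3"]
        )

    def test_folds_equal_runs(self):
        rng = np.random.default_rng(2)
        subs = [self._subject(rng, True, n_runs=10) for _ in range(3)]
        accs, t, p = eye_decode(subs, "endo_vs_exo")
        assert len(accs) == 3

    def test_biased_gaze_above_chance(self):
        rng = np.random.default_rng(3)
        subs = [self._subject(rng, True) for _ in range(5)]
        accs, t, p = eye_decode(subs, "endo_vs_exo")
        assert np.mean(accs) > 75.0
        assert p < 0.05

    def test_missing_class_errors(self):
        rng = np.random.default_rng(4)
        df = self._subject(rng, False)
        df = df[df.condition != "endo_self"]
        df.loc[df.condition == "endo_other", "condition"] = "exo_other"
        with pytest.raises(ValueError):
            eye_decode([df], "endo_vs_exo")


def test_trial_features_end_to_end(small_design):
    """Simulated streams featurize into one labeled row per trial."""
    geometry = DisplayGeometry()
    streams = bd.simulate_eye(small_design, GazeModel(blink_rate=10.0), geometry, seed=5)
    grid = grid_from_geometry(geometry)
    feats = trial_features(streams, small_design, grid)
    assert len(feats) == small_design.n_trials
    fcols = [c for c in feats.columns if c.startswith("f")]
    assert len(fcols) == 1056
    fix = feats[fcols[:32]].to_numpy()
    np.testing.assert_allclose(fix.sum(axis=1), 1.0, atol=1e-9)
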