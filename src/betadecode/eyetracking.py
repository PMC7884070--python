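"""Eye-movement decoding control.

Gaze streams are cleaned of blink artifacts (missing-pupil samples plus a
padding margin), smoothed with a 20 ms moving average, and featurized per
trial on an 8 x 4 grid spanning the story display area: 32 fixation
dwell-time proportions plus a 32 x 32 directional cell-transition matrix
(1056 features).  Feature vectors are averaged per condition per run and
decoded with the same leave-one-run-out SVM used for the fMRI patterns;
group inference is a one-sample t-test against 50%.  If the eye decoder
stays at chance while the brain decodes, eye movements cannot explain the
fMRI result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoding import ClassifierSpec, _binary_labels, _fit_predict, zscore_fold
from .design import SOCIAL_CONDITIONS, TimedDesign
from .inference import ttest_vs_chance
from .simulate import DisplayGeometry, EyeStream


@dataclass(frozen=True)
class GazeGrid:
    """8 x 4 grid of equal cells over the story bounding box.

    Cells are half-open on their lower edges; the far edges of the box
    belong to the last row/column so the grid partitions the box exactly.
    Cell index = row * n_cols + col (row-major).
    """

    bounds: tuple[float, float, float, float]  # x0, y0, x1, y1
    n_cols: int = 8
    n_rows: int = 4

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Cell index per sample; -1 for off-grid samples."""
        x0, y0, x1, y1 = self.bounds
        cw = (x1 - x0) / self.n_cols
        ch = (y1 - y0) / self.n_rows
        col = np.floor((np.asarray(x, float) - x0) / cw).astype(int)
        row = np.floor((np.asarray(y, float) - y0) / ch).astype(int)
        # far edge belongs to the last cell
        col[np.asarray(x, float) == x1] = self.n_cols - 1
        row[np.asarray(y, float) == y1] = self.n_rows - 1
        cell = row * self.n_cols + col
        off = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        cell[off] = -1
        return cell


def grid_from_geometry(geometry: DisplayGeometry) -> GazeGrid:
    return GazeGrid(bounds=(geometry.x0, geometry.y0, geometry.x1, geometry.y1))


def clean_blinks(stream: EyeStream, pad_ms: float = 50.0) -> EyeStream:
    """Flag missing-pupil samples, padded by ``pad_ms`` on each side, invalid.

    No interpolation is performed; invalid samples are simply excluded from
    smoothing and featurization downstream.
    """
    if pad_ms < 0:
        raise ValueError("pad_ms must be non-negative")
    missing = np.isnan(stream.pupil)
    pad = int(round(pad_ms))  # samples at 1 kHz
    if pad > 0 and missing.any():
        kernel = np.ones(2 * pad + 1)
        missing = np.convolve(missing.astype(float), kernel, mode="same") > 0
    return EyeStream(
        time_ms=stream.time_ms,
        x=stream.x,
        y=stream.y,
        pupil=stream.pupil,
        valid=~missing,
    )


def smooth(stream: EyeStream, window_ms: float = 20.0) -> EyeStream:
    """Centered moving average of gaze position over valid samples only.

    Each valid sample becomes the mean of the valid samples in a centered
    window of ``window_ms`` (at the 1 kHz rate).  Invalid samples are left
    untouched and stay invalid.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    w = max(int(round(window_ms)), 1)
    kernel = np.ones(w)
    valid = stream.valid.astype(float)
    counts = np.convolve(valid, kernel, mode="same")
    x = stream.x.copy()
    y = stream.y.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        xs = np.convolve(np.where(stream.valid, stream.x, 0.0), kernel, "same") / counts
        ys = np.convolve(np.where(stream.valid, stream.y, 0.0), kernel, "same") / counts
    x[stream.valid] = xs[stream.valid]
    y[stream.valid] = ys[stream.valid]
    return EyeStream(
        time_ms=stream.time_ms, x=x, y=y, pupil=stream.pupil, valid=stream.valid.copy()
    )


def grid_featurize(
    x: np.ndarray,
    y: np.ndarray,
    valid: np.ndarray,
    grid: GazeGrid,
    transition_counts: bool = False,
    include_diagonal: bool = False,
) -> np.ndarray:
    """32 fixation + 1024 transition features for one trial's samples.

    Fixation features are the proportions of valid in-grid dwell time per
    cell.  Transition features count directional cell changes between
    consecutive valid samples (same-cell pairs are not transitions, and
    pairs spanning an invalid gap are not counted); by default they are
    normalized to proportions of all transitions, all-zero when none occur.
    """
    valid = np.asarray(valid, bool)
    cell = grid.cell_of(x, y)
    ok = valid & (cell >= 0)
    if not ok.any():
        raise ValueError("no valid in-grid samples in trial")
    n = grid.n_cells
    fixation = np.bincount(cell[ok], minlength=n).astype(float)
    fixation /= fixation.sum()
    # consecutive valid in-grid samples
    pair_ok = ok[:-1] & ok[1:]
    a, b = cell[:-1][pair_ok], cell[1:][pair_ok]
    if not include_diagonal:
        moved = a != b
        a, b = a[moved], b[moved]
    trans = np.zeros((n, n))
    np.add.at(trans, (a, b), 1.0)
    if not transition_counts and trans.sum() > 0:
        trans /= trans.sum()
    return np.concatenate([fixation, trans.ravel()])


def trial_features(
    streams: list[EyeStream],
    design: TimedDesign,
    grid: GazeGrid,
    pad_ms: float = 50.0,
    window_ms: float = 20.0,
    **featurize_kwargs,
) -> pd.DataFrame:
    """Clean, smooth and featurize every story-phase trial of a subject.

    Returns a DataFrame with columns condition, run, and f0..f1055.
    """
    rows = []
    for r, (run, stream) in enumerate(zip(design.runs, streams)):
        cleaned = smooth(clean_blinks(stream, pad_ms=pad_ms), window_ms=window_ms)
        for t in run.trials:
            a = int(t.story_onset * 1000)
            b = int((t.story_onset + t.story_duration) * 1000)
            sl = slice(a, min(b, len(cleaned.time_ms)))
            try:
                feats = grid_featurize(
                    cleaned.x[sl], cleaned.y[sl], cleaned.valid[sl], grid,
                    **featurize_kwargs,
                )
            except ValueError as err:
                raise ValueError(
                    f"run {r}, trial at {t.story_onset}s ({t.condition}): {err}"
                ) from err
            rows.append(dict(condition=t.condition, run=r, features=feats))
    df = pd.DataFrame(
        [r["features"] for r in rows],
        columns=[f"f{i}" for i in range(rows[0]["features"].size)],
    )
    df.insert(0, "condition", [r["condition"] for r in rows])
    df.insert(1, "run", [r["run"] for r in rows])
    return df


def condition_run_average(features: pd.DataFrame, conditions=SOCIAL_CONDITIONS) -> pd.DataFrame:
    """Average trial feature vectors per condition per run.

    Under the default design this yields 4 conditions x 10 runs = 40
    vectors per subject.  An empty (condition, run) cell is an error.
    """
    sub = features[features["condition"].isin(conditions)]
    runs = sorted(sub["run"].unique())
    for c in conditions:
        for r in runs:
            if not ((sub["condition"] == c) & (sub["run"] == r)).any():
                raise ValueError(f"no trials for condition {c!r} in run {r}")
    return (
        sub.groupby(["condition", "run"], as_index=False).mean(numeric_only=True)
    )


def eye_decode(
    subject_vectors: list[pd.DataFrame],
    contrast: str,
    spec: ClassifierSpec = ClassifierSpec(),
) -> tuple[np.ndarray, float, float]:
    """Leave-one-run-out eye-feature decoding with a group t-test vs 50%.

    ``subject_vectors`` holds one condition-by-run averaged feature table
    per subject (from :func:`condition_run_average`).  Returns the
    per-subject run-averaged accuracies and the group (t, p).
    """
    accs = []
    for df in subject_vectors:
        cols = [c for c in df.columns if c.startswith("f")]
        X = df[cols].to_numpy(float)
        cond = df["condition"].to_numpy(object)
        run = df["run"].to_numpy(int)
        y = _binary_labels(cond, contrast)
        keep = y != 0
        X, y, run = X[keep], y[keep], run[keep]
        fold_acc = []
        for r in np.unique(run):
            if len(np.unique(y[run == r])) < 2:
                raise ValueError(f"run {r} is missing one class of {contrast}")
        for r in np.unique(run):
            tr, te = run != r, run == r
            train_z, test_z = zscore_fold(X[tr], X[te])
            pred = _fit_predict(train_z, y[tr], test_z, spec.C)
            fold_acc.append(100.0 * np.mean(pred == y[te]))
        accs.append(float(np.mean(fold_acc)))
    accs = np.array(accs)
    t, p = ttest_vs_chance(accs, chance=50.0)
    return accs, t, p
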