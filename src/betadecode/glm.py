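"""First-level GLM: trialwise (least-squares-all) beta-series estimation.

One boxcar regressor per story trial (100 under the default design), a
single probe regressor of no interest, run-specific intercepts and six
motion regressors are assembled into one joint design matrix; ordinary
least squares per voxel yields the trial x voxel beta matrix that feeds
the multivariate analyses.  The first volumes of each run (default three)
are discarded before fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import TimedDesign
from .roi import VoxelMask

logger = logging.getLogger(__name__)


def canonical_hrf(dt: float, length_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function.

    The kernel is the difference of two gamma densities — response peaking
    at 6 s minus an undershoot peaking at 16 s scaled by 1/6, both with
    1 s dispersion — sampled on [0, length_s] at spacing ``dt`` and
    normalized to unit peak.

    Parameters
    ----------
    dt : float
        Sampling interval in seconds, 0 < dt <= 1.
    length_s : float
        Kernel support in seconds.
    """
    if not 0 < dt <= 1:
        raise ValueError("dt must satisfy 0 < dt <= 1")
    t = np.arange(0, length_s + dt / 2, dt)
    h = stats.gamma.pdf(t, 6.0, scale=1.0) - stats.gamma.pdf(t, 16.0, scale=1.0) / 6.0
    return h / h.max()


@dataclass
class DesignMatrix:
    """Concatenated-run design matrix with per-column role labels.

    ``columns`` is a DataFrame with one row per matrix column carrying
    role ('trial', 'probe', 'run_intercept', 'motion'), and for trial
    columns the run, within-run order, and condition label.
    """

    values: np.ndarray
    columns: pd.DataFrame
    tr: float
    run_rows: list[int]  # retained volumes per run
    discard_volumes: int

    @property
    def n_trial_columns(self) -> int:
        return int((self.columns["role"] == "trial").sum())

    def trial_column_indices(self) -> np.ndarray:
        return np.flatnonzero(self.columns["role"].to_numpy() == "trial")


def _convolved_column(
    onsets: np.ndarray,
    durations: np.ndarray,
    sample_times: np.ndarray,
    run_duration: float,
    dt: float,
) -> np.ndarray:
    """Boxcar(s) convolved with the canonical HRF, sampled at volume times."""
    hires_n = int(np.ceil((run_duration + 32.0) / dt)) + 1
    box = np.zeros(hires_n)
    for onset, dur in zip(onsets, durations):
        a = int(np.round(onset / dt))
        b = int(np.round((onset + dur) / dt))
        box[a:b] = 1.0
    hrf = canonical_hrf(dt)
    conv = np.convolve(box, hrf)[:hires_n] * dt
    idx = np.round(sample_times / dt).astype(int)
    return conv[idx]


def build_design_matrix(
    design: TimedDesign,
    motion: list[np.ndarray] | None = None,
    dt_oversample: float = 0.1,
    discard_volumes: int = 3,
) -> DesignMatrix:
    """Assemble the trialwise (least-squares-all) design matrix.

    Each trial contributes one column: its 10 s story boxcar convolved with
    the canonical HRF at ``dt_oversample`` resolution and sampled at volume
    acquisition times.  A single probe column pools every 4 s probe boxcar
    across runs.  Run intercepts are disjoint 0/1 blocks; motion regressors
    (6 columns) are stacked across runs.  Rows for the first
    ``discard_volumes`` volumes of each run are excluded.
    """
    n_runs = len(design.runs)
    if motion is not None and len(motion) != n_runs:
        raise ValueError("one motion array per run required")
    run_rows = []
    trial_cols, trial_meta = [], []
    probe_segments = []
    motion_segments = []
    trial_index = 1
    for r, run in enumerate(design.runs):
        run_duration = run.n_volumes * run.tr
        vol_times = np.arange(run.n_volumes) * run.tr
        keep = vol_times[discard_volumes:]
        run_rows.append(len(keep))
        for k, t in enumerate(run.trials):
            if t.story_onset + t.story_duration > run_duration:
                raise ValueError(
                    f"trial onset {t.story_onset} s overruns run {r} "
                    f"({run_duration} s)"
                )
            series = _convolved_column(
                np.array([t.story_onset]),
                np.array([t.story_duration]),
                keep,
                run_duration,
                dt_oversample,
            )
            trial_cols.append((r, series))
            trial_meta.append(
                dict(
                    role="trial",
                    run=r,
                    order=k,
                    trial_index=trial_index,
                    condition=t.condition,
                )
            )
            trial_index += 1
        probe_segments.append(
            _convolved_column(
                np.array([t.probe_onset for t in run.trials]),
                np.array([t.probe_duration for t in run.trials]),
                keep,
                run_duration,
                dt_oversample,
            )
        )
        if motion is not None:
            m = np.asarray(motion[r], dtype=float)
            if m.shape != (run.n_volumes, 6):
                raise ValueError(
                    f"motion for run {r} must be ({run.n_volumes}, 6), got {m.shape}"
                )
            motion_segments.append(m[discard_volumes:])

    total_rows = sum(run_rows)
    offsets = np.r_[0, np.cumsum(run_rows)]
    n_trials = len(trial_cols)
    n_motion = 6 if motion is not None else 0
    X = np.zeros((total_rows, n_trials + 1 + n_runs + n_motion))
    meta = []
    for j, ((r, series), m) in enumerate(zip(trial_cols, trial_meta)):
        X[offsets[r] : offsets[r + 1], j] = series
        meta.append(m)
    probe_j = n_trials
    for r, seg in enumerate(probe_segments):
        X[offsets[r] : offsets[r + 1], probe_j] = seg
    meta.append(dict(role="probe", run=-1, order=-1, trial_index=-1, condition=""))
    for r in range(n_runs):
        X[offsets[r] : offsets[r + 1], n_trials + 1 + r] = 1.0
        meta.append(
            dict(role="run_intercept", run=r, order=-1, trial_index=-1, condition="")
        )
    if motion is not None:
        mstack = np.vstack(motion_segments)
        X[:, n_trials + 1 + n_runs :] = mstack
        for m6 in range(6):
            meta.append(
                dict(role="motion", run=-1, order=m6, trial_index=-1, condition="")
            )
    return DesignMatrix(
        values=X,
        columns=pd.DataFrame(meta),
        tr=design.runs[0].tr,
        run_rows=run_rows,
        discard_volumes=discard_volumes,
    )


@dataclass
class BetaSeries:
    """Trial x voxel matrix of GLM coefficients with labels.

    Rows are ordered by (run, within-run trial order); columns follow the
    canonical (lexicographic) voxel order of ``mask``.
    """

    betas: np.ndarray  # n_trials x n_voxels
    condition: np.ndarray  # str per trial
    run: np.ndarray  # int per trial
    mask: VoxelMask

    def __post_init__(self):
        self.condition = np.asarray(self.condition, dtype=object)
        self.run = np.asarray(self.run, dtype=int)
        if not (len(self.betas) == len(self.condition) == len(self.run)):
            raise ValueError("betas, condition and run must agree in length")
        if self.betas.shape[1] != self.mask.n_voxels:
            raise ValueError("beta columns must match mask voxels")

    @property
    def n_trials(self) -> int:
        return len(self.betas)

    def select_conditions(self, labels) -> "BetaSeries":
        keep = np.isin(self.condition, list(labels))
        return BetaSeries(
            self.betas[keep], self.condition[keep], self.run[keep], self.mask
        )

    def labels(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(trial=np.arange(self.n_trials), condition=self.condition, run=self.run)
        )


def _bold_rows(bold_runs, mask: VoxelMask, discard_volumes: int) -> np.ndarray:
    """Stack masked, steady-state voxel time series across runs."""
    flat = mask.flat()
    segs = []
    for vol4d in bold_runs:
        arr = np.asarray(vol4d, dtype=float)
        n_vol = arr.shape[-1]
        y = arr.reshape(-1, n_vol)[flat].T  # volumes x voxels
        segs.append(y[discard_volumes:])
    return np.vstack(segs)


def fit_trial_betas(
    bold_runs, X: DesignMatrix, mask: VoxelMask
) -> BetaSeries:
    """Per-voxel OLS fit; returns trial-regressor coefficients only.

    ``bold_runs`` is a list of 4D arrays (x, y, z, volumes), one per run,
    on the grid of ``mask``.  If the design matrix is rank deficient the
    system is solved by pseudoinverse and a warning names the offending
    columns.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    Y = _bold_rows(bold_runs, mask, X.discard_volumes)
    if Y.shape[0] != X.values.shape[0]:
        raise ValueError(
            f"{Y.shape[0]} retained volumes vs {X.values.shape[0]} design rows"
        )
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.values.shape[1]:
        # identify dependent columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X.values, mode="economic", pivoting=True)
        dropped = sorted(piv[rank:])
        names = [
            f"{X.columns.iloc[j]['role']}[{j}]" for j in dropped
        ]
        msg = f"design matrix rank deficient; collinear columns: {names}"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        coef = np.linalg.pinv(X.values) @ Y
    else:
        coef, *_ = np.linalg.lstsq(X.values, Y, rcond=None)
    tcols = X.trial_column_indices()
    tmeta = X.columns.iloc[tcols]
    order = np.lexsort((tmeta["order"].to_numpy(), tmeta["run"].to_numpy()))
    tcols = tcols[order]
    tmeta = X.columns.iloc[tcols]
    return BetaSeries(
        betas=coef[tcols],
        condition=tmeta["condition"].to_numpy(dtype=object),
        run=tmeta["run"].to_numpy(dtype=int),
        mask=mask,
    )


class BetaSeriesGLM:
    """Trialwise GLM model: BOLD runs + timed design -> beta series.

    Parameters
    ----------
    bold_runs : list of 4D arrays
        One (x, y, z, volumes) array per run.
    design : TimedDesign
    mask : VoxelMask
        Voxels to fit.
    motion : list of (volumes, 6) arrays, optional
    """

    def __init__(
        self,
        bold_runs,
        design: TimedDesign,
        mask: VoxelMask,
        motion=None,
        dt_oversample: float = 0.1,
        discard_volumes: int = 3,
    ):
        self.bold_runs = bold_runs
        self.design = design
        self.mask = mask
        self.motion = motion
        self.design_matrix = build_design_matrix(
            design, motion, dt_oversample=dt_oversample, discard_volumes=discard_volumes
        )

    def fit(self) -> "BetaSeriesResults":
        betas = fit_trial_betas(self.bold_runs, self.design_matrix, self.mask)
        return BetaSeriesResults(self, betas)


@dataclass
class BetaSeriesResults:
    model: BetaSeriesGLM
    beta_series: BetaSeries

    def summary(self) -> pd.DataFrame:
        """Per-condition mean/SD of the mean-over-voxels beta."""
        voxmean = self.beta_series.betas.mean(axis=1)
        df = pd.DataFrame(
            dict(condition=self.beta_series.condition, beta=voxmean)
        )
        return df.groupby("condition")["beta"].agg(["mean", "std", "count"])
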