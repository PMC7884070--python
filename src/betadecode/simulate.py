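"""Synthetic subjects with known ground-truth effect structure.

The generator emulates the story-reading experiment end to end: a timed
trial schedule, 4D BOLD runs built from condition-specific multivoxel
patterns convolved with the canonical HRF plus cosine drift and AR(1)
noise, eye-tracker streams at 1000 Hz with optional condition-dependent
gaze and blink artifacts, smooth random-walk motion parameters, and
probe-phase behavioral responses.

The effect structure is factorial.  The neural amplitude of trial ``t`` at
voxel ``v`` is

    a(t, v) = base + sum_c  s_c * code_c(condition_t) * p_c(v)

over the four contrasts c in {attention, agent, social, interaction}, where
``code_c`` is the +/-1 (or 0) condition coding, ``p_c`` is a standard-normal
pattern vector drawn once per subject and fixed across runs, and ``s_c`` is
the tunable pattern separation.  Setting ``s_c = 0`` makes the two classes
of that contrast exchangeable by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    AGENT_CODE,
    ATTENTION_CODE,
    SOCIAL_CODE,
    TimedDesign,
)
from .glm import _convolved_column
from .roi import GridSpec, RoiSpec, VoxelMask

logger = logging.getLogger(__name__)

CONTRAST_CODES = {
    "attention": ATTENTION_CODE,
    "agent": AGENT_CODE,
    "social": SOCIAL_CODE,
}


@dataclass
class EffectSpec:
    """Tunable ground-truth effect structure for one subject's BOLD.

    pattern_separation maps contrast name ('attention', 'agent', 'social',
    'interaction') to the scale of its multivoxel pattern, in the same
    (arbitrary) signal units as noise_sd.  Zero means no effect for that
    contrast (label-exchangeable data).
    """

    pattern_separation: dict = field(default_factory=dict)
    base_amplitude: float = 1.0
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 1.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")
        unknown = set(self.pattern_separation) - {
            "attention",
            "agent",
            "social",
            "interaction",
        }
        if unknown:
            raise ValueError(f"unknown contrasts: {sorted(unknown)}")


def _condition_code(contrast: str, condition: str) -> float:
    if contrast == "interaction":
        return ATTENTION_CODE[condition] * AGENT_CODE[condition]
    return CONTRAST_CODES[contrast][condition]


def _cosine_drift(n_vol: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete cosine basis with periods longer than ``cutoff_s`` (no DC)."""
    duration = n_vol * tr
    k_max = int(np.floor(2 * duration / cutoff_s))
    t = np.arange(n_vol)
    basis = [
        np.cos(np.pi * k * (2 * t + 1) / (2 * n_vol)) for k in range(1, k_max + 1)
    ]
    if not basis:
        return np.zeros((n_vol, 0))
    return np.column_stack(basis)


def _ar1_noise(rng, shape, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    n_vol = shape[0]
    innov_sd = sd * np.sqrt(1 - rho**2)
    eps = rng.normal(0.0, 1.0, size=shape)
    out = np.empty(shape)
    out[0] = eps[0] * sd
    for i in range(1, n_vol):
        out[i] = rho * out[i - 1] + innov_sd * eps[i]
    return out


def simulate_bold(
    design: TimedDesign,
    grid: GridSpec,
    effects: EffectSpec,
    signal_mask: VoxelMask | None = None,
    seed: int | np.random.Generator = 0,
    dt_oversample: float = 0.1,
    return_truth: bool = False,
):
    """Simulate one subject's 4D BOLD runs on ``grid``.

    Contrast patterns live on ``signal_mask`` voxels (default: the whole
    grid); all voxels receive the shared per-trial base response, drift and
    AR(1) noise.  Deterministic given the seed.  Returns a list of
    (x, y, z, volumes) arrays, plus the ground-truth per-trial amplitude
    matrix when ``return_truth`` is set.
    """
    rng = np.random.default_rng(seed)
    n_vox = grid.n_voxels
    if n_vox == 0:
        raise ValueError("empty grid")
    if signal_mask is None:
        sig_flat = np.arange(n_vox)
    else:
        sig_flat = signal_mask.flat()
    if effects.noise_sd == 0 and not any(effects.pattern_separation.values()):
        warnings.warn(
            "noise_sd = 0 with all pattern separations 0 yields degenerate "
            "(constant-amplitude) voxels",
            RuntimeWarning,
            stacklevel=2,
        )
    # subject-level patterns, fixed across runs
    patterns = {
        c: rng.standard_normal(len(sig_flat))
        for c in ("attention", "agent", "social", "interaction")
    }
    runs = []
    truths = []
    for run in design.runs:
        n_vol = run.n_volumes
        run_duration = n_vol * run.tr
        vol_times = np.arange(n_vol) * run.tr
        n_trials = len(run.trials)
        # per-trial HRF regressors (volumes x trials)
        R = np.column_stack(
            [
                _convolved_column(
                    np.array([t.story_onset]),
                    np.array([t.story_duration]),
                    vol_times,
                    run_duration,
                    dt_oversample,
                )
                for t in run.trials
            ]
        )
        # amplitudes (trials x voxels)
        A = np.full((n_trials, n_vox), effects.base_amplitude)
        for c, sep in effects.pattern_separation.items():
            if sep == 0:
                continue
            codes = np.array(
                [_condition_code(c, t.condition) for t in run.trials]
            )
            A[:, sig_flat] += sep * np.outer(codes, patterns[c])
        signal = R @ A  # volumes x voxels
        drift_basis = _cosine_drift(n_vol, run.tr)
        if drift_basis.shape[1] and effects.drift_amplitude:
            coefs = rng.normal(
                0.0, effects.drift_amplitude, size=(drift_basis.shape[1], n_vox)
            )
            signal = signal + drift_basis @ coefs
        if effects.noise_sd > 0:
            signal = signal + _ar1_noise(
                rng, (n_vol, n_vox), effects.noise_sd, effects.ar1_rho
            )
        runs.append(
            np.ascontiguousarray(signal.T.reshape(grid.shape + (n_vol,)))
        )
        truths.append(A)
    if return_truth:
        return runs, truths
    return runs


def simulate_motion(
    design: TimedDesign, seed: int | np.random.Generator = 0, step_sd: float = 0.02
) -> list[np.ndarray]:
    """Smooth random-walk motion parameters, (volumes, 6) per run.

    Purely to exercise the nuisance-regressor interface; no motion is
    applied to the simulated volumes.
    """
    rng = np.random.default_rng(seed)
    out = []
    for run in design.runs:
        steps = rng.normal(0.0, step_sd, size=(run.n_volumes, 6))
        out.append(np.cumsum(steps, axis=0))
    return out


# ---------------------------------------------------------------------------
# Eye tracking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DisplayGeometry:
    """Story-area bounding box in screen pixels (1920 x 1080 display)."""

    x0: float = 460.0
    y0: float = 340.0
    x1: float = 1460.0
    y1: float = 740.0

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0


@dataclass
class GazeModel:
    """Fixation-sequence gaze generator over the 8 x 4 story grid.

    condition_bias maps a condition label to a length-32 weight vector over
    grid cells used while that condition's story is on screen; missing or
    None means uniform (condition-independent gaze).  Fixations last
    150-400 ms; blinks arrive as a Poisson process at blink_rate per minute
    with 100-300 ms of missing pupil.
    """

    condition_bias: dict = field(default_factory=dict)
    blink_rate: float = 15.0  # events per minute
    fixation_ms: tuple[float, float] = (150.0, 400.0)
    blink_ms: tuple[float, float] = (100.0, 300.0)
    jitter_px: float = 2.0


@dataclass
class EyeStream:
    """One run's eye samples at 1 ms spacing.

    ``pupil`` is NaN during blinks.  ``valid`` is filled by blink cleaning;
    until then it simply marks non-missing pupil samples.
    """

    time_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self):
        if self.valid is None:
            self.valid = ~np.isnan(self.pupil)
        dt = np.diff(self.time_ms)
        if len(dt) and not np.all(dt > 0):
            raise ValueError("sample times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(time_ms=self.time_ms, x=self.x, y=self.y, pupil=self.pupil)
        )


def _cell_centers(geometry: DisplayGeometry, n_cols: int = 8, n_rows: int = 4):
    cw = geometry.width / n_cols
    ch = geometry.height / n_rows
    cx = geometry.x0 + cw * (np.arange(n_cols) + 0.5)
    cy = geometry.y0 + ch * (np.arange(n_rows) + 0.5)
    xx, yy = np.meshgrid(cx, cy)  # row-major: cell = row * n_cols + col
    return np.c_[xx.ravel(), yy.ravel()], (cw, ch)


def simulate_eye(
    design: TimedDesign,
    gaze_model: GazeModel | None = None,
    geometry: DisplayGeometry = DisplayGeometry(),
    seed: int | np.random.Generator = 0,
) -> list[EyeStream]:
    """Simulate 1000 Hz eye streams, one per run.

    Gaze is a sequence of fixations on grid-cell centers (plus pixel
    jitter); during a story the fixated cell is drawn from the condition's
    bias weights, elsewhere uniformly.  Deterministic given the seed.
    """
    if geometry.width <= 0 or geometry.height <= 0:
        raise ValueError("story window must have positive area")
    gm = gaze_model or GazeModel()
    rng = np.random.default_rng(seed)
    centers, (cw, ch) = _cell_centers(geometry)
    n_cells = len(centers)
    uniform = np.full(n_cells, 1.0 / n_cells)
    streams = []
    for run in design.runs:
        n_ms = int(run.n_volumes * run.tr * 1000)
        t = np.arange(n_ms, dtype=float)
        x = np.empty(n_ms)
        y = np.empty(n_ms)
        # condition on screen at each ms (or None between stories)
        cond_at = np.full(n_ms, "", dtype=object)
        for trial in run.trials:
            a = int(trial.story_onset * 1000)
            b = min(int((trial.story_onset + trial.story_duration) * 1000), n_ms)
            cond_at[a:b] = trial.condition
        pos = 0
        while pos < n_ms:
            dur = int(rng.uniform(*gm.fixation_ms))
            cond = cond_at[pos]
            if cond:
                w = np.asarray(
                    gm.condition_bias.get(cond, uniform), dtype=float
                )
                w = w / w.sum()
            else:
                w = uniform
            cell = rng.choice(n_cells, p=w)
            cx, cy = centers[cell]
            end = min(pos + dur, n_ms)
            x[pos:end] = cx + rng.normal(0, gm.jitter_px)
            y[pos:end] = cy + rng.normal(0, gm.jitter_px)
            pos = end
        pupil = 1000.0 + rng.normal(0.0, 10.0, size=n_ms)
        if gm.blink_rate > 0:
            n_blinks = rng.poisson(gm.blink_rate * n_ms / 60000.0)
            starts = rng.uniform(0, n_ms, size=n_blinks)
            for s in starts:
                a = int(s)
                b = min(a + int(rng.uniform(*gm.blink_ms)), n_ms)
                pupil[a:b] = np.nan
        streams.append(EyeStream(time_ms=t, x=x, y=y, pupil=pupil))
    return streams


def simulate_behavior(
    design: TimedDesign,
    p_correct: float = 0.9,
    latency_mean_ms: float = 1800.0,
    latency_sd_ms: float = 400.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Probe responses: one (trial, condition, run, correct, latency_ms) row
    per trial; latencies are truncated to the 4000 ms probe window."""
    if not 0 <= p_correct <= 1:
        raise ValueError("p_correct must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    idx = 1
    for r, run in enumerate(design.runs):
        for t in run.trials:
            lat = rng.normal(latency_mean_ms, latency_sd_ms)
            lat = float(np.clip(lat, 0.0, t.probe_duration * 1000.0))
            rows.append(
                dict(
                    trial_index=idx,
                    condition=t.condition,
                    run=r,
                    correct=bool(rng.random() < p_correct),
                    latency_ms=lat,
                )
            )
            idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Desk-scale layout helpers
# ---------------------------------------------------------------------------


def demo_grid(shape=(20, 20, 10), voxel_mm: float = 2.5) -> GridSpec:
    """Compact isotropic grid for synthetic runs (origin at the corner)."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return GridSpec(shape=tuple(shape), affine=affine)


def demo_rois(
    grid: GridSpec, n_rois: int = 6, radius_mm: float = 5.0
) -> tuple[RoiSpec, ...]:
    """Non-overlapping synthetic spheres spread over a compact grid.

    These stand in for published ROI coordinates when the simulation grid
    does not cover standard space; names are roi_1..roi_n.  Centers are
    snapped to voxel centers and must be at least one voxel farther apart
    than two radii, so the masks are guaranteed disjoint.
    """
    nx, ny, nz = grid.shape
    vox = float(grid.affine[0, 0])
    zc = (nz // 2) * vox
    cols = int(np.ceil(np.sqrt(n_rois)))
    rows = int(np.ceil(n_rois / cols))
    spacing_x = nx * vox / cols
    spacing_y = ny * vox / rows
    min_spacing = 2 * radius_mm + vox
    if min(spacing_x, spacing_y) < min_spacing:
        raise ValueError(
            f"grid too small for {n_rois} disjoint spheres of radius "
            f"{radius_mm} mm (need {min_spacing} mm spacing, have "
            f"{min(spacing_x, spacing_y):.1f})"
        )
    rois = []
    for i in range(n_rois):
        # snap to the nearest voxel center
        cx = round((i % cols + 0.5) * spacing_x / vox) * vox
        cy = round((i // cols + 0.5) * spacing_y / vox) * vox
        rois.append(RoiSpec(f"roi_{i + 1}", (cx, cy, zc), radius_mm))
    return tuple(rois)
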