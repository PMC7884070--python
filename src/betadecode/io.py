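"""Readers and writers for the on-disk formats.

Events are BIDS-style TSV (onset/duration in seconds, trial_type, 0-based
run, 1-based trial_index), motion parameters 6-column TSV, eye samples CSV
(time_ms, x, y, pupil with empty pupil marking blinks), BOLD and masks
NIfTI-1 via nibabel, beta series a NIfTI (one volume per trial) with a
label sidecar TSV, and ROI tables TSV (name, x, y, z, radius).
"""

from __future__ import annotations

import nibabel as nib
import numpy as np
import pandas as pd

from .design import RunDesign, TimedDesign, Trial
from .glm import BetaSeries
from .roi import GridSpec, RoiSpec, VoxelMask
from .simulate import EyeStream

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


# -- events ------------------------------------------------------------------

def write_events(design: TimedDesign, path) -> None:
    design.events().to_csv(path, sep="\t", index=False)


def read_events(
    path, n_volumes: int = 130, tr: float = 2.0, subject_id: str = ""
) -> TimedDesign:
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type", "run"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for i, row in df.iterrows():
        if not np.isfinite(row["onset"]) or row["onset"] < 0:
            raise ValueError(f"{path}: bad onset at line {i + 2}")
    runs = []
    for r in sorted(df["run"].unique()):
        sub = df[df["run"] == r].sort_values("onset")
        trials = [
            Trial(
                condition=row["trial_type"],
                story_onset=float(row["onset"]),
                story_duration=float(row["duration"]),
                probe_onset=float(row.get("probe_onset", row["onset"] + row["duration"])),
                probe_duration=float(row.get("probe_duration", 4.0)),
            )
            for _, row in sub.iterrows()
        ]
        runs.append(RunDesign(trials=trials, n_volumes=n_volumes, tr=tr))
    return TimedDesign(subject_id=subject_id, runs=runs)


# -- motion ------------------------------------------------------------------

def write_motion(motion: list[np.ndarray], paths) -> None:
    for m, path in zip(motion, paths):
        pd.DataFrame(m, columns=MOTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_motion(paths) -> list[np.ndarray]:
    out = []
    for path in paths:
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] != 6:
            raise ValueError(f"{path}: expected 6 motion columns, got {df.shape[1]}")
        out.append(df.to_numpy(float))
    return out


# -- eye samples -------------------------------------------------------------

def write_eye(stream: EyeStream, path) -> None:
    df = stream.to_frame()
    if np.all(df["time_ms"] == df["time_ms"].astype(np.int64)):
        df["time_ms"] = df["time_ms"].astype(np.int64)
    # fixed format keeps 260k-row run files fast to write and compact
    df.to_csv(path, index=False, float_format="%.4f")


def read_eye(path) -> EyeStream:
    df = pd.read_csv(path)
    required = {"time_ms", "x", "y", "pupil"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return EyeStream(
        time_ms=df["time_ms"].to_numpy(float),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        pupil=df["pupil"].to_numpy(float),  # empty fields parse to NaN
    )


# -- NIfTI -------------------------------------------------------------------

def write_bold(arr4d: np.ndarray, grid: GridSpec, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr4d, np.float32), grid.affine), str(path))


def read_bold(path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=float)
    return arr, GridSpec(shape=arr.shape[:3], affine=np.asarray(img.affine))


def write_mask(mask: VoxelMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.as_volume(), mask.grid.affine), str(path))


def read_mask(path) -> VoxelMask:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    grid = GridSpec(shape=vol.shape, affine=np.asarray(img.affine))
    return VoxelMask(indices=np.argwhere(vol > 0), grid=grid)


# -- beta series -------------------------------------------------------------

def write_beta_series(bs: BetaSeries, nifti_path, sidecar_path) -> None:
    """One volume per trial (zeros outside the mask) plus a label TSV."""
    grid = bs.mask.grid
    vol = np.zeros(grid.shape + (bs.n_trials,), dtype=np.float32)
    flat = bs.mask.flat()
    vol.reshape(-1, bs.n_trials)[flat] = bs.betas.T
    nib.save(nib.Nifti1Image(vol, grid.affine), str(nifti_path))
    bs.labels().to_csv(sidecar_path, sep="\t", index=False)


def read_beta_series(nifti_path, sidecar_path, mask: VoxelMask) -> BetaSeries:
    arr, grid = read_bold(nifti_path)
    labels = pd.read_csv(sidecar_path, sep="\t")
    flat = mask.flat()
    betas = arr.reshape(-1, arr.shape[-1])[flat].T
    return BetaSeries(
        betas=betas,
        condition=labels["condition"].to_numpy(object),
        run=labels["run"].to_numpy(int),
        mask=mask,
    )


# -- ROI tables --------------------------------------------------------------

def write_rois(rois, path) -> None:
    pd.DataFrame(
        [
            dict(name=r.name, x=r.center_mm[0], y=r.center_mm[1], z=r.center_mm[2],
                 radius=r.radius_mm)
            for r in rois
        ]
    ).to_csv(path, sep="\t", index=False)


def read_rois(path) -> tuple[RoiSpec, ...]:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "x", "y", "z", "radius"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return tuple(
        RoiSpec(row["name"], (row["x"], row["y"], row["z"]), row["radius"])
        for _, row in df.iterrows()
    )
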