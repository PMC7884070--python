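"""End-to-end orchestration: simulate -> GLM -> decode -> infer -> eye -> report.

Every stage writes its artifacts under the output directory and is skipped
on re-run when those artifacts already exist (``force`` recomputes).  All
randomness derives from the config's master seed through named
``SeedSequence`` spawns, so two identical invocations produce byte-identical
tables.  Analysis choices that published protocols typically leave open
(permutation scheme, searchlight radius, HRF parameters) are recorded in
``provenance.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .decoding import (
    CONTRASTS,
    ClassifierSpec,
    RoiDecoder,
    cross_classify,
    extract_patterns,
    interaction_score,
    loro_decode,
    searchlight_map,
)
from .design import CONDITIONS, make_design
from .eyetracking import condition_run_average, eye_decode, grid_from_geometry, trial_features
from .glm import BetaSeriesGLM
from .inference import GroupDecoding, report_table
from .roi import roi_masks, union_mask
from .simulate import (
    DisplayGeometry,
    EffectSpec,
    GazeModel,
    demo_grid,
    demo_rois,
    simulate_behavior,
    simulate_bold,
    simulate_eye,
    simulate_motion,
)

logger = logging.getLogger(__name__)

ALL_CONTRASTS = list(CONTRASTS) + ["interaction", "xclass"]


@dataclass
class PipelineConfig:
    """Every knob of a synthetic end-to-end run.

    Defaults mirror the experimental design (32 subjects, 10 runs, 130
    volumes at TR 2 s, 10,000 permutations/bootstraps); tests and demos
    shrink them.
    """

    n_subjects: int = 32
    n_runs: int = 10
    per_condition_per_run: int = 2
    grid_shape: tuple[int, int, int] = (20, 20, 10)
    voxel_mm: float = 2.5
    n_rois: int = 6
    roi_radius_mm: float = 5.0
    rois_path: str | None = None  # TSV overriding the synthetic layout
    signal_roi: str | None = None  # ROI carrying the effect (None = all grid)
    pattern_separation: dict = field(default_factory=dict)
    base_amplitude: float = 1.0
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 1.0
    gaze_condition_bias: dict = field(default_factory=dict)
    blink_rate: float = 15.0
    p_correct: float = 0.9
    latency_mean_ms: float = 1800.0
    latency_sd_ms: float = 400.0
    contrasts: list = field(
        default_factory=lambda: ["endo_vs_exo", "self_vs_other", "interaction", "xclass"]
    )
    n_perm: int = 10_000
    n_boot: int = 10_000
    seed: int = 0
    searchlight: bool = False
    searchlight_radius_vox: float = 4.0
    searchlight_contrast: str = "endo_vs_exo"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _subject_ids(cfg: PipelineConfig) -> list[str]:
    return [f"sub-{s + 1:02d}" for s in range(cfg.n_subjects)]


def _rng(cfg: PipelineConfig, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, *keys]))


def _layout(cfg: PipelineConfig):
    grid = demo_grid(cfg.grid_shape, cfg.voxel_mm)
    if cfg.rois_path:
        rois = io.read_rois(cfg.rois_path)
    else:
        rois = demo_rois(grid, cfg.n_rois, cfg.roi_radius_mm)
    masks = roi_masks(rois, grid, report_overlap=False)
    return grid, rois, masks


def _effects(cfg: PipelineConfig) -> EffectSpec:
    return EffectSpec(
        pattern_separation=dict(cfg.pattern_separation),
        base_amplitude=cfg.base_amplitude,
        noise_sd=cfg.noise_sd,
        ar1_rho=cfg.ar1_rho,
        drift_amplitude=cfg.drift_amplitude,
    )


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject: str, err: Exception):
        super().__init__(f"stage {stage!r} failed for {subject!r}: {err}")
        self.stage = stage
        self.subject = subject


# -- stages -------------------------------------------------------------------

def simulate_stage(cfg: PipelineConfig, outdir: Path, force: bool = False) -> None:
    """Write per-subject events, BOLD runs, motion, eye samples, responses."""
    raw = outdir / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    grid, rois, masks = _layout(cfg)
    io.write_rois(rois, outdir / "rois.tsv")
    effects = _effects(cfg)
    signal_mask = masks[cfg.signal_roi] if cfg.signal_roi else None
    geometry = DisplayGeometry()
    gaze = GazeModel(
        condition_bias={
            k: np.asarray(v, float) for k, v in cfg.gaze_condition_bias.items()
        },
        blink_rate=cfg.blink_rate,
    )
    for s, sid in enumerate(_subject_ids(cfg)):
        marker = raw / f"{sid}_responses.tsv"
        if marker.exists() and not force:
            logger.info("simulate: %s cached", sid)
            continue
        try:
            design = make_design(
                subject_id=sid, n_runs=cfg.n_runs,
                per_condition_per_run=cfg.per_condition_per_run,
                seed=_rng(cfg, 0, s),
            )
            io.write_events(design, raw / f"{sid}_events.tsv")
            bold = simulate_bold(
                design, grid, effects, signal_mask=signal_mask, seed=_rng(cfg, 1, s)
            )
            for r, arr in enumerate(bold):
                io.write_bold(arr, grid, raw / f"{sid}_run-{r:02d}_bold.nii.gz")
            motion = simulate_motion(design, seed=_rng(cfg, 2, s))
            io.write_motion(
                motion, [raw / f"{sid}_run-{r:02d}_motion.tsv" for r in range(cfg.n_runs)]
            )
            eye = simulate_eye(design, gaze, geometry, seed=_rng(cfg, 3, s))
            for r, stream in enumerate(eye):
                io.write_eye(stream, raw / f"{sid}_run-{r:02d}_eye.csv")
            simulate_behavior(
                design, cfg.p_correct, cfg.latency_mean_ms, cfg.latency_sd_ms,
                seed=_rng(cfg, 4, s),
            ).to_csv(marker, sep="\t", index=False)
        except Exception as err:  # noqa: BLE001 - re-raised with context
            raise PipelineError("simulate", sid, err) from err


def glm_stage(cfg: PipelineConfig, outdir: Path, force: bool = False) -> None:
    """Fit the trialwise GLM per subject over the union of ROI voxels."""
    raw = outdir / "raw"
    bdir = outdir / "betas"
    bdir.mkdir(parents=True, exist_ok=True)
    grid, rois, masks = _layout(cfg)
    fit_mask = union_mask(masks.values())
    for sid in _subject_ids(cfg):
        nifti = bdir / f"{sid}_betas.nii.gz"
        if nifti.exists() and not force:
            continue
        try:
            design = io.read_events(raw / f"{sid}_events.tsv")
            bold = [
                io.read_bold(raw / f"{sid}_run-{r:02d}_bold.nii.gz")[0]
                for r in range(cfg.n_runs)
            ]
            motion = io.read_motion(
                [raw / f"{sid}_run-{r:02d}_motion.tsv" for r in range(cfg.n_runs)]
            )
            res = BetaSeriesGLM(bold, design, fit_mask, motion=motion).fit()
            io.write_beta_series(
                res.beta_series, nifti, bdir / f"{sid}_labels.tsv"
            )
        except Exception as err:  # noqa: BLE001
            raise PipelineError("glm", sid, err) from err


def _load_betas(cfg: PipelineConfig, outdir: Path):
    grid, rois, masks = _layout(cfg)
    fit_mask = union_mask(masks.values())
    out = {}
    for sid in _subject_ids(cfg):
        out[sid] = io.read_beta_series(
            outdir / "betas" / f"{sid}_betas.nii.gz",
            outdir / "betas" / f"{sid}_labels.tsv",
            fit_mask,
        )
    return out, masks


def decode_stage(cfg: PipelineConfig, outdir: Path, force: bool = False) -> pd.DataFrame:
    """Per-subject, per-ROI decoding results for every configured contrast."""
    ddir = outdir / "decode"
    ddir.mkdir(parents=True, exist_ok=True)
    path = ddir / "decoding.tsv"
    if path.exists() and not force:
        return pd.read_csv(path, sep="\t")
    betas, masks = _load_betas(cfg, outdir)
    rows = []
    for sid, bs in betas.items():
        for roi_name, mask in masks.items():
            for contrast in cfg.contrasts:
                try:
                    res = RoiDecoder(
                        bs, contrast, mask=mask, subject_id=sid
                    ).fit()
                except Exception as err:  # noqa: BLE001
                    raise PipelineError(f"decode[{contrast}/{roi_name}]", sid, err) from err
                rows.append(
                    dict(
                        subject=sid,
                        roi=roi_name,
                        contrast=contrast,
                        n_folds=res.n_folds,
                        mean_accuracy=res.mean_accuracy,
                        fold_accuracies=",".join(
                            f"{a:.4f}" for a in res.fold_accuracies
                        ),
                    )
                )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def _decode_fn(contrast: str, spec: ClassifierSpec = ClassifierSpec()):
    if contrast == "xclass":
        return lambda X, c, r: cross_classify(X, c, r, spec).mean_accuracy
    if contrast == "interaction":
        return lambda X, c, r: interaction_score(X, c, r, spec)
    return lambda X, c, r: loro_decode(X, c, r, contrast, spec).mean_accuracy


def infer_stage(cfg: PipelineConfig, outdir: Path, force: bool = False) -> dict:
    """Group permutation + bootstrap inference, FDR-corrected across ROIs."""
    rdir = outdir / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    done = {
        c: rdir / f"report_{c}.tsv" for c in cfg.contrasts
    }
    if all(p.exists() for p in done.values()) and not force:
        return {c: pd.read_csv(p, sep="\t") for c, p in done.items()}
    betas, masks = _load_betas(cfg, outdir)
    tables = {}
    for ci, contrast in enumerate(cfg.contrasts):
        fn = _decode_fn(contrast)
        results = {}
        for ri, (roi_name, mask) in enumerate(masks.items()):
            subject_data = []
            for bs in betas.values():
                sub = extract_patterns(bs, mask)
                subject_data.append((sub.betas, sub.condition, sub.run))
            g = GroupDecoding(subject_data, fn).fit(
                n_perm=cfg.n_perm, n_boot=cfg.n_boot, seed=_rng(cfg, 5, ci, ri)
            )
            if contrast == "interaction":
                g.chance = 0.0
            results[roi_name] = g
        table = report_table(results)
        table.insert(0, "contrast", contrast)
        table.to_csv(done[contrast], sep="\t", index=False)
        tables[contrast] = table
    return tables


def searchlight_stage(cfg: PipelineConfig, outdir: Path, force: bool = False) -> None:
    """Whole-grid searchlight accuracy map per subject (optional)."""
    if not cfg.searchlight:
        return
    sdir = outdir / "searchlight"
    sdir.mkdir(parents=True, exist_ok=True)
    grid, rois, masks = _layout(cfg)
    fit_mask = union_mask(masks.values())
    betas, _ = _load_betas(cfg, outdir)
    for sid, bs in betas.items():
        path = sdir / f"{sid}_searchlight.nii.gz"
        if path.exists() and not force:
            continue
        mp = searchlight_map(
            bs, fit_mask, cfg.searchlight_contrast, cfg.searchlight_radius_vox
        )
        import nibabel as nib

        nib.save(nib.Nifti1Image(mp.astype(np.float32), grid.affine), str(path))


def eyetrack_stage(cfg: PipelineConfig, outdir: Path, force: bool = False) -> pd.DataFrame:
    """Eye-feature extraction and decoding control (endo/exo, self/other)."""
    rdir = outdir / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    path = rdir / "eye_decoding.tsv"
    if path.exists() and not force:
        return pd.read_csv(path, sep="\t")
    raw = outdir / "raw"
    grid = grid_from_geometry(DisplayGeometry())
    per_subject = []
    for sid in _subject_ids(cfg):
        try:
            design = io.read_events(raw / f"{sid}_events.tsv")
            streams = [
                io.read_eye(raw / f"{sid}_run-{r:02d}_eye.csv")
                for r in range(cfg.n_runs)
            ]
            feats = trial_features(streams, design, grid)
            per_subject.append(condition_run_average(feats))
        except Exception as err:  # noqa: BLE001
            raise PipelineError("eyetrack", sid, err) from err
    rows = []
    for contrast in ("endo_vs_exo", "self_vs_other"):
        accs, t, p = eye_decode(per_subject, contrast)
        rows.append(
            dict(
                contrast=contrast,
                mean_accuracy=float(np.mean(accs)),
                t=t,
                p=p,
                subject_accuracies=",".join(f"{a:.4f}" for a in accs),
            )
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def behavior_stage(cfg: PipelineConfig, outdir: Path, force: bool = False) -> pd.DataFrame:
    """Descriptive per-condition summary of probe accuracy and latency."""
    rdir = outdir / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    path = rdir / "behavior.tsv"
    if path.exists() and not force:
        return pd.read_csv(path, sep="\t")
    frames = []
    for sid in _subject_ids(cfg):
        df = pd.read_csv(outdir / "raw" / f"{sid}_responses.tsv", sep="\t")
        df["subject"] = sid
        frames.append(df)
    allr = pd.concat(frames)
    per_subj = allr.groupby(["subject", "condition"]).agg(
        accuracy=("correct", "mean"), latency_ms=("latency_ms", "mean")
    ).reset_index()
    sem = lambda v: v.std(ddof=1) / np.sqrt(len(v))  # noqa: E731
    summary = per_subj.groupby("condition").agg(
        accuracy_mean=("accuracy", "mean"),
        accuracy_sem=("accuracy", sem),
        latency_mean_ms=("latency_ms", "mean"),
        latency_sem_ms=("latency_ms", sem),
    ).reset_index()
    summary.to_csv(path, sep="\t", index=False)
    return summary


def run_pipeline(cfg: PipelineConfig, outdir, force: bool = False) -> dict:
    """Run every stage; returns {'reports', 'eye', 'behavior', 'decoding'}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    provenance = dict(
        permutation_scheme="condition labels shuffled within run, within subject",
        iteration_pairing="i-th permuted accuracy pooled across subjects",
        bootstrap="percentile, resampling subject means",
        hrf="double-gamma, peaks 6 s / 16 s, dispersions 1 s, ratio 1/6, peak normalized",
        hrf_oversampling_s=0.1,
        discard_volumes_per_run=3,
        searchlight_radius_vox=cfg.searchlight_radius_vox,
        classifier="linear SVM, C=1",
        zero_variance_voxels="set to 0 after fold z-scoring",
        blink_pad_ms=50.0,
        eye_transitions="directional proportions, diagonal excluded",
    )
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    simulate_stage(cfg, outdir, force)
    glm_stage(cfg, outdir, force)
    decoding = decode_stage(cfg, outdir, force)
    reports = infer_stage(cfg, outdir, force)
    searchlight_stage(cfg, outdir, force)
    eye = eyetrack_stage(cfg, outdir, force)
    behavior = behavior_stage(cfg, outdir, force)
    return dict(reports=reports, eye=eye, behavior=behavior, decoding=decoding)
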