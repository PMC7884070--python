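"""Cross-validated pattern classification of beta series.

Leave-one-run-out (LORO) linear SVM decoding with fold-wise
z-normalization fitted on the training runs only, plus the derived
analyses: two-way cross-classification across agents, the attention x
agent interaction difference score, a whole-grid searchlight accuracy
map, and univariate ROI contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .design import SOCIAL_CONDITIONS
from .glm import BetaSeries
from .roi import VoxelMask

CHANCE = 50.0

#: Named binary contrasts: condition labels of class A, class B.
CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "endo_vs_exo": (("endo_self", "endo_other"), ("exo_self", "exo_other")),
    "self_vs_other": (("endo_self", "exo_self"), ("endo_other", "exo_other")),
    **{
        f"{c}_vs_nonsocial": ((c,), ("nonsocial",))
        for c in SOCIAL_CONDITIONS
    },
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Linear max-margin classifier with fixed regularization (C = 1)."""

    C: float = 1.0


@dataclass
class DecodingResult:
    """Per-subject LORO decoding outcome for one contrast."""

    subject_id: str
    contrast: str
    fold_accuracies: np.ndarray  # percent, one per run
    chance: float = CHANCE

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def n_folds(self) -> int:
        return len(self.fold_accuracies)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                subject=[self.subject_id],
                contrast=[self.contrast],
                n_folds=[self.n_folds],
                mean_accuracy=[self.mean_accuracy],
                chance=[self.chance],
            )
        )


def zscore_fold(train: np.ndarray, test: np.ndarray):
    """Z-transform both sets with per-voxel statistics fitted on train only.

    Zero-variance training columns are set to zero in both sets.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[1] != test.shape[1]:
        raise ValueError("train and test must share voxel columns")
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    train_z = (train - mu) / sd_safe
    test_z = (test - mu) / sd_safe
    train_z[:, degenerate] = 0.0
    test_z[:, degenerate] = 0.0
    return train_z, test_z


def _binary_labels(condition, contrast_name: str) -> np.ndarray:
    """+1 for class A, -1 for class B, NaN-free; raises on unknown contrast."""
    class_a, class_b = CONTRASTS[contrast_name]
    y = np.where(
        np.isin(condition, class_a), 1, np.where(np.isin(condition, class_b), -1, 0)
    )
    return y


def _decision_svc(train_X, train_y, test_X, C: float) -> np.ndarray:
    clf = SVC(kernel="linear", C=C)
    clf.fit(train_X, train_y)
    dec = clf.decision_function(test_X)
    if clf.classes_[1] != 1:  # sklearn orders classes ascending: [-1, +1]
        dec = -dec
    return dec


def _decision_libsvm(train_X, train_y, test_X, C: float) -> np.ndarray:
    """Low-level libsvm call, identical solution to ``SVC`` but without the
    per-fit estimator overhead (permutation tests refit thousands of times).

    The raw decision value is oriented toward whichever class libsvm
    encountered first; the sign of the first support-vector coefficient
    (alpha_i * y_i in libsvm's internal labeling) recovers that class, and
    the output is flipped so positive always means class +1.
    """
    from sklearn.svm._base import libsvm

    libsvm.set_verbosity_wrap(0)
    support, SV, _, sv_coef, intercept, *_ = libsvm.fit(
        np.ascontiguousarray(train_X, dtype=np.float64),
        np.asarray(train_y, dtype=np.float64),
        svm_type=0,
        kernel="linear",
        C=C,
    )
    dec = test_X @ (sv_coef[0] @ SV) + intercept[0]
    first_class = train_y[support[0]] if sv_coef[0][0] > 0 else -train_y[support[0]]
    return dec if first_class == 1 else -dec


def _fit_predict(train_X, train_y, test_X, C: float) -> np.ndarray:
    """Linear SVM prediction in {+1, -1}; decision ties go to class A (+1)."""
    try:
        dec = _decision_libsvm(train_X, train_y, test_X, C)
    except Exception:  # pragma: no cover - private-API drift safety net
        dec = _decision_svc(train_X, train_y, test_X, C)
    return np.where(dec >= 0, 1, -1)


def loro_decode(
    patterns: np.ndarray,
    condition: np.ndarray,
    run: np.ndarray,
    contrast: str,
    spec: ClassifierSpec = ClassifierSpec(),
    subject_id: str = "",
) -> DecodingResult:
    """Leave-one-run-out SVM decoding of a binary contrast.

    For each fold the held-out run is the test set; training betas are
    z-normalized per voxel and the same transform is applied to the test
    run.  Fold accuracy is the percent of correctly classified test trials;
    the result carries all fold accuracies and their run average.
    """
    condition = np.asarray(condition, dtype=object)
    run = np.asarray(run, dtype=int)
    y = _binary_labels(condition, contrast)
    keep = y != 0
    X, y, run = patterns[keep], y[keep], run[keep]
    runs = np.unique(run)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out requires at least 2 runs")
    for r in runs:
        if len(np.unique(y[run == r])) < 2:
            raise ValueError(f"run {r} is missing one class of contrast {contrast}")
    fold_acc = []
    for r in runs:
        tr, te = run != r, run == r
        train_z, test_z = zscore_fold(X[tr], X[te])
        pred = _fit_predict(train_z, y[tr], test_z, spec.C)
        fold_acc.append(100.0 * np.mean(pred == y[te]))
    return DecodingResult(
        subject_id=subject_id, contrast=contrast, fold_accuracies=np.array(fold_acc)
    )


def cross_classify(
    patterns: np.ndarray,
    condition: np.ndarray,
    run: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
    subject_id: str = "",
    train_all_runs: bool = False,
) -> DecodingResult:
    """Two-way cross-classification of attention type across agents.

    One classifier learns endogenous vs. exogenous on self stories and is
    tested on other stories; a second learns on other stories and is tested
    on self stories; the result averages the two directions.  By default
    each direction runs leave-one-run-out folds: train on the training
    agent's trials from all runs but the held-out one, test on the held-out
    run's trials of the other agent.  ``train_all_runs`` instead trains each
    direction once on all runs of the training agent.
    """
    condition = np.asarray(condition, dtype=object)
    run = np.asarray(run, dtype=int)
    runs = np.unique(run)
    for r in runs:
        present = set(condition[run == r])
        missing = set(SOCIAL_CONDITIONS) - present
        if missing:
            raise ValueError(f"run {r} is missing conditions {sorted(missing)}")
    attn = np.where(np.char.startswith(condition.astype(str), "endo"), 1, -1)
    is_self = np.char.endswith(condition.astype(str), "_self")
    social = np.isin(condition, SOCIAL_CONDITIONS)
    direction_acc = []
    for train_self in (True, False):
        tr_pool = social & (is_self == train_self)
        te_pool = social & (is_self != train_self)
        fold_acc = []
        for r in runs:
            tr = tr_pool if train_all_runs else (tr_pool & (run != r))
            te = te_pool & (run == r)
            train_z, test_z = zscore_fold(patterns[tr], patterns[te])
            pred = _fit_predict(train_z, attn[tr], test_z, spec.C)
            fold_acc.append(100.0 * np.mean(pred == attn[te]))
        direction_acc.append(fold_acc)
    fold_mean = np.mean(direction_acc, axis=0)
    return DecodingResult(
        subject_id=subject_id, contrast="xclass", fold_accuracies=fold_mean
    )


def interaction_score(
    patterns: np.ndarray,
    condition: np.ndarray,
    run: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
    subject_id: str = "",
) -> float:
    """Attention-decoding difference between agents, in percentage points:
    (endo-self vs exo-self) minus (endo-other vs exo-other)."""
    condition = np.asarray(condition, dtype=object)
    self_kept = np.isin(condition, ("endo_self", "exo_self"))
    other_kept = np.isin(condition, ("endo_other", "exo_other"))
    acc_self = loro_decode(
        patterns[self_kept],
        condition[self_kept],
        np.asarray(run)[self_kept],
        "endo_vs_exo",
        spec,
        subject_id,
    ).mean_accuracy
    acc_other = loro_decode(
        patterns[other_kept],
        condition[other_kept],
        np.asarray(run)[other_kept],
        "endo_vs_exo",
        spec,
        subject_id,
    ).mean_accuracy
    return acc_self - acc_other


def _sphere_offsets(radius_vox: float) -> np.ndarray:
    r = int(np.floor(radius_vox))
    rng = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(rng, rng, rng, indexing="ij")
    offs = np.c_[ii.ravel(), jj.ravel(), kk.ravel()]
    return offs[np.linalg.norm(offs, axis=1) <= radius_vox]


def searchlight_map(
    betas: BetaSeries,
    brain_mask: VoxelMask,
    contrast: str,
    radius_vox: float = 4.0,
    spec: ClassifierSpec = ClassifierSpec(),
) -> np.ndarray:
    """Per-voxel LORO accuracy map over spherical neighborhoods.

    For every in-mask voxel, decodes the contrast on the voxel's spherical
    neighborhood (intersected with the mask; partial spheres allowed) and
    stores the run-averaged accuracy at the center.  Returns a grid-shaped
    array, NaN outside the mask.
    """
    if brain_mask.n_voxels == 0:
        raise ValueError("empty mask")
    grid_shape = betas.mask.grid.shape
    col_of = {tuple(v): j for j, v in enumerate(betas.mask.indices)}
    in_mask = set(map(tuple, brain_mask.indices))
    offsets = _sphere_offsets(max(radius_vox, 0.0))
    out = np.full(grid_shape, np.nan)
    for center in brain_mask.indices:
        neigh = center + offsets
        cols = [
            col_of[t]
            for t in map(tuple, neigh)
            if t in in_mask and t in col_of
        ]
        if not cols:
            continue
        res = loro_decode(
            betas.betas[:, cols], betas.condition, betas.run, contrast, spec
        )
        out[tuple(center)] = res.mean_accuracy
    return out


def roi_univariate_contrast(
    betas: BetaSeries, mask: VoxelMask, contrast: str
) -> float:
    """Mean-over-ROI univariate difference: mean beta of class A minus B."""
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    sub = extract_patterns(betas, mask)
    y = _binary_labels(sub.condition, contrast)
    if not (y == 1).any() or not (y == -1).any():
        raise ValueError("both classes must be present")
    return float(
        sub.betas[y == 1].mean() - sub.betas[y == -1].mean()
    )


def extract_patterns(betas: BetaSeries, mask: VoxelMask) -> BetaSeries:
    """Restrict a beta series to the voxels of ``mask`` (canonical order)."""
    col_of = {tuple(v): j for j, v in enumerate(betas.mask.indices)}
    cols = [col_of[t] for t in map(tuple, mask.indices) if t in col_of]
    if not cols:
        raise ValueError("mask does not intersect the beta-series grid")
    kept = VoxelMask(
        indices=np.array([v for v in mask.indices if tuple(v) in col_of]),
        grid=betas.mask.grid,
    )
    return BetaSeries(betas.betas[:, cols], betas.condition, betas.run, kept)


class RoiDecoder:
    """Decoding model for one subject, ROI and contrast.

    ``contrast`` is a named binary contrast, ``"xclass"`` for two-way
    cross-classification, or ``"interaction"`` for the attention x agent
    difference score.  ``fit()`` returns a :class:`DecodingResult` (or the
    interaction score wrapped in one, with the score as ``mean_accuracy``
    offset from 0 rather than 50).
    """

    def __init__(
        self,
        betas: BetaSeries,
        contrast: str,
        mask: VoxelMask | None = None,
        spec: ClassifierSpec = ClassifierSpec(),
        subject_id: str = "",
    ):
        self.betas = extract_patterns(betas, mask) if mask is not None else betas
        self.contrast = contrast
        self.spec = spec
        self.subject_id = subject_id

    def fit(self) -> DecodingResult:
        b = self.betas
        if self.contrast == "xclass":
            return cross_classify(
                b.betas, b.condition, b.run, self.spec, self.subject_id
            )
        if self.contrast == "interaction":
            score = interaction_score(
                b.betas, b.condition, b.run, self.spec, self.subject_id
            )
            return DecodingResult(
                subject_id=self.subject_id,
                contrast="interaction",
                fold_accuracies=np.array([score]),
                chance=0.0,
            )
        return loro_decode(
            b.betas, b.condition, b.run, self.contrast, self.spec, self.subject_id
        )
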