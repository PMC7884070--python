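# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Experimental design model

A subject is a set of runs; each run holds `n_volumes = 130` volumes at
`tr = 2` s and 10 story trials (2 per condition x 5 conditions: the 2 x 2
factorial endogenous/exogenous x self/other plus a nonsocial control).
Trial order is drawn by rejection sampling under the constraint that
consecutive trials never share a condition; a feasibility check (one
condition holding more than half the slots, rounded up) and an attempt cap
turn unsatisfiable requests into errors.  Timing: the first story starts at
18 s; each trial is a 10 s story plus a 4 s probe; inter-trial intervals
are uniform on [9, 11] s with onsets rounded to the millisecond.  Because
i.i.d. intervals can exceed the fixed run length, interval vectors are
resampled until the last probe offset leaves at least 12 s of trailing
baseline inside the 260 s run; a configuration that cannot fit even with
all-minimum intervals raises instead of truncating.  The 12 s trailing
baseline is therefore a minimum, not an exact value — the only reading
compatible with a fixed 130-volume run and jittered intervals.

## BOLD generator

For trial t and voxel v the neural amplitude is

    a(t, v) = base + sum_c s_c * code_c(cond_t) * p_c(v),

with contrasts c in {attention, agent, social, interaction}, +/-1 (or 0)
condition codings `code_c`, standard-normal pattern vectors `p_c` drawn once
per subject and fixed across runs (so leave-one-run-out generalization is
the quantity being tested), and tunable separations `s_c`.  Setting
`s_c = 0` makes the two classes of contrast c exchangeable by construction
— the basis of all null-calibration tests.  Patterns live on a designated
signal mask (default: the whole grid), so effects can be confined to one
ROI.

The voxel time series is `sum_t a(t, v) * (boxcar_t (*) HRF)` sampled at
volume times, plus a discrete-cosine drift (periods > 128 s, coefficient
SD `drift_amplitude`, default 1) and stationary AR(1) Gaussian noise
(marginal SD `noise_sd`, default 1; rho = 0.3 by default — conventional
values, as the noise model of the target acquisition is unspecified).
Defaults mirror the experiment: 32 subjects, 10 runs; tests shrink both.
Default grid: 2.5 mm isotropic.  Units are arbitrary; only the
separation-to-noise ratio matters.  What the generator does *not* model:
hemodynamic nonlinearity, physiological noise, spatial autocorrelation,
head motion (motion regressors are smooth random walks generated purely to
exercise the nuisance interface).  Passing tests therefore show the
*analysis machinery* is correct and calibrated, not that real BOLD meets
its assumptions.

## First-level GLM

Least-squares-all: one joint model with 100 trial regressors (10 s story
boxcars convolved with the canonical double-gamma HRF — response gamma
peaking at 6 s minus undershoot gamma peaking at 16 s scaled by 1/6,
dispersions 1 s, kernel sampled on [0, 32] s and normalized to unit peak),
one pooled 4 s probe regressor, 10 run intercepts, 6 motion regressors.
Convolution is computed at 0.1 s resolution and sampled at volume onsets
(slice-timing correction is assumed done upstream).  The first three
volumes of each run are discarded before fitting.  Estimation is ordinary
least squares per voxel; a rank-deficient design falls back to the
pseudoinverse with a warning naming the collinear columns.  No high-pass
filter or prewhitening is applied beyond the run intercepts (the drift in
the generator is low-order and largely absorbed by them); both choices are
deliberate defaults where the target analysis is silent, and the design
matrix builder accepts arbitrary extra nuisance via the motion interface.

## ROI geometry

ROIs are spheres (center in MNI mm, radius 10 mm by default); a voxel
belongs to the mask when its center lies within the radius (no
partial-volume weighting).  Millimeter-to-voxel conversion rounds
half-integers away from zero.  Masks are stored in canonical lexicographic
(i, j, k) order, so extraction is insertion-order invariant.  The six
default centers are the theory-of-mind meta-analytic peaks; overlap between
user-supplied ROIs is permitted but logged.  The desk-scale generator
(`demo_rois`) instead places disjoint spheres on a compact grid and
enforces a one-voxel margin between them, because touching spheres share
boundary voxels and would leak signal between "independent" ROIs (a failure
mode we hit and now test against).

## Decoding

Linear SVM, C = 1, binary contrasts only.  Per leave-one-run-out fold,
per-voxel mean/SD are computed on the training runs and applied to both
sets; zero-variance training voxels are zeroed in both.  Fold accuracy is
trial-weighted within the fold; the subject statistic is the unweighted
mean over folds ("run-averaged accuracy").  Decision ties (value exactly 0)
go to class A — measure-zero with continuous features but pinned down for
reproducibility.  Cross-classification runs two directions (train self /
test other and the reverse); each direction holds out one run of the *test*
agent per fold and trains on the other agent's remaining runs
(`train_all_runs=True` switches to training on all runs of the training
agent).  The interaction score is the difference of the two within-agent
attention decodings, in percentage points (chance 0).  The searchlight
decodes each in-mask voxel's spherical neighborhood (radius 4 voxels = 10 mm
on the 2.5 mm default grid; partial spheres allowed) and writes the
run-averaged accuracy at the center.

For speed, the SVM is fit through scikit-learn's low-level libsvm binding
(identical solutions to `SVC`, verified in the tests to 1e-6 on random
problems; an `SVC` fallback guards against private-API drift).  Permutation
tests refit the classifier thousands of times, and the estimator wrapper
overhead — not libsvm itself — would otherwise dominate the runtime.

## Group inference

The permutation scheme shuffles condition labels within each run within
each subject — the most conservative exchangeable scheme that preserves run
balance and the cross-validation structure — and pools the i-th permuted
accuracy across subjects into the i-th null group mean.  p = (1 + #{null >
true}) / (1 + N) with strict inequality, so ties count against rejection
and the smallest reportable p at N = 10,000 is 1/10,001 (prints as 0.0001).
The 95% CI is a percentile bootstrap (default 10,000 resamples of subject
means).  FDR across ROIs is Benjamini-Hochberg step-up (delegated to
statsmodels; tests verify it against a hand-rolled step-up oracle to
1e-12).  Significance requires corrected p < 0.05 *and* a CI excluding
chance.  Labels are permuted on the beta series, not re-fit through the
GLM — the only computationally feasible reading of re-running the MVPA
10,000 times, and the label-exchangeability argument applies equally at
the beta level.  The searchlight group output is voxelwise one-sample t
vs. 50% with an uncorrected p < 0.001 threshold only (no cluster-level
correction).

## Eye-movement control

Blink cleaning flags missing-pupil samples plus 50 ms padding on each side
(configurable; the padding value is a default where the target analysis
gives none) with no interpolation.  Smoothing is a 20 ms moving average
over valid samples only; invalid samples stay invalid.  Featurization on
the 8 x 4 story-area grid: dwell-time proportions over the 32 cells, and
directional transitions between consecutive valid samples that land in
different cells — "saccades between regions" operationalized as cell
changes, with no velocity-based event detection, since the features are
defined directly on grid regions.  Same-cell pairs are not transitions
(zero diagonal) and pairs spanning a blink gap are not counted; transition
features are proportions of all transitions (all-zero when none occur;
raw counts and diagonal inclusion are config switches).  Per-trial vectors
are averaged per condition per run (4 x 10 = 40 vectors per subject under
the default design), decoded with the identical fold-normalized LORO SVM,
and tested against 50% with a one-sample t-test over subjects.  The gaze
generator draws fixation targets from per-condition cell weights (uniform
= condition-independent gaze, the null regime); the biased regime used in
tests down-weights the non-preferred display half by 30%, which yields
clearly above-chance but non-saturated decoding — full saturation would
give every subject 100% accuracy and a degenerate (zero-variance) t-test,
which the package treats as an error rather than p = 0.

## Numerical and scale choices

Every random stage consumes an explicit seed; the pipeline derives
per-subject, per-stage streams from one master seed via `SeedSequence`
spawns, so identical configs produce byte-identical outputs.  Tests and the
acceptance script run at desk scale — 4-8 subjects, 4-6 runs, grids of a
few hundred voxels, 200-500 permutations — sizes chosen so the Monte-Carlo
bands asserted (e.g. null accuracy within 50 +/- 2 seed-averaged, type-I
rate in [0.02, 0.10] over 200 replicates, bootstrap coverage in [92, 98]%)
have comfortable margins at the implied binomial standard errors.  Package
defaults remain the experiment-scale values (32 subjects, 10 runs,
n_perm = n_boot = 10,000).

## Known limitations

- No AR(1) prewhitening or high-pass filtering in estimation; with strong
  drift and weak run intercepts, beta-series noise is inflated.
- The searchlight loops over centers in Python; whole-brain maps at full
  resolution are slow (hours, not minutes) — it is intended for targeted
  masks at desk scale.
- Eye featurization assumes the nominal 1000 Hz / 1 ms sampling of the
  stream; irregular sampling is not resampled.
- The nonsocial condition shares the social conditions' base response; no
  semantic-content model beyond the factorial amplitude codes.
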