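"""Trial schedule for the story-reading experiment.

The experiment crosses attention type (endogenous vs. exogenous) with agent
(self vs. other) and adds a nonsocial control, five conditions in all.  Each
run presents 10 story trials (two per condition) in a randomized order with
no two consecutive trials from the same condition.  A run holds 130 volumes
at TR = 2 s: 18 s of baseline, then for each trial a 10 s story and a 4 s
probe statement, separated by 9-11 s inter-trial intervals, with a final
baseline after the last probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS: tuple[str, ...] = (
    "endo_self",
    "exo_self",
    "endo_other",
    "exo_other",
    "nonsocial",
)

SOCIAL_CONDITIONS: tuple[str, ...] = CONDITIONS[:4]

#: +1 endogenous, -1 exogenous, 0 for the nonsocial control
ATTENTION_CODE = {
    "endo_self": 1.0,
    "exo_self": -1.0,
    "endo_other": 1.0,
    "exo_other": -1.0,
    "nonsocial": 0.0,
}
#: +1 self, -1 other, 0 for the nonsocial control
AGENT_CODE = {
    "endo_self": 1.0,
    "exo_self": 1.0,
    "endo_other": -1.0,
    "exo_other": -1.0,
    "nonsocial": 0.0,
}
#: +1 social story, -1 nonsocial control
SOCIAL_CODE = {c: (1.0 if c != "nonsocial" else -1.0) for c in CONDITIONS}


@dataclass(frozen=True)
class Trial:
    """One story trial: a 10 s story followed by a 4 s probe statement."""

    condition: str
    story_onset: float  # seconds from run start
    story_duration: float
    probe_onset: float
    probe_duration: float


@dataclass
class RunDesign:
    trials: list[Trial]
    n_volumes: int = 130
    tr: float = 2.0

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr


@dataclass
class TimedDesign:
    """Per-subject trial schedule across runs.

    ``runs[r].trials`` are in presentation order; run indices are 0-based.
    """

    subject_id: str
    runs: list[RunDesign] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return sum(len(r.trials) for r in self.runs)

    def events(self) -> pd.DataFrame:
        """BIDS-style long table: onset, duration, trial_type, run, trial_index."""
        rows = []
        idx = 1
        for r, run in enumerate(self.runs):
            for t in run.trials:
                rows.append(
                    dict(
                        onset=t.story_onset,
                        duration=t.story_duration,
                        trial_type=t.condition,
                        run=r,
                        trial_index=idx,
                        probe_onset=t.probe_onset,
                        probe_duration=t.probe_duration,
                    )
                )
                idx += 1
        return pd.DataFrame(rows)

    def conditions(self) -> np.ndarray:
        return np.array(
            [t.condition for run in self.runs for t in run.trials], dtype=object
        )

    def run_labels(self) -> np.ndarray:
        return np.array(
            [r for r, run in enumerate(self.runs) for _ in run.trials], dtype=int
        )


def generate_trial_sequence(
    n_runs: int = 10,
    per_condition_per_run: int = 2,
    conditions: tuple[str, ...] = CONDITIONS,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 10_000,
) -> list[list[str]]:
    """Randomized per-run condition sequences with no adjacent repeats.

    Each run contains ``per_condition_per_run`` trials of every condition,
    shuffled under the constraint that two consecutive trials never share a
    condition.  Sampling is by rejection: shuffle, test, repeat.

    Returns a list of ``n_runs`` lists of condition labels.

    Raises
    ------
    ValueError
        If the constraint is unsatisfiable (one condition holding more than
        half the slots, rounded up) or no valid shuffle is found within
        ``max_attempts``.
    """
    if n_runs < 1 or per_condition_per_run < 1:
        raise ValueError("n_runs and per_condition_per_run must be positive")
    n = per_condition_per_run * len(conditions)
    if per_condition_per_run > (n + 1) // 2:
        raise ValueError(
            f"no-adjacent-repeat arrangement impossible: one condition would "
            f"occupy {per_condition_per_run} of {n} slots"
        )
    rng = np.random.default_rng(seed)
    base = [c for c in conditions for _ in range(per_condition_per_run)]
    runs = []
    for _ in range(n_runs):
        for _attempt in range(max_attempts):
            order = list(rng.permutation(base))
            if all(a != b for a, b in zip(order, order[1:])):
                runs.append(order)
                break
        else:
            raise ValueError(
                f"no valid trial order found in {max_attempts} attempts"
            )
    return runs


def assign_timing(
    sequence: list[list[str]],
    iti_range: tuple[float, float] = (9.0, 11.0),
    story_s: float = 10.0,
    probe_s: float = 4.0,
    pre_s: float = 18.0,
    post_s: float = 12.0,
    tr: float = 2.0,
    n_volumes: int = 130,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sub-01",
    max_attempts: int = 10_000,
) -> TimedDesign:
    """Attach onsets to a condition sequence.

    The first story starts at ``pre_s``; each subsequent story follows the
    previous probe offset after an inter-trial interval drawn uniformly from
    ``iti_range`` (onsets rounded to the millisecond).  A run must leave at
    least ``post_s`` of baseline before the end of the 130-volume window;
    interval vectors that would overrun are resampled, and an error is raised
    if the timing cannot fit at all (e.g. with all-minimum intervals).
    """
    rng = np.random.default_rng(seed)
    run_len = n_volumes * tr
    runs = []
    for conds in sequence:
        n_iti = max(len(conds) - 1, 0)
        minimal = pre_s + len(conds) * (story_s + probe_s) + n_iti * iti_range[0]
        if minimal + post_s > run_len:
            raise ValueError(
                f"timing overruns the run: {minimal + post_s:.1f} s needed, "
                f"{run_len:.1f} s available ({n_volumes} volumes at TR {tr})"
            )
        for _attempt in range(max_attempts):
            itis = rng.uniform(*iti_range, size=n_iti)
            trials = []
            t = pre_s
            for i, c in enumerate(conds):
                onset = round(t, 3)
                probe_on = round(onset + story_s, 3)
                trials.append(Trial(c, onset, story_s, probe_on, probe_s))
                t = probe_on + probe_s
                if i < n_iti:
                    t += itis[i]
            if trials[-1].probe_onset + probe_s + post_s <= run_len:
                break
        else:  # pragma: no cover - reachable only with pathological ranges
            raise ValueError("could not sample inter-trial intervals that fit")
        runs.append(RunDesign(trials=trials, n_volumes=n_volumes, tr=tr))
    return TimedDesign(subject_id=subject_id, runs=runs)


def make_design(
    subject_id: str = "sub-01",
    n_runs: int = 10,
    per_condition_per_run: int = 2,
    seed: int | np.random.Generator = 0,
    **timing_kwargs,
) -> TimedDesign:
    """Convenience wrapper: sequence generation plus timing in one call."""
    rng = np.random.default_rng(seed)
    seq = generate_trial_sequence(
        n_runs=n_runs, per_condition_per_run=per_condition_per_run, seed=rng
    )
    return assign_timing(seq, seed=rng, subject_id=subject_id, **timing_kwargs)
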