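"""Group-level inference for decoding accuracies.

The group statistic is the mean over subjects of the run-averaged decoding
accuracy.  Its null distribution is built by repeating the decoding with
permuted condition labels (shuffled within run, within subject, preserving
the leave-one-run-out structure); permutation iteration i pools the i-th
permuted accuracy from every subject into one group mean.  The p-value is

    p = (1 + #{permuted group means > true group mean}) / (1 + N)

with the tie-conservative strict inequality, so the smallest reportable p
at N = 10,000 is 1/10,001 ~ 0.0001.  A percentile bootstrap over subjects
gives the 95% CI, and Benjamini-Hochberg FDR corrects across ROIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def permutation_pvalue(true_stat: float, null_stats) -> float:
    """(1 + #{null > true}) / (1 + N); ties do not count as exceeding."""
    null_stats = np.asarray(null_stats, dtype=float)
    if null_stats.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(null_stats > true_stat)) / (1 + null_stats.size))


def bootstrap_ci(
    subject_values,
    n_boot: int = 10_000,
    level: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the group mean (resampling subjects)."""
    values = np.asarray(subject_values, dtype=float)
    if values.size == 0:
        raise ValueError("no subject values")
    if values.size == 1:
        logger.warning("bootstrap CI degenerate with a single subject")
        return float(values[0]), float(values[0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(means, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def ttest_vs_chance(subject_values, chance: float = 50.0) -> tuple[float, float]:
    """One-sample two-sided t-test of subject values against chance."""
    values = np.asarray(subject_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 subjects")
    if np.allclose(values.std(ddof=1), 0.0):
        raise ValueError("zero variance across subjects")
    res = stats.ttest_1samp(values, popmean=chance)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupInference:
    """Group permutation/bootstrap inference for one contrast and ROI."""

    true_mean: float
    subject_values: np.ndarray
    null_means: np.ndarray
    p_uncorrected: float
    ci95: tuple[float, float]
    n_perm: int
    n_boot: int
    chance: float = 50.0
    p_fdr: float | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        """Corrected p < alpha and the 95% CI does not cross chance."""
        p = self.p_fdr if self.p_fdr is not None else self.p_uncorrected
        lo, hi = self.ci95
        return p < alpha and (lo > self.chance or hi < self.chance)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                mean=[self.true_mean],
                ci_low=[self.ci95[0]],
                ci_high=[self.ci95[1]],
                p=[self.p_uncorrected],
                p_fdr=[self.p_fdr],
                n_perm=[self.n_perm],
                n_boot=[self.n_boot],
            )
        )


def _permute_within_runs(rng, condition: np.ndarray, run: np.ndarray) -> np.ndarray:
    out = condition.copy()
    for r in np.unique(run):
        rows = np.flatnonzero(run == r)
        out[rows] = condition[rows[rng.permutation(len(rows))]]
    return out


def group_permutation_test(
    subject_data: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    decode_fn,
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> GroupInference:
    """Group-mean permutation test of a decoding statistic.

    Parameters
    ----------
    subject_data : list of (patterns, condition, run) triples, one per subject.
    decode_fn : callable(patterns, condition, run) -> accuracy (%)
        The decoding statistic; it is re-run on every permutation.
    n_perm : int
        Label permutations; condition labels are shuffled within each run
        within each subject, and iteration i pools the i-th permuted
        accuracy across subjects into one group mean.
    """
    if len(subject_data) < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    true_vals = np.array(
        [decode_fn(X, cond, run) for X, cond, run in subject_data]
    )
    null = np.zeros((n_perm, len(subject_data)))
    for s, (X, cond, run) in enumerate(subject_data):
        cond = np.asarray(cond, dtype=object)
        run = np.asarray(run, dtype=int)
        for i in range(n_perm):
            perm = _permute_within_runs(rng, cond, run)
            null[i, s] = decode_fn(X, perm, run)
    null_means = null.mean(axis=1)
    true_mean = float(true_vals.mean())
    p = permutation_pvalue(true_mean, null_means)
    ci = bootstrap_ci(true_vals, n_boot=n_boot, seed=rng)
    return GroupInference(
        true_mean=true_mean,
        subject_values=true_vals,
        null_means=null_means,
        p_uncorrected=p,
        ci95=ci,
        n_perm=n_perm,
        n_boot=n_boot,
    )


class GroupDecoding:
    """Group model: per-subject labeled patterns -> permutation inference.

    ``fit()`` runs the true decoding and the permutation/bootstrap machinery
    and returns a :class:`GroupInference`.
    """

    def __init__(self, subject_data, decode_fn):
        self.subject_data = subject_data
        self.decode_fn = decode_fn

    def fit(
        self,
        n_perm: int = 10_000,
        n_boot: int = 10_000,
        seed: int | np.random.Generator = 0,
    ) -> GroupInference:
        return group_permutation_test(
            self.subject_data, self.decode_fn, n_perm=n_perm, n_boot=n_boot, seed=seed
        )


def report_table(results: dict[str, GroupInference], alpha: float = 0.05) -> pd.DataFrame:
    """ROI-by-statistic table with FDR-adjusted p-values across ROIs."""
    names = list(results)
    ps = [results[n].p_uncorrected for n in names]
    adj = fdr_bh(ps)
    rows = []
    for name, p_adj in zip(names, adj):
        g = results[name]
        g.p_fdr = float(p_adj)
        rows.append(
            dict(
                roi=name,
                mean_accuracy=g.true_mean,
                ci_low=g.ci95[0],
                ci_high=g.ci95[1],
                p=g.p_uncorrected,
                p_fdr=g.p_fdr,
                significant=g.significant(alpha),
            )
        )
    return pd.DataFrame(rows)
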