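import numpy as np
import pytest

import betadecode as bd
from betadecode.decoding import extract_patterns


@pytest.fixture(scope="session")
def small_design():
    """4-run design with the standard trial structure."""
    return bd.make_design("sub-01", n_runs=4, seed=11)


@pytest.fixture(scope="session")
def small_grid():
    return bd.demo_grid((12, 12, 4))


@pytest.fixture(scope="session")
def small_masks(small_grid):
    rois = bd.demo_rois(small_grid, n_rois=3, radius_mm=4.5)
    return bd.roi_masks(rois, small_grid, report_overlap=False)


def balanced_labels(n_runs: int, conditions=bd.CONDITIONS):
    """Condition and run labels: one trial per condition per... two per run."""
    cond = np.array(
        [c for _ in range(n_runs) for c in list(conditions) * 2], dtype=object
    )
    run = np.repeat(np.arange(n_runs), 2 * len(conditions))
    return cond, run


def simulate_betas(
    sep: float,
    seed: int,
    grid,
    masks,
    signal_roi: str = "roi_1",
    n_runs: int = 4,
    contrast: str = "attention",
    noise_sd: float = 1.0,
):
    """Full simulate -> GLM path on the desk-scale layout; returns per-ROI
    beta-series patterns."""
    design = bd.make_design("sub", n_runs=n_runs, seed=seed)
    eff = bd.EffectSpec(
        pattern_separation={contrast: sep} if sep else {}, noise_sd=noise_sd
    )
    bold = bd.simulate_bold(
        design, grid, eff, signal_mask=masks[signal_roi], seed=seed + 10_000
    )
    fit_mask = bd.union_mask(masks.values())
    bs = bd.BetaSeriesGLM(bold, design, fit_mask).fit().beta_series
    return {name: extract_patterns(bs, m) for name, m in masks.items()}
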