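import numpy as np
import pandas as pd
import pytest

from reinstate.data_model import TRIAL_COLUMNS, VolumeGrid, validate_trial_table
from reinstate.synth import box_mask


def make_trials(phase: str, video_ids, runs=None, subject="sub-01",
                onset_step=50.0) -> pd.DataFrame:
    """Minimal valid trial table for one phase (helper for unit tests)."""
    video_ids = list(video_ids)
    if runs is None:
        runs = [3] * len(video_ids) if phase == "DelRet" else [1] * len(video_ids)
    rows = []
    for k, (v, r) in enumerate(zip(video_ids, runs)):
        is_ret = phase in ("ImRet", "DelRet")
        rows.append(dict(onset=4.0 + k * onset_step, duration=35.0,
                         subject_id=subject, phase=phase, run=r, video_id=v,
                         cue_onset=2.0 + k * onset_step if is_ret else np.nan,
                         vividness=4.0 if is_ret else np.nan,
                         retrieval_duration=35.0 if is_ret else np.nan))
    return validate_trial_table(pd.DataFrame(rows)[TRIAL_COLUMNS])


def day1_design_trials(phase: str, n_videos=24, n_runs=2, subject="sub-01"):
    """Phase trials for the 2-run Day-1 split (videos 1..n in run order)."""
    per = n_videos // n_runs
    vids, runs = [], []
    for r in range(1, n_runs + 1):
        vids += list(range((r - 1) * per + 1, r * per + 1))
        runs += [r] * per
    return make_trials(phase, vids, runs, subject=subject)


@pytest.fixture
def small_grid():
    return VolumeGrid((10, 10, 10), (3.0, 3.0, 3.0))


@pytest.fixture
def small_mask(small_grid):
    return box_mask(small_grid, (0, 0, 0), small_grid.shape)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_searchlight(patterns_a, patterns_b, w, spec):
    """Independent oracle: naive per-center, per-pair recomputation of the
    weighted sum of Fisher-z Pearson correlations."""
    from reinstate.rsa import sphere_neighborhood

    mask = patterns_a.mask
    flat = mask.flat_indices()
    col_of = {f: c for c, f in enumerate(flat)}
    out = np.full(mask.grid.shape, np.nan)
    ii, jj = np.nonzero(w.weights)
    for center in mask.indices:
        nb = sphere_neighborhood(center, spec, mask)
        if len(nb) < spec.min_voxels:
            continue
        cols = [col_of[np.ravel_multi_index(tuple(p), mask.grid.shape)]
                for p in nb]
        s = 0.0
        for i, j in zip(ii, jj):
            x = patterns_a.values[i, cols]
            y = patterns_b.values[j, cols]
            if x.std() == 0 or y.std() == 0:
                r = 0.0
            else:
                r = np.corrcoef(x, y)[0, 1]
            r = min(max(r, -(1 - 1e-7)), 1 - 1e-7)
            s += w.weights[i, j] * np.arctanh(r)
        out[tuple(center)] = s
    return out
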