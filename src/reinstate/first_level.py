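"""Per-trial first-level GLM: one regressor of interest per trial.

Each encoding/retrieval trial gets its own HRF-convolved boxcar (duration =
the video length or the self-paced retrieval window); each retrieval cue gets
a fixed 2 s regressor.  Nuisance columns are the vividness-rating events, six
motion series and a global white-matter drift series (used instead of
high-pass filtering), plus an intercept.  Ordinary least squares is fit per
voxel and each interest column's t statistic (beta / SE, residual df) becomes
that trial's pattern map.

A control variant excludes the first 12 s of every retrieval trial from its
regressor of interest (the excluded window is modeled by a separate
no-interest column), to rule out cue-driven pattern effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from nilearn.glm.first_level import compute_regressor

from .data_model import Mask, PatternSet

__all__ = [
    "RetrievalModelVariant",
    "DesignMatrix",
    "wm_drift_regressor",
    "build_design_matrix",
    "fit_trial_tmaps",
    "fit_run",
]

_EXCLUDE_WINDOW_S = 12.0
_RETRIEVAL_PHASES = ("ImRet", "DelRet")


@dataclass(frozen=True)
class RetrievalModelVariant:
    """``full_trial`` models each retrieval trial from its onset;
    ``exclude_first_12s`` starts the interest boxcar 12 s after onset and
    assigns the first 12 s to a separate no-interest column."""

    mode: str = "full_trial"

    def __post_init__(self) -> None:
        if self.mode not in ("full_trial", "exclude_first_12s"):
            raise ValueError(f"unknown variant {self.mode!r}")


def wm_drift_regressor(series: np.ndarray, wm_mask: Mask) -> np.ndarray:
    """Global white-matter drift: mean over WM voxels of each voxel's
    z-scored (over time) series.

    ``series`` is a 4D array on the mask's grid.  Zero-variance voxels are
    excluded with a warning; an effectively empty mask is an error.  The
    output has mean ~0 by construction.
    """
    if series.shape[:3] != wm_mask.grid.shape:
        raise ValueError("series grid does not match WM mask grid")
    data = series[wm_mask.voxels]  # (n_wm, T)
    sd = data.std(axis=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"wm_drift_regressor: {n_dropped} zero-variance WM "
                      "voxels excluded", stacklevel=2)
    if not keep.any():
        raise ValueError("all WM voxels have zero temporal variance")
    data = data[keep]
    z = (data - data.mean(axis=1, keepdims=True)) / sd[keep, None]
    return z.mean(axis=0)


def _convolved(onset: float, duration: float, frame_times: np.ndarray
               ) -> np.ndarray:
    reg, _ = compute_regressor(np.array([[onset], [duration], [1.0]]),
                               "glover", frame_times, oversampling=16)
    return reg.ravel()


@dataclass
class DesignMatrix:
    """Design matrix plus labels; ``interest`` flags columns whose t maps are
    returned (trial and cue regressors)."""

    matrix: np.ndarray
    labels: list[str]
    interest: np.ndarray       # bool per column
    trial_rows: pd.DataFrame   # one row per non-cue interest column, in order

    @property
    def n_interest(self) -> int:
        return int(self.interest.sum())


def build_design_matrix(trials: pd.DataFrame, frame_times: np.ndarray,
                        nuisance: dict | None = None,
                        variant: RetrievalModelVariant = RetrievalModelVariant(),
                        ) -> DesignMatrix:
    """One run's design: per-trial interest regressors, 2 s cue regressors,
    nuisance columns and an intercept.

    ``nuisance`` may carry ``motion`` (T x 6), ``wm_drift`` (T,) and
    ``rating_duration`` (seconds; rating events are placed at each retrieval
    trial's offset).  Under ``exclude_first_12s``, each retrieval trial's
    interest boxcar spans [onset+12, offset] and its first 12 s go into one
    shared no-interest column.
    """
    nuisance = nuisance or {}
    run_end = frame_times[-1]
    if (trials["onset"] > run_end).any():
        raise ValueError("trial onsets fall outside the run duration")
    cols, labels, interest = [], [], []
    exclude = variant.mode == "exclude_first_12s"
    excluded_window = np.zeros_like(frame_times)
    trial_rows = []
    for _, row in trials.iterrows():
        onset, dur, ph = float(row["onset"]), float(row["duration"]), row["phase"]
        if exclude and ph in _RETRIEVAL_PHASES:
            w = min(_EXCLUDE_WINDOW_S, dur)
            excluded_window += _convolved(onset, w, frame_times)
            onset_i, dur_i = onset + w, max(dur - w, 0.0)
        else:
            onset_i, dur_i = onset, dur
        cols.append(_convolved(onset_i, dur_i, frame_times))
        labels.append(f"{ph}_video{int(row['video_id']):02d}")
        interest.append(True)
        trial_rows.append(row)
        if ph in _RETRIEVAL_PHASES and np.isfinite(row.get("cue_onset", np.nan)):
            cols.append(_convolved(float(row["cue_onset"]), 2.0, frame_times))
            labels.append(f"cue_video{int(row['video_id']):02d}")
            interest.append(True)
            trial_rows.append(None)
    n_noncue_interest = sum(r is not None for r in trial_rows)
    if exclude and excluded_window.any():
        cols.append(excluded_window)
        labels.append("retrieval_first12s")
        interest.append(False)
    rating_dur = float(nuisance.get("rating_duration", 4.0))
    rating = np.zeros_like(frame_times)
    ret = trials[trials["phase"].isin(_RETRIEVAL_PHASES)]
    for _, row in ret.iterrows():
        rating += _convolved(float(row["onset"]) + float(row["duration"]),
                             rating_dur, frame_times)
    if rating.any():
        cols.append(rating)
        labels.append("rating")
        interest.append(False)
    motion = nuisance.get("motion")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != len(frame_times):
            raise ValueError("motion series length != number of volumes")
        for k in range(motion.shape[1]):
            cols.append(motion[:, k] - motion[:, k].mean())
            labels.append(f"motion{k + 1}")
            interest.append(False)
    wm = nuisance.get("wm_drift")
    if wm is not None:
        wm = np.asarray(wm, dtype=float)
        if wm.shape[0] != len(frame_times):
            raise ValueError("wm drift length != number of volumes")
        cols.append(wm - wm.mean())
        labels.append("wm_drift")
        interest.append(False)
    cols.append(np.ones_like(frame_times))
    labels.append("intercept")
    interest.append(False)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the error message
        _, r = np.linalg.qr(X)
        dep = [labels[i] for i in range(X.shape[1])
               if abs(r[i, i]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {dep or 'unidentified'}")
    rows = pd.DataFrame([r for r in trial_rows if r is not None])
    assert len(rows) == n_noncue_interest
    return DesignMatrix(X, labels, np.asarray(interest, bool),
                        rows.reset_index(drop=True))


def fit_trial_tmaps(series: np.ndarray, design: DesignMatrix, mask: Mask,
                    drop_initial: int = 0, include_cues: bool = False
                    ) -> PatternSet:
    """OLS per voxel; per interest column t = beta / SE(beta), residual
    df = volumes - columns.  Returns one t-map row per (non-cue) trial.

    ``drop_initial`` discards leading volumes (T1 equilibration) before the
    fit; the design must already be built on the retained frame times.
    Voxels with zero residual variance get t = +-inf (flagged, not raised).
    """
    if series.shape[:3] != mask.grid.shape:
        raise ValueError("series grid does not match mask grid")
    Y = series[mask.voxels][:, drop_initial:].T  # (T, n_vox)
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"{Y.shape[0]} volumes vs {X.shape[0]} design rows")
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    which = np.flatnonzero(design.interest)
    if not include_cues:
        which = np.array([i for i in which
                          if not design.labels[i].startswith("cue_")])
    se = np.sqrt(np.outer(np.diag(xtx_inv)[which], sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[which] / se
    t[np.isnan(t)] = 0.0  # 0/0: no signal, no noise
    return PatternSet(mask.grid, mask, design.trial_rows.copy(), t)


def fit_run(run, variant: RetrievalModelVariant = RetrievalModelVariant(),
            drop_initial: int = 5, rating_duration: float = 4.0) -> PatternSet:
    """Convenience wrapper: full first-level fit of a synthetic
    :class:`~reinstate.synth.TimeseriesRun` (WM drift regressor computed from
    the run's own WM mask, motion series from its nuisance truth)."""
    retained = run.series[..., drop_initial:]
    frame_times = np.arange(retained.shape[-1]) * _tr_of(run)
    wm = wm_drift_regressor(retained, run.wm_mask)
    design = build_design_matrix(
        run.trials, frame_times,
        nuisance={"motion": run.motion[drop_initial:], "wm_drift": wm,
                  "rating_duration": rating_duration},
        variant=variant)
    brain = run.injected_patterns.mask
    return fit_trial_tmaps(run.series, design, brain, drop_initial=drop_initial)


def _tr_of(run) -> float:
    return getattr(run, "tr", 2.62)
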