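"""Synthetic multi-subject study generator with known reinstatement truth.

The generator emulates a naturalistic video-memory design: each subject
watches 24 short videos (encoding, Enc), silently retrieves them immediately
(ImRet) — both split over two Day-1 runs of 12 videos — and retrieves all 24
again a week later in one run (DelRet).  It produces either direct per-trial
pattern maps (the fast path used for RSA testing) or full BOLD-like time
series to exercise the first-level GLM.

Latent pattern model (per effect region)
----------------------------------------
Each video v has a unit-variance Gaussian latent pattern; a fraction
``shared_fraction`` of its variance is common across subjects.  An observed
trial pattern in the region is

    x = sqrt(c) * common + sqrt(rho) * latent_v + sqrt(1 - c - rho) * noise

where ``common`` is a video-unspecific component shared by all of the
subject's trials in the region (it produces a nonzero different-video
correlation, as real data show) and all three components are unit-variance
Gaussian.  Cross-phase correlations are then c for different videos and
c + rho for the same video, so the Fisher-z gap is controlled analytically:

    delta_z_same = atanh(c + rho) - atanh(c),   c = tanh(base_z_diff).

Behavior coupling adds ``behavior_coupling * (relative memory score)`` to the
same-video Fisher-z target per subject and video.  Outside effect regions,
patterns are pure N(0, 1) noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .data_model import (Mask, PatternSet, TRIAL_COLUMNS, VolumeGrid,
                         validate_trial_table)

__all__ = [
    "EffectSpec",
    "GeneratorConfig",
    "StudyData",
    "default_brain_mask",
    "ellipsoid_mask",
    "box_mask",
    "generate_behavior",
    "generate_pattern_study",
    "generate_timeseries_study",
]

_MAX_RHO = 1.0 - 1e-6


def ellipsoid_mask(grid: VolumeGrid, center=None, semi_axes=None) -> Mask:
    """Ellipsoidal mask in voxel-index units (a desk-scale 'brain')."""
    shape = np.asarray(grid.shape, dtype=float)
    center = shape / 2 - 0.5 if center is None else np.asarray(center, float)
    semi_axes = shape / 2 - 1 if semi_axes is None else np.asarray(semi_axes, float)
    ix = np.indices(grid.shape).astype(float)
    d = sum(((ix[k] - center[k]) / semi_axes[k]) ** 2 for k in range(3))
    return Mask(grid, d <= 1.0)


def box_mask(grid: VolumeGrid, lo, hi) -> Mask:
    """Axis-aligned box mask; ``lo`` inclusive, ``hi`` exclusive voxel indices."""
    vox = np.zeros(grid.shape, dtype=bool)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    vox[sl] = True
    return Mask(grid, vox)


def default_brain_mask(grid: VolumeGrid) -> Mask:
    return ellipsoid_mask(grid)


@dataclass
class EffectSpec:
    """Ground-truth reinstatement effect within one region.

    Parameters
    ----------
    region : Mask
        Where the effect lives (must lie within the brain mask).
    delta_z_same : float
        Target mean excess Fisher-z similarity of same-video over
        different-video cross-phase pairs.  A scalar applies to all three
        phase pairs.
    base_z_diff : float
        Target Fisher-z of different-video cross-phase correlations (a
        video-unspecific component; 0 for a pure video-specific effect).
    behavior_coupling : float
        Slope of the same-video Fisher-z target on the subject's centered
        (relative) memory-detail score, in z units per detail point.
    shared_fraction : float
        Portion of each video's latent pattern variance common across
        subjects (drives inter-subject RSA effects).
    """

    region: Mask
    delta_z_same: float = 0.0
    base_z_diff: float = 0.0
    behavior_coupling: float = 0.0
    shared_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_z_same < 0:
            raise ValueError("delta_z_same must be >= 0")
        if self.behavior_coupling < 0:
            raise ValueError("behavior_coupling must be >= 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        c = np.tanh(self.base_z_diff)
        if np.tanh(self.base_z_diff + self.delta_z_same) >= _MAX_RHO:
            raise ValueError("delta_z_same implies correlation >= 1")
        if c < 0:
            raise ValueError("base_z_diff must be >= 0")


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters for the synthetic generator.

    Defaults follow the emulated design: 21 subjects, 24 videos split over
    two Day-1 runs of 12 plus one Day-8 run of 24, TR 2.62 s, video durations
    29-48 s, 12 s ISI, 2 s retrieval cues, self-paced retrieval in (20, 55) s
    (mean 35 s, SD 8 s), memory-detail scores with mean 11.5 and SD 2.7 in
    0.5-point steps, and a mean vividness drop of 0.7 (scale 1-6) from
    immediate to delayed retrieval.
    """

    n_subjects: int = 21
    n_videos: int = 24
    n_day1_runs: int = 2
    grid: VolumeGrid | None = None
    brain_mask: Mask | None = None
    tr: float = 2.62
    video_duration_range: tuple[float, float] = (29.0, 48.0)
    isi: float = 12.0
    cue_duration: float = 2.0
    retrieval_mean: float = 35.0
    retrieval_sd: float = 8.0
    retrieval_window: tuple[float, float] = (20.5, 54.5)
    rating_duration: float = 4.0
    noise_sd: float = 1.0
    effects: list[EffectSpec] = field(default_factory=list)
    behavior_mean_details: float = 11.5
    behavior_sd: float = 2.7
    vividness_mean_imret: float = 4.2
    vividness_subject_sd: float = 0.4
    vividness_drop: float = 0.7
    vividness_drop_sd: float = 0.4
    vividness_score_coupling: float = 0.26
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid is None:
            self.grid = VolumeGrid((24, 28, 24), (3.0, 3.0, 3.0),
                                   space_label="common")
        if self.brain_mask is None:
            self.brain_mask = default_brain_mask(self.grid)
        if self.n_videos % self.n_day1_runs:
            raise ValueError("n_videos must divide evenly across Day-1 runs")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for d in (self.tr, self.isi, self.cue_duration, *self.video_duration_range):
            if d <= 0:
                raise ValueError("all durations must be positive")
        for eff in self.effects:
            if not self.brain_mask.contains(eff.region):
                raise ValueError("effect region extends outside the brain mask")

    @property
    def subjects(self) -> list[str]:
        return [f"sub-{i + 1:02d}" for i in range(self.n_subjects)]


@dataclass
class StudyData:
    """A generated study: per-(subject, phase) pattern sets, behavior, truth."""

    config: GeneratorConfig
    pattern_sets: dict[tuple[str, str], PatternSet]
    behavior: pd.DataFrame
    truth: dict

    def phase(self, subject: str, phase: str) -> PatternSet:
        return self.pattern_sets[(subject, phase)]


# ---------------------------------------------------------------------------
# Trial timing
# ---------------------------------------------------------------------------

def _draw_retrieval_durations(cfg: GeneratorConfig, rng, n: int) -> np.ndarray:
    lo, hi = cfg.retrieval_window
    a = (lo - cfg.retrieval_mean) / cfg.retrieval_sd
    b = (hi - cfg.retrieval_mean) / cfg.retrieval_sd
    return truncnorm.rvs(a, b, loc=cfg.retrieval_mean, scale=cfg.retrieval_sd,
                         size=n, random_state=rng)


def _schedule_subject(cfg: GeneratorConfig, rng, subject: str,
                      behavior_sub: pd.DataFrame) -> pd.DataFrame:
    """Trial table for one subject: Enc + ImRet per Day-1 run, DelRet in run 3."""
    n_per_run = cfg.n_videos // cfg.n_day1_runs
    order = rng.permutation(cfg.n_videos) + 1
    lo, hi = cfg.video_duration_range
    video_dur = {v: round(float(rng.uniform(lo, hi)), 1)
                 for v in range(1, cfg.n_videos + 1)}
    viv = behavior_sub.set_index("video_id")
    rows = []
    for run in range(1, cfg.n_day1_runs + 1):
        vids = order[(run - 1) * n_per_run: run * n_per_run]
        t = 4.0
        for v in vids:  # encoding block
            rows.append(dict(onset=t, duration=video_dur[v], subject_id=subject,
                             phase="Enc", run=run, video_id=int(v),
                             cue_onset=np.nan, vividness=np.nan,
                             retrieval_duration=np.nan))
            t += video_dur[v] + cfg.isi
        ret_dur = _draw_retrieval_durations(cfg, rng, len(vids))
        for v, rd in zip(vids, ret_dur):  # immediate-retrieval block
            cue = t
            onset = cue + cfg.cue_duration
            rows.append(dict(onset=onset, duration=round(float(rd), 1),
                             subject_id=subject, phase="ImRet", run=run,
                             video_id=int(v), cue_onset=cue,
                             vividness=float(viv.loc[int(v), "vividness_imret"]),
                             retrieval_duration=round(float(rd), 1)))
            t = onset + round(float(rd), 1) + cfg.rating_duration + cfg.isi
    t = 4.0
    ret_dur = _draw_retrieval_durations(cfg, rng, cfg.n_videos)
    for v, rd in zip(rng.permutation(cfg.n_videos) + 1, ret_dur):  # Day 8
        cue = t
        onset = cue + cfg.cue_duration
        rows.append(dict(onset=onset, duration=round(float(rd), 1),
                         subject_id=subject, phase="DelRet", run=3,
                         video_id=int(v), cue_onset=cue,
                         vividness=float(viv.loc[int(v), "vividness_delret"]),
                         retrieval_duration=round(float(rd), 1)))
        t = onset + round(float(rd), 1) + cfg.rating_duration + cfg.isi
    return validate_trial_table(pd.DataFrame(rows)[TRIAL_COLUMNS])


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def generate_behavior(config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Subject x video behavior table: detail scores, relative scores,
    vividness (ImRet and DelRet) and retrieval durations.

    Detail scores are drawn around ``behavior_mean_details`` with SD
    ``behavior_sd``, rounded to 0.5 steps and floored at 0 (free-recall
    detail marks of 0/0.5/1 sum to such totals).  Vividness is positively
    coupled to the subject's within-subject score profile and drops by
    ``vividness_drop`` on average from immediate to delayed retrieval.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_s, n_v = config.n_subjects, config.n_videos
    raw = rng.normal(config.behavior_mean_details, config.behavior_sd, (n_s, n_v))
    scores = np.maximum(np.round(raw * 2) / 2, 0.0)
    relative = scores - scores.mean(axis=0, keepdims=True)
    base = rng.normal(config.vividness_mean_imret, config.vividness_subject_sd, n_s)
    score_std = (scores - scores.mean(axis=1, keepdims=True))
    sd = score_std.std(axis=1, keepdims=True)
    score_std = score_std / np.where(sd > 0, sd, 1.0)
    k = config.vividness_score_coupling
    viv_im = base[:, None] + k * score_std + rng.normal(0, 0.4, (n_s, n_v))
    drop = rng.normal(config.vividness_drop, config.vividness_drop_sd, n_s)
    viv_del = viv_im - drop[:, None] + rng.normal(0, 0.3, (n_s, n_v))
    viv_im = np.clip(viv_im, 1.0, 6.0)
    viv_del = np.clip(viv_del, 1.0, 6.0)
    dur_im = _draw_retrieval_durations(config, rng, n_s * n_v).reshape(n_s, n_v)
    dur_del = _draw_retrieval_durations(config, rng, n_s * n_v).reshape(n_s, n_v)
    recs = []
    for i, sub in enumerate(config.subjects):
        for v in range(n_v):
            recs.append(dict(subject_id=sub, video_id=v + 1,
                             detail_score=scores[i, v],
                             relative_score=relative[i, v],
                             vividness_imret=viv_im[i, v],
                             vividness_delret=viv_del[i, v],
                             retrieval_duration_imret=dur_im[i, v],
                             retrieval_duration_delret=dur_del[i, v]))
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Pattern-level study
# ---------------------------------------------------------------------------

def _region_columns(brain: Mask, region: Mask) -> np.ndarray:
    return np.isin(brain.flat_indices(), region.flat_indices())


def generate_pattern_study(config: GeneratorConfig) -> StudyData:
    """Generate per-trial pattern maps for every subject and phase.

    Within each effect region, same-video cross-phase pairs share a latent
    component scaled so the expected same-minus-different Fisher-z gap equals
    ``delta_z_same`` (plus any behavior coupling); outside effect regions
    patterns are pure noise.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    behavior = generate_behavior(config, rng)
    brain = config.brain_mask
    n_vox = brain.n_voxels
    rel = behavior.pivot(index="subject_id", columns="video_id",
                         values="relative_score").loc[config.subjects].to_numpy()

    # Precompute per-effect component banks.
    effect_state = []
    shared_rng = np.random.default_rng(config.seed + 1)
    for eff in config.effects:
        cols = _region_columns(brain, eff.region)
        k = int(cols.sum())
        shared_latents = shared_rng.standard_normal((config.n_videos, k))
        shared_common = shared_rng.standard_normal(k)
        effect_state.append((eff, cols, shared_latents, shared_common))

    pattern_sets: dict[tuple[str, str], PatternSet] = {}
    truth_strength = np.zeros((config.n_subjects, config.n_videos))
    for i, sub in enumerate(config.subjects):
        sub_beh = behavior[behavior["subject_id"] == sub]
        trials = _schedule_subject(config, rng, sub, sub_beh)
        phase_values = {ph: rng.standard_normal(
            (int((trials["phase"] == ph).sum()), n_vox)) for ph in
            ("Enc", "ImRet", "DelRet")}
        for eff, cols, shared_latents, shared_common in effect_state:
            k = int(cols.sum())
            g = eff.shared_fraction
            own_latents = rng.standard_normal((config.n_videos, k))
            own_common = rng.standard_normal(k)
            latents = np.sqrt(g) * shared_latents + np.sqrt(1 - g) * own_latents
            common = np.sqrt(g) * shared_common + np.sqrt(1 - g) * own_common
            c = np.tanh(eff.base_z_diff)
            z_same = (eff.base_z_diff + eff.delta_z_same
                      + eff.behavior_coupling * rel[i])  # per video
            rho = np.clip(np.tanh(np.maximum(z_same, 0.0)) - c, 0.0, _MAX_RHO - c)
            if eff.behavior_coupling > 0:
                truth_strength[i] += np.arctanh(c + rho) - np.arctanh(c)
            for ph in ("Enc", "ImRet", "DelRet"):
                ph_trials = trials[trials["phase"] == ph].reset_index(drop=True)
                vals = phase_values[ph]
                for t_idx, vid in enumerate(ph_trials["video_id"]):
                    r = rho[vid - 1]
                    vals[t_idx, cols] = (np.sqrt(c) * common
                                         + np.sqrt(r) * latents[vid - 1]
                                         + np.sqrt(max(1 - c - r, 0.0))
                                         * vals[t_idx, cols])
        for ph in ("Enc", "ImRet", "DelRet"):
            ph_trials = trials[trials["phase"] == ph].reset_index(drop=True)
            pattern_sets[(sub, ph)] = PatternSet(config.grid, brain, ph_trials,
                                                 phase_values[ph])
    truth = {
        "effects": [dict(delta_z_same=e.delta_z_same, base_z_diff=e.base_z_diff,
                         behavior_coupling=e.behavior_coupling,
                         shared_fraction=e.shared_fraction,
                         region_voxels=int(e.region.n_voxels))
                    for e in config.effects],
        "region_flat_indices": [e.region.flat_indices().tolist()
                                for e in config.effects],
        "per_subject_video_strength": truth_strength.tolist(),
        "seed": config.seed,
    }
    return StudyData(config, pattern_sets, behavior, truth)


# ---------------------------------------------------------------------------
# Time-series study
# ---------------------------------------------------------------------------

@dataclass
class TimeseriesRun:
    """One run's BOLD-like series plus the truth needed to check the GLM."""

    subject_id: str
    run: int
    series: np.ndarray          # grid.shape + (n_volumes,)
    trials: pd.DataFrame        # onsets relative to post-discard series
    motion: np.ndarray          # n_volumes x 6
    drift: np.ndarray           # n_volumes (the injected global drift)
    wm_mask: Mask
    injected_patterns: PatternSet
    tr: float = 2.62
    drop_initial: int = 5

    @property
    def n_volumes(self) -> int:
        return self.series.shape[-1]


def _smooth_series(rng, n: int, scale: float) -> np.ndarray:
    x = np.cumsum(rng.standard_normal(n))
    x -= x.mean()
    s = x.std()
    return x / s * scale if s > 0 else x


def generate_timeseries_study(config: GeneratorConfig,
                              subjects: list[str] | None = None,
                              drop_initial: int = 5,
                              drift_amplitude: float = 1.0,
                              motion_amplitude: float = 0.3,
                              ) -> tuple[list[TimeseriesRun], StudyData]:
    """HRF-convolved BOLD-like series carrying the pattern study's latent
    structure, plus global white-matter drift, motion-correlated nuisance and
    Gaussian noise of SD ``config.noise_sd``.

    The emitted trial tables use onsets relative to the retained series (the
    first ``drop_initial`` volumes are baseline padding the GLM discards).
    Returns the runs and the underlying pattern study (whose per-trial
    patterns are the injected spatial truth).
    """
    from nilearn.glm.first_level import compute_regressor

    study = generate_pattern_study(config)
    rng = np.random.default_rng(config.seed + 2)
    subjects = config.subjects if subjects is None else subjects
    brain = config.brain_mask
    wm = Mask(config.grid, ~brain.voxels) if (~brain.voxels).any() else None
    if wm is None:
        raise ValueError("grid has no out-of-brain voxels to host a WM mask")
    runs: list[TimeseriesRun] = []
    for sub in subjects:
        trials_all = pd.concat([study.phase(sub, ph).trials
                                for ph in ("Enc", "ImRet", "DelRet")],
                               ignore_index=True)
        for run in sorted(trials_all["run"].unique()):
            tr_run = trials_all[trials_all["run"] == run].reset_index(drop=True)
            end = float((tr_run["onset"] + tr_run["duration"]).max()) + 24.0
            n_vol = int(np.ceil(end / config.tr)) + drop_initial
            frame_times = (np.arange(n_vol) - drop_initial) * config.tr
            vol_shape = config.grid.shape + (n_vol,)
            series = rng.normal(0.0, config.noise_sd, vol_shape)
            flat = series.reshape(-1, n_vol)
            brain_flat = brain.flat_indices()
            pat_rows = []
            for _, row in tr_run.iterrows():
                ph, vid = row["phase"], row["video_id"]
                ps = study.phase(sub, ph)
                k = int(ps.trials.index[ps.trials["video_id"] == vid][0])
                pat_rows.append(ps.values[k])
                reg, _ = compute_regressor(
                    np.array([[row["onset"]], [row["duration"]], [1.0]]),
                    "glover", frame_times, oversampling=16)
                flat[brain_flat] += np.outer(ps.values[k], reg.ravel())
            drift = _smooth_series(rng, n_vol, drift_amplitude)
            flat += drift[None, :]  # global drift hits every voxel
            motion = np.column_stack(
                [_smooth_series(rng, n_vol, 1.0) for _ in range(6)])
            couplings = rng.normal(0, motion_amplitude,
                                   (flat.shape[0], 6)) * config.noise_sd
            flat += couplings @ motion.T
            pat = PatternSet(config.grid, brain,
                             tr_run.copy(), np.asarray(pat_rows))
            runs.append(TimeseriesRun(sub, int(run), series, tr_run, motion,
                                      drift, wm, pat, tr=config.tr,
                                      drop_initial=drop_initial))
    return runs, study


# ---------------------------------------------------------------------------
# Serialization used by the CLI
# ---------------------------------------------------------------------------

def write_study(study: StudyData, out_dir: str | Path) -> None:
    """Write a pattern study as NIfTI volumes, TSV tables and truth JSON."""
    from .data_model import write_mask, write_pattern_set
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (sub, ph), ps in study.pattern_sets.items():
        write_pattern_set(ps, out / sub / ph)
    study.behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    write_mask(study.config.brain_mask, out / "brain_mask.nii.gz")
    (out / "ground_truth.json").write_text(json.dumps(study.truth, indent=1))
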