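"""Inter-subject RSA: shared representations across participants.

Each subject's per-video pattern from phase A is correlated (searchlight)
with the leave-one-out average of all *other* subjects' patterns for the same
video from phase B.  Patterns are first smoothed with a 6 mm FWHM Gaussian
kernel (renormalized within the mask so edge voxels are not diluted), since
averaging across brains only makes sense at a coarser spatial scale.  The
weight machinery is shared with the within-subject RSAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data_model import Mask, PatternSet, StatMap
from .rsa import SearchlightSpec, WeightMatrix, neighborhood_matrix, searchlight_rsa

__all__ = [
    "SmoothingSpec",
    "smooth_volume",
    "smooth_pattern_set",
    "leave_one_out_average",
    "intersubject_searchlight",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class SmoothingSpec:
    """Gaussian smoothing kernel width (FWHM, mm); 0 disables smoothing."""

    fwhm_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("FWHM must be >= 0")

    def sigma_voxels(self, voxel_size) -> tuple[float, ...]:
        return tuple(self.fwhm_mm / _FWHM_TO_SIGMA / v for v in voxel_size)


def smooth_volume(volume: np.ndarray, spec: SmoothingSpec, mask: Mask
                  ) -> np.ndarray:
    """Mask-renormalized Gaussian smoothing of one 3D volume.

    Data outside the mask are treated as missing: the masked volume and the
    mask itself are both smoothed and their ratio taken, so values near the
    mask edge are proper weighted averages of in-mask neighbors rather than
    being diluted toward zero.
    """
    if spec.fwhm_mm == 0:
        return volume.copy()
    sigma = spec.sigma_voxels(mask.grid.voxel_size)
    filled = np.where(mask.voxels, volume, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma)
    den = ndimage.gaussian_filter(mask.voxels.astype(float), sigma=sigma)
    out = np.full_like(volume, np.nan, dtype=float)
    inm = mask.voxels
    out[inm] = num[inm] / den[inm]
    return out


def smooth_pattern_set(patterns: PatternSet, spec: SmoothingSpec) -> PatternSet:
    """Smooth every trial pattern of a :class:`PatternSet` within its mask."""
    if spec.fwhm_mm == 0:
        return patterns
    vols = patterns.unmask(fill=0.0)
    out = np.empty_like(patterns.values)
    for i in range(patterns.n_trials):
        out[i] = smooth_volume(vols[i], spec, patterns.mask)[patterns.mask.voxels]
    return PatternSet(patterns.grid, patterns.mask, patterns.trials.copy(), out)


def leave_one_out_average(pattern_sets: dict[str, PatternSet],
                          held_out_subject: str) -> PatternSet:
    """Voxelwise mean pattern over all subjects except ``held_out_subject``.

    All pattern sets must be on one grid/mask and hold the same videos (rows
    are matched by video id).  Requires at least 3 subjects so the average
    spans at least 2.
    """
    if len(pattern_sets) < 3:
        raise ValueError("leave-one-out averaging needs at least 3 subjects")
    if held_out_subject not in pattern_sets:
        raise KeyError(held_out_subject)
    ref = pattern_sets[held_out_subject]
    order = ref.trials["video_id"].to_numpy()
    acc = np.zeros((len(order), ref.values.shape[1]))
    n = 0
    for sub, ps in pattern_sets.items():
        if sub == held_out_subject:
            continue
        if not ps.grid.matches(ref.grid):
            raise ValueError("pattern sets on different grids")
        vid_to_row = {v: k for k, v in enumerate(ps.trials["video_id"])}
        rows = [vid_to_row[v] for v in order]
        acc += ps.values[rows]
        n += 1
    return PatternSet(ref.grid, ref.mask, ref.trials.copy(), acc / n)


def intersubject_searchlight(pattern_sets_a: dict[str, PatternSet],
                             pattern_sets_b: dict[str, PatternSet],
                             make_weights,
                             spec: SearchlightSpec = SearchlightSpec(),
                             smoothing: SmoothingSpec = SmoothingSpec(),
                             ) -> dict[str, StatMap]:
    """Per-subject inter-subject searchlight maps.

    For each subject s: smooth s's phase-A patterns and every other subject's
    phase-B patterns, average the latter leaving s out, and run the standard
    searchlight between s's patterns and the average.  ``make_weights`` is
    called as ``make_weights(trials_a, trials_b)`` and must return a
    :class:`WeightMatrix` (the same contrast builders as the within-subject
    RSAs apply).
    """
    subjects = list(pattern_sets_a)
    if set(subjects) != set(pattern_sets_b):
        raise ValueError("phase A and B cover different subjects")
    sm_a = {s: smooth_pattern_set(ps, smoothing)
            for s, ps in pattern_sets_a.items()}
    sm_b = {s: smooth_pattern_set(ps, smoothing)
            for s, ps in pattern_sets_b.items()}
    any_ps = next(iter(sm_a.values()))
    nbm = neighborhood_matrix(any_ps.mask, spec)
    maps: dict[str, StatMap] = {}
    for s in subjects:
        loo = leave_one_out_average(sm_b, s)
        w = make_weights(sm_a[s].trials, loo.trials)
        if not isinstance(w, WeightMatrix):
            raise TypeError("make_weights must return a WeightMatrix")
        maps[s] = searchlight_rsa(sm_a[s], loo, w, spec, nbm=nbm)
    return maps
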