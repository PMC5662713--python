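"""Group-level inference on subject statistic maps.

One-sample and paired t maps, cluster-defining thresholding, and cluster-
extent family-wise-error correction by sign-flip permutation: under the null
that each subject's map is symmetrically distributed around zero, flipping
the sign of whole subject maps is an exact permutation scheme, and the
distribution of the maximum supra-threshold cluster size across flips gives
FWE-corrected cluster p values.  This replaces parametric random-field
cluster correction with a distribution-free equivalent.  An optional ROI
restricts both thresholding and the permutation maxima (small-volume
correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .data_model import Mask, StatMap

__all__ = [
    "one_sample_t_map",
    "paired_t_map",
    "ClusterConfig",
    "Cluster",
    "ClusterResult",
    "cluster_fwe",
    "interaction_anova_2x3",
]

_CONNECTIVITY = {6: ndimage.generate_binary_structure(3, 1),
                 18: ndimage.generate_binary_structure(3, 2),
                 26: ndimage.generate_binary_structure(3, 3)}


def _stack(maps: list[StatMap]) -> tuple[np.ndarray, StatMap]:
    if len(maps) < 2:
        raise ValueError("need at least 2 subject maps")
    g = maps[0].grid
    for m in maps[1:]:
        if not m.grid.matches(g):
            raise ValueError("subject maps on different grids")
    return np.stack([m.values for m in maps]), maps[0]


def one_sample_t_map(subject_maps: list[StatMap]) -> StatMap:
    """Voxelwise one-sample t against zero; df = n - 1.

    NaN wherever any subject is NaN; voxels with zero between-subject
    variance but nonzero mean are flagged +-inf.
    """
    data, first = _stack(subject_maps)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a one-sample t map")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = (sd == 0) & np.isfinite(mean)
    with np.errstate(invalid="ignore"):
        t[zero_var] = np.sign(mean[zero_var]) * np.inf
    t[zero_var & (mean == 0)] = 0.0
    return StatMap(first.grid, t, "t", df=n - 1)


def paired_t_map(maps_a: list[StatMap], maps_b: list[StatMap]) -> StatMap:
    """Paired t map = one-sample t of the per-subject differences."""
    if len(maps_a) != len(maps_b):
        raise ValueError("paired t requires the same subjects in both lists")
    diffs = [StatMap(a.grid, a.values - b.values, "searchlight_sum")
             for a, b in zip(maps_a, maps_b)]
    return one_sample_t_map(diffs)


@dataclass(frozen=True)
class ClusterConfig:
    """Cluster-extent FWE parameters.

    ``cdt_p`` is the voxelwise cluster-defining p (one-tailed positive by
    default; ``two_sided`` thresholds |t|), ``fwe_p`` the family-wise alpha,
    ``connectivity`` the 3D neighbor rule for labeling.
    """

    cdt_p: float = 0.001
    fwe_p: float = 0.05
    connectivity: int = 18
    n_permutations: int = 5000
    two_sided: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.connectivity not in _CONNECTIVITY:
            raise ValueError("connectivity must be 6, 18 or 26")
        if not 0 < self.cdt_p < 1 or not 0 < self.fwe_p < 1:
            raise ValueError("p thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class Cluster:
    peak_voxel: tuple[int, int, int]
    peak_t: float
    size: int
    p_fwe: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: StatMap
    t_threshold: float
    config: ClusterConfig
    null_max_sizes: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_fwe < self.config.fwe_p]

    def table(self) -> pd.DataFrame:
        grid = self.t_map.grid
        rows = []
        for c in self.clusters:
            world = grid.affine @ np.array([*c.peak_voxel, 1.0])
            rows.append(dict(x=world[0], y=world[1], z=world[2],
                             peak_t=c.peak_t, size=c.size, p_fwe=c.p_fwe))
        return pd.DataFrame(rows, columns=["x", "y", "z", "peak_t", "size",
                                           "p_fwe"])


def _cluster_sizes(supra: np.ndarray, structure: np.ndarray
                   ) -> tuple[np.ndarray, int, np.ndarray]:
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return labels, 0, np.zeros(0, dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, n, sizes


def _sign_matrix(n: int, n_permutations: int, seed: int) -> np.ndarray:
    """All 2^n sign patterns when feasible, else seeded random draws
    (identity included first so the observed statistic is in its own null)."""
    if 2 ** n <= n_permutations:
        bits = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1)
        return 1.0 - 2.0 * bits
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    signs[0] = 1.0
    return signs


def cluster_fwe(subject_maps: list[StatMap], config: ClusterConfig = ClusterConfig(),
                roi: Mask | None = None) -> ClusterResult:
    """Cluster-extent FWE correction of a one-sample group test by sign-flip
    permutation of whole subject maps.

    Observed clusters are connected supra-threshold components of the group
    t map at the cluster-defining threshold; the null distribution of the
    maximum cluster size comes from random sign flips.  Corrected p = fraction
    of permutation maxima >= the observed size.  With ``roi``, thresholding
    and maxima are restricted to the ROI (small-volume correction); an empty
    supra-threshold set returns an empty (not erroneous) result.
    """
    import warnings

    data, first = _stack(subject_maps)
    n = data.shape[0]
    if n < 6:
        warnings.warn("cluster_fwe with fewer than 6 subjects: the sign-flip "
                      "null has limited resolution", stacklevel=2)
    df = n - 1
    t_obs_map = one_sample_t_map(subject_maps)
    analysis = np.all(np.isfinite(data), axis=0)
    if roi is not None:
        if not first.grid.matches(roi.grid):
            raise ValueError("ROI grid differs from map grid")
        analysis &= roi.voxels
    if config.two_sided:
        t_thr = stats.t.ppf(1 - config.cdt_p / 2, df)
    else:
        t_thr = stats.t.ppf(1 - config.cdt_p, df)
    structure = _CONNECTIVITY[config.connectivity]

    flat = data.reshape(n, -1)[:, analysis.ravel()]
    v = flat.shape[1]
    sumsq = (flat ** 2).sum(axis=0)
    signs = _sign_matrix(n, config.n_permutations, config.seed)
    n_perm = signs.shape[0]
    max_sizes = np.zeros(n_perm, dtype=int)
    supra_vol = np.zeros(first.grid.shape, dtype=bool)
    chunk = max(1, int(2e7 // max(v, 1)))
    for start in range(0, n_perm, chunk):
        s = signs[start:start + chunk]
        mean_p = s @ flat / n
        var_p = (sumsq[None, :] - n * mean_p ** 2) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_p = mean_p / np.sqrt(var_p / n)
        stat = np.abs(t_p) if config.two_sided else t_p
        supra = stat > t_thr
        for k in range(supra.shape[0]):
            if not supra[k].any():
                continue
            supra_vol[:] = False
            supra_vol[analysis] = supra[k]
            _, n_cl, sizes = _cluster_sizes(supra_vol, structure)
            if n_cl:
                max_sizes[start + k] = sizes.max()

    t_obs = np.where(analysis, t_obs_map.values, np.nan)
    stat_obs = np.abs(t_obs) if config.two_sided else t_obs
    with np.errstate(invalid="ignore"):
        supra_obs = stat_obs > t_thr
    labels, n_cl, sizes = _cluster_sizes(supra_obs, structure)
    clusters = []
    for lab in range(1, n_cl + 1):
        in_cl = labels == lab
        vals = np.where(in_cl, stat_obs, -np.inf)
        peak = np.unravel_index(np.nanargmax(vals), vals.shape)
        size = int(sizes[lab - 1])
        p = float((max_sizes >= size).mean())
        clusters.append(Cluster(tuple(int(i) for i in peak),
                                float(t_obs[peak]), size, p))
    clusters.sort(key=lambda c: -c.size)
    return ClusterResult(clusters, t_obs_map, float(t_thr), config, max_sizes)


def interaction_anova_2x3(roi_values: np.ndarray) -> tuple[float, int, int, float]:
    """Repeated-measures interaction of correlation type x phase pair.

    ``roi_values``: array (n_subjects, 2, 3) — per subject, the ROI mean
    Fisher-z for {same, different} video pairs in each of the three phase
    pairs.  Returns (F, df1, df2, p) for the type-by-phase interaction, with
    df = (2, 2(n-1)) computed from the data's own dimensions.
    """
    import pingouin as pg

    vals = np.asarray(roi_values, dtype=float)
    if vals.ndim != 3 or vals.shape[1:] != (2, 3):
        raise ValueError("roi_values must have shape (n_subjects, 2, 3)")
    if not np.all(np.isfinite(vals)):
        raise ValueError("missing cells in the within-subject table")
    n = vals.shape[0]
    rows = []
    for s in range(n):
        for ci, ctype in enumerate(("same", "different")):
            for pi, pair in enumerate(("Enc_ImRet", "Enc_DelRet", "ImRet_DelRet")):
                rows.append(dict(subject=s, ctype=ctype, pair=pair,
                                 z=vals[s, ci, pi]))
    df = pd.DataFrame(rows)
    aov = pg.rm_anova(data=df, dv="z", within=["ctype", "pair"],
                      subject="subject", detailed=True)
    inter = aov[aov["Source"].str.contains(r"\*")].iloc[0]
    return (float(inter["F"]), int(inter["ddof1"]), int(inter["ddof2"]),
            float(inter["p_unc"]))
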