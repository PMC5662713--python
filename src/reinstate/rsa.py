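"""Within-subject RSA: contrast weight matrices, Fisher-z pattern
correlations, and searchlight / ROI reinstatement statistics.

The reinstatement statistic at a searchlight center v is

    S(v) = sum_ij  w_ij * atanh( corr(a_i[N(v)], b_j[N(v)]) )

where a_i, b_j are per-trial pattern vectors from two phases, N(v) is the
spherical neighborhood of v, and the weights w encode the contrast of
interest.  Because the weights sum to zero the statistic is invariant to any
constant shift of all correlations, so under exchangeable trial labels its
expectation is zero.

Two contrast kinds are supported:

* ``same_vs_different`` — positive weight on same-video trial pairs, negative
  on different-video pairs.  With the default normalization the statistic is
  mean(same z) - mean(different z).
* ``weighted_diagonal`` — nonzero weight only on same-video pairs, equal to a
  per-video score centered across videos, so reinstatement that is uniform
  over videos cancels and only score-coupled reinstatement survives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import GridMismatchError, Mask, PatternSet, StatMap

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_z",
    "WeightMatrix",
    "build_same_vs_different",
    "build_weighted_diagonal",
    "SearchlightSpec",
    "sphere_offsets",
    "sphere_neighborhood",
    "neighborhood_matrix",
    "searchlight_rsa",
    "roi_rsa",
    "RsaResult",
]

_CLIP = 1.0 - 1e-7


def fisher_z(r):
    """Fisher z (atanh) transform of a correlation, clipped at |r| = 1 - 1e-7.

    Accepts scalars or arrays; raises ``ValueError`` for |r| > 1 (beyond
    floating-point slack).
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    return float(z) if z.ndim == 0 else z


# ---------------------------------------------------------------------------
# Weight matrices
# ---------------------------------------------------------------------------

@dataclass
class WeightMatrix:
    """Trial-pair weights for an RSA contrast.

    ``weights[i, j]`` multiplies the Fisher-z correlation of phase-A trial i
    with phase-B trial j.  Excluded pairs carry weight exactly 0 and are never
    computed.  All weights sum to zero by construction.
    """

    trials_a: pd.DataFrame
    trials_b: pd.DataFrame
    weights: np.ndarray
    kind: str
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.trials_a), len(self.trials_b)):
            raise ValueError("weight matrix shape mismatch with trial tables")
        if self.excluded is None:
            self.excluded = np.zeros_like(self.weights, dtype=bool)
        if np.any(self.weights[self.excluded] != 0):
            raise ValueError("excluded pairs must carry weight 0")
        s = self.weights.sum()
        if abs(s) > 1e-9 * max(1.0, np.abs(self.weights).sum()):
            raise ValueError(f"weights must sum to zero, got {s}")

    @property
    def nonzero_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.weights)

    def transpose(self) -> "WeightMatrix":
        return WeightMatrix(self.trials_b, self.trials_a, self.weights.T,
                            self.kind, self.excluded.T)


def _same_video(trials_a: pd.DataFrame, trials_b: pd.DataFrame) -> np.ndarray:
    va = trials_a["video_id"].to_numpy()
    vb = trials_b["video_id"].to_numpy()
    return va[:, None] == vb[None, :]


def build_same_vs_different(trials_a: pd.DataFrame, trials_b: pd.DataFrame,
                            exclude_between_run_day1: bool = True,
                            normalize: bool = True) -> WeightMatrix:
    """Same-video vs different-video contrast weights.

    Same-video pairs get +1/N_same, different-video pairs -1/N_diff (after
    exclusions), so the searchlight statistic equals mean(same z) minus
    mean(different z).  With ``normalize=False`` the same-pair weight is +1
    and the different-pair weight -N_same/N_diff ("summed difference" scale);
    the two differ by the constant factor N_same, which leaves one-sample
    group inference unchanged.

    When both trial sets come from Day 1 (Enc and/or ImRet, runs 1-2) and
    ``exclude_between_run_day1`` is set, pairs spanning different runs are
    excluded to keep run effects out of the contrast.  Pairs involving the
    Day-8 DelRet run necessarily span runs and are never excluded.
    """
    same = _same_video(trials_a, trials_b)
    day1_a = trials_a["phase"].isin(["Enc", "ImRet"]).to_numpy()
    day1_b = trials_b["phase"].isin(["Enc", "ImRet"]).to_numpy()
    excluded = np.zeros_like(same)
    if exclude_between_run_day1:
        ra = trials_a["run"].to_numpy()
        rb = trials_b["run"].to_numpy()
        excluded = (day1_a[:, None] & day1_b[None, :]) & (ra[:, None] != rb[None, :])
    keep = ~excluded
    n_same = int((same & keep).sum())
    n_diff = int((~same & keep).sum())
    if n_same == 0:
        raise ValueError("all same-video pairs excluded; contrast undefined")
    if n_diff == 0:
        raise ValueError("no different-video pairs; contrast undefined")
    w = np.zeros(same.shape, dtype=float)
    if normalize:
        w[same & keep] = 1.0 / n_same
        w[~same & keep] = -1.0 / n_diff
    else:
        w[same & keep] = 1.0
        w[~same & keep] = -n_same / n_diff
    return WeightMatrix(trials_a.reset_index(drop=True),
                        trials_b.reset_index(drop=True),
                        w, "same_vs_different", excluded)


def build_weighted_diagonal(trials_a: pd.DataFrame, trials_b: pd.DataFrame,
                            scores_per_video: dict | pd.Series) -> WeightMatrix:
    """Behavior-weighted contrast: same-video pairs weighted by centered score.

    ``scores_per_video`` maps video id -> score (e.g. the subject's relative
    memory-detail score).  Scores are re-centered across the subject's videos
    here, so the weights sum to zero regardless of any prior centering.  Only
    same-video ("diagonal") pairs carry weight; if all scores are equal every
    weight is zero and the resulting statistic is identically 0 (a warning is
    logged).
    """
    scores = pd.Series(scores_per_video, dtype=float)
    same = _same_video(trials_a, trials_b)
    videos = np.unique(trials_a["video_id"].to_numpy())
    missing = set(videos) - set(scores.index)
    if missing:
        raise ValueError(f"no score for videos: {sorted(missing)}")
    centered = scores.loc[videos] - scores.loc[videos].mean()
    if np.allclose(centered, 0):
        logger.warning("constant scores: weighted contrast is identically 0")
    per_video = dict(zip(videos, centered.to_numpy()))
    va = trials_a["video_id"].to_numpy()
    w = np.zeros(same.shape, dtype=float)
    ii, jj = np.nonzero(same)
    w[ii, jj] = [per_video[v] for v in va[ii]]
    # each video contributes the same number of same-video pairs, so
    # centering across videos keeps the total at zero; guard for ragged designs
    counts = {v: int((va[ii] == v).sum()) for v in videos}
    if len(set(counts.values())) > 1:
        # re-center over pairs to restore the zero sum exactly
        w[ii, jj] -= w[ii, jj].mean()
    return WeightMatrix(trials_a.reset_index(drop=True),
                        trials_b.reset_index(drop=True),
                        w, "weighted_diagonal")


# ---------------------------------------------------------------------------
# Searchlight geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchlightSpec:
    """Spherical searchlight: Euclidean radius in voxel-index units, center
    included, voxels at exactly the radius included.  Centers whose in-mask
    neighborhood is smaller than ``min_voxels`` get NaN output."""

    radius_voxels: float = 3.0
    min_voxels: int = 10

    def __post_init__(self) -> None:
        if self.radius_voxels <= 0:
            raise ValueError("radius must be positive")


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer lattice offsets with Euclidean norm <= radius (ties included)."""
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2 + 1e-9
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def sphere_neighborhood(center_voxel, spec: SearchlightSpec, mask: Mask) -> np.ndarray:
    """(k, 3) in-mask voxel indices within ``spec.radius_voxels`` of center."""
    center = np.asarray(center_voxel, dtype=int)
    if not mask.voxels[tuple(center)]:
        raise ValueError("searchlight center must lie inside the mask")
    pts = center[None, :] + sphere_offsets(spec.radius_voxels)
    shape = np.asarray(mask.grid.shape)
    ok = np.all((pts >= 0) & (pts < shape), axis=1)
    pts = pts[ok]
    inmask = mask.voxels[pts[:, 0], pts[:, 1], pts[:, 2]]
    return pts[inmask]


def neighborhood_matrix(mask: Mask, spec: SearchlightSpec) -> sp.csr_matrix:
    """Sparse (n_mask x n_mask) indicator: row v marks the in-mask voxels in
    the spherical neighborhood of in-mask center v.

    Row sums give neighborhood sizes; multiplying a (trials x n_mask) matrix by
    its transpose accumulates neighborhood sums for every center at once, which
    is what makes the searchlight fast.
    """
    shape = mask.grid.shape
    flat_of_voxel = -np.ones(shape, dtype=np.int64)
    idx = mask.indices
    flat_of_voxel[idx[:, 0], idx[:, 1], idx[:, 2]] = np.arange(len(idx))
    offsets = sphere_offsets(spec.radius_voxels)
    rows, cols = [], []
    shape_arr = np.asarray(shape)
    for off in offsets:
        pts = idx + off
        ok = np.all((pts >= 0) & (pts < shape_arr), axis=1)
        nb = flat_of_voxel[pts[ok, 0], pts[ok, 1], pts[ok, 2]]
        valid = nb >= 0
        rows.append(np.flatnonzero(ok)[valid])
        cols.append(nb[valid])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.ones(len(rows), dtype=np.float64)
    n = len(idx)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------------
# Searchlight and ROI statistics
# ---------------------------------------------------------------------------

@dataclass
class RsaResult:
    """Either a searchlight statistic map or an ROI scalar summary."""

    phase_pair: tuple[str, str]
    weight_kind: str
    stat_map: StatMap | None = None
    mean_same_z: float | None = None
    mean_diff_z: float | None = None
    weighted_sum: float | None = None

    @property
    def reinstatement(self) -> float:
        """mean(same z) - mean(diff z) for ROI same-vs-different results."""
        return self.mean_same_z - self.mean_diff_z


def _pair_correlations_by_neighborhood(a_vals: np.ndarray, b_vals: np.ndarray,
                                       ii: np.ndarray, jj: np.ndarray,
                                       nbm: sp.csr_matrix, counts: np.ndarray
                                       ) -> tuple[np.ndarray, int]:
    """Pearson r per (pair, center voxel) over spherical neighborhoods.

    ``a_vals``/``b_vals``: full (n_trials, n_mask) pattern matrices; ``ii``,
    ``jj`` index the nonzero-weight pairs.  All neighborhood sums (per-trial
    first and second moments plus per-pair cross products) are accumulated in
    a single sparse multiply, which is what keeps the searchlight fast.
    Zero-variance patterns within a neighborhood yield r = 0 (counted and
    logged by the caller).
    """
    na, nb = a_vals.shape[0], b_vals.shape[0]
    stacked = np.concatenate([
        a_vals[ii] * b_vals[jj],     # cross products, one row per pair
        a_vals, a_vals * a_vals,
        b_vals, b_vals * b_vals,
    ], axis=0)
    sums = (nbm @ stacked.T).T
    npairs = len(ii)
    sum_ab = sums[:npairs]
    sum_a = sums[npairs:npairs + na][ii]
    sum_a2 = sums[npairs + na:npairs + 2 * na][ii]
    sum_b = sums[npairs + 2 * na:npairs + 2 * na + nb][jj]
    sum_b2 = sums[npairs + 2 * na + nb:][jj]
    n = counts[None, :]
    cov = sum_ab - sum_a * sum_b / n
    var_a = sum_a2 - sum_a**2 / n
    var_b = sum_b2 - sum_b**2 / n
    denom2 = var_a * var_b
    degenerate = denom2 <= 1e-24
    n_degenerate = int(degenerate.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(np.where(degenerate, 1.0, denom2))
    r[degenerate] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return r, n_degenerate


def searchlight_rsa(patterns_a: PatternSet, patterns_b: PatternSet,
                    w: WeightMatrix, spec: SearchlightSpec = SearchlightSpec(),
                    nbm: sp.csr_matrix | None = None) -> StatMap:
    """Searchlight reinstatement map: weighted sum of Fisher-z correlations.

    Only pairs with nonzero weight are computed.  Pass a precomputed
    ``neighborhood_matrix`` via ``nbm`` when running many subjects on one
    mask.  Centers with fewer than ``spec.min_voxels`` in-mask neighbors are
    NaN; all out-of-mask voxels are NaN.
    """
    if not patterns_a.grid.matches(patterns_b.grid):
        raise GridMismatchError("pattern sets on different grids")
    if patterns_a.mask.n_voxels != patterns_b.mask.n_voxels or not np.array_equal(
            patterns_a.mask.voxels, patterns_b.mask.voxels):
        raise GridMismatchError("pattern sets use different masks")
    if w.weights.shape != (patterns_a.n_trials, patterns_b.n_trials):
        raise ValueError("weight matrix not conformable with pattern sets")
    if nbm is None:
        nbm = neighborhood_matrix(patterns_a.mask, spec)
    counts = np.asarray(nbm.sum(axis=1)).ravel()
    ii, jj = w.nonzero_pairs
    r, n_degenerate = _pair_correlations_by_neighborhood(
        patterns_a.values, patterns_b.values, ii, jj, nbm, counts)
    if n_degenerate:
        logger.info("searchlight: %d zero-variance pattern/neighborhood pairs "
                    "treated as r=0", n_degenerate)
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    stat = w.weights[ii, jj] @ z
    stat[counts < spec.min_voxels] = np.nan
    vol = np.full(patterns_a.grid.shape, np.nan)
    vol[patterns_a.mask.voxels] = stat
    return StatMap(patterns_a.grid, vol, "searchlight_sum")


def roi_rsa(patterns_a: PatternSet, patterns_b: PatternSet, roi: Mask,
            w: WeightMatrix) -> RsaResult:
    """ROI reinstatement: one pattern per trial over all ROI voxels.

    For ``same_vs_different`` weights, returns the average Fisher-z same-video
    and different-video correlations separately (group tests are done
    downstream); averages honor the weight matrix's pair exclusions.  For
    ``weighted_diagonal``, returns the weighted sum of Fisher-z correlations.
    """
    if roi.n_voxels < 2:
        raise ValueError("ROI must contain at least 2 voxels")
    a = patterns_a.restrict(roi).values
    b = patterns_b.restrict(roi).values
    ii, jj = w.nonzero_pairs
    az = a[ii] - a[ii].mean(axis=1, keepdims=True)
    bz = b[jj] - b[jj].mean(axis=1, keepdims=True)
    denom = np.sqrt((az * az).sum(axis=1) * (bz * bz).sum(axis=1))
    degenerate = denom <= 1e-24
    if degenerate.any():
        logger.info("roi_rsa: %d zero-variance patterns treated as r=0",
                    int(degenerate.sum()))
    r = np.where(degenerate, 0.0, (az * bz).sum(axis=1) / np.where(degenerate, 1.0, denom))
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    phase_pair = (str(patterns_a.trials["phase"].iloc[0]),
                  str(patterns_b.trials["phase"].iloc[0]))
    if w.kind == "weighted_diagonal":
        return RsaResult(phase_pair, w.kind,
                         weighted_sum=float(w.weights[ii, jj] @ z))
    ws = w.weights[ii, jj]
    return RsaResult(phase_pair, w.kind,
                     mean_same_z=float(z[ws > 0].mean()),
                     mean_diff_z=float(z[ws < 0].mean()))
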