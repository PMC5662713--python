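"""Behavioral scoring and statistics for the video-memory design.

Free-recall descriptions are scored detail-by-detail with marks of 0, 0.5 or
1; a video's detail score is the (uncapped) sum of its marks.  Because some
videos are intrinsically more memorable than others, parametric analyses use
*relative* memory performance: each subject's score for a video minus that
video's mean score across subjects.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .rsa import fisher_z

__all__ = [
    "aggregate_details",
    "relative_performance",
    "paired_comparisons",
    "vividness_performance_association",
]

_ALLOWED_MARKS = (0.0, 0.5, 1.0)


def aggregate_details(detail_marks) -> float:
    """Sum a list of per-detail marks from {0, 0.5, 1}.

    There is no cap on the number of details, so the score is unbounded above.
    An empty list scores 0.
    """
    marks = [float(m) for m in detail_marks]
    bad = [m for m in marks if m not in _ALLOWED_MARKS]
    if bad:
        raise ValueError(f"detail marks must be 0, 0.5 or 1; got {bad}")
    return float(sum(marks))


def relative_performance(scores: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Center a subject x video score matrix by each video's across-subject
    mean, indexing performance relative to the video's memorability."""
    values = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) \
        else np.asarray(scores, dtype=float)
    if np.isnan(values).any():
        raise ValueError("score matrix has missing entries")
    centered = values - values.mean(axis=0, keepdims=True)
    if isinstance(scores, pd.DataFrame):
        return pd.DataFrame(centered, index=scores.index, columns=scores.columns)
    return centered


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        # constant nonzero shift: infinite evidence, flagged as +-inf
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def paired_comparisons(behavior: pd.DataFrame) -> dict:
    """Two-tailed paired t tests (on subject means) of retrieval duration and
    vividness between immediate and delayed retrieval.

    ``behavior`` is a long subject x video table with columns
    ``vividness_imret/vividness_delret`` and
    ``retrieval_duration_imret/retrieval_duration_delret``.
    """
    per_sub = behavior.groupby("subject_id")[
        ["retrieval_duration_imret", "retrieval_duration_delret",
         "vividness_imret", "vividness_delret"]].mean()
    if len(per_sub) < 3:
        raise ValueError("need at least 3 subjects for paired comparisons")
    dur = _paired_t(per_sub["retrieval_duration_imret"].to_numpy(),
                    per_sub["retrieval_duration_delret"].to_numpy())
    viv = _paired_t(per_sub["vividness_imret"].to_numpy(),
                    per_sub["vividness_delret"].to_numpy())
    return {"duration": dur, "vividness": viv, "n": len(per_sub)}


def vividness_performance_association(behavior: pd.DataFrame,
                                      phase: str = "ImRet") -> dict:
    """Association between retrieval vividness and memory detail scores.

    Per subject, Pearson r between vividness (``phase`` selects ImRet or
    DelRet ratings) and detail scores over the videos; the r's are Fisher-z
    transformed and tested against zero with a one-sample t.  Subjects with
    zero variance in either variable are excluded with a warning.  Also
    reports how many subjects are individually significant at p < .05
    (two-tailed).
    """
    col = {"ImRet": "vividness_imret", "DelRet": "vividness_delret"}[phase]
    rs, n_sig, excluded = [], 0, []
    for sub, grp in behavior.groupby("subject_id"):
        v = grp[col].to_numpy(dtype=float)
        s = grp["detail_score"].to_numpy(dtype=float)
        if len(v) < 3 or v.std() == 0 or s.std() == 0:
            excluded.append(sub)
            continue
        r, p = stats.pearsonr(v, s)
        rs.append(r)
        n_sig += int(p < 0.05)
    if excluded:
        warnings.warn(f"excluded zero-variance subjects: {excluded}",
                      stacklevel=2)
    if len(rs) < 3:
        raise ValueError("need at least 3 subjects with variance")
    zs = fisher_z(np.asarray(rs))
    t, p = stats.ttest_1samp(zs, 0.0)
    return {"per_subject_r": np.asarray(rs), "per_subject_z": zs,
            "t": float(t), "p": float(p), "df": len(rs) - 1,
            "n_individually_significant": n_sig, "n_subjects": len(rs)}
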