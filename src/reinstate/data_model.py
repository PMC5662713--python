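"""Core domain types and NIfTI/TSV input-output.

Voxel-grid conventions used throughout the package:

* voxel indices are 0-based; world (mm) coordinates are obtained through the
  grid's 4x4 affine;
* per-trial pattern values are stored *masked* — as a ``trials x in-mask-voxel``
  matrix — and only scattered back into a full volume at write time;
* TSV with an explicit header row is the canonical tabular format, with the
  BIDS events convention (``onset`` and ``duration`` as the first columns) for
  trial tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "Mask",
    "PatternSet",
    "StatMap",
    "PHASES",
    "TRIAL_COLUMNS",
    "validate_trial_table",
    "read_trial_table",
    "write_trial_table",
    "read_mask",
    "write_mask",
    "read_pattern_set",
    "write_pattern_set",
    "read_stat_map",
    "write_stat_map",
    "GridMismatchError",
    "AlignmentError",
]

#: Experiment phases: encoding, immediate retrieval (Day 1), delayed retrieval
#: (Day 8).
PHASES = ("Enc", "ImRet", "DelRet")

#: Canonical trial-table column order (BIDS events dialect: onset/duration
#: first).  ``cue_onset``, ``vividness`` and ``retrieval_duration`` are NaN for
#: encoding trials.
TRIAL_COLUMNS = [
    "onset",
    "duration",
    "subject_id",
    "phase",
    "run",
    "video_id",
    "cue_onset",
    "vividness",
    "retrieval_duration",
]


class GridMismatchError(ValueError):
    """Volumes or masks do not share a common voxel grid."""


class AlignmentError(ValueError):
    """Trial table rows and pattern volumes do not align one-to-one."""


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel geometry of a 3D volume.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis (all >= 1).
    voxel_size : tuple of float
        Edge length of a voxel per axis, in mm (> 0).
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform (must be invertible).
    space_label : str
        Free-text label for the coordinate space (``"native"``, ``"common"``).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    space_label: str = "common"

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {shape}")
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be positive, got {vs}")
        affine = self.affine
        if affine is None:
            affine = np.diag([vs[0], vs[1], vs[2], 1.0])
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def from_img(cls, img: nib.Nifti1Image, space_label: str = "common") -> "VolumeGrid":
        zooms = img.header.get_zooms()[:3]
        return cls(tuple(img.shape[:3]), tuple(float(z) for z in zooms),
                   np.asarray(img.affine), space_label)

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.affine, other.affine, atol=atol))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass(frozen=True)
class Mask:
    """Boolean voxel selection on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=bool)
        if vox.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {vox.shape} != grid shape {self.grid.shape}")
        if not vox.any():
            raise ValueError("mask must contain at least one true voxel")
        object.__setattr__(self, "voxels", vox)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def indices(self) -> np.ndarray:
        """(n, 3) integer voxel indices of true voxels, C order."""
        return np.argwhere(self.voxels)

    def flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.voxels.ravel())

    def contains(self, other: "Mask") -> bool:
        """True if every voxel of ``other`` is inside this mask."""
        if not self.grid.matches(other.grid):
            raise GridMismatchError("masks on different grids")
        return bool(np.all(self.voxels[other.voxels]))


@dataclass
class PatternSet:
    """Stack of per-trial statistic patterns restricted to a mask.

    ``values[i, j]`` is trial *i*'s statistic at the *j*-th in-mask voxel
    (voxels ordered by C-order flat index).  This is the unit object all RSAs
    consume.
    """

    grid: VolumeGrid
    mask: Mask
    trials: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.grid.matches(self.mask.grid):
            raise GridMismatchError("pattern grid and mask grid differ")
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (trials x voxels)")
        if self.values.shape[0] != len(self.trials):
            raise AlignmentError(
                f"{self.values.shape[0]} pattern rows vs {len(self.trials)} trials")
        if self.values.shape[1] != self.mask.n_voxels:
            raise AlignmentError(
                f"{self.values.shape[1]} columns vs {self.mask.n_voxels} mask voxels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pattern values must be finite inside the mask")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def select(self, row_mask: np.ndarray | pd.Series) -> "PatternSet":
        row_mask = np.asarray(row_mask)
        return PatternSet(self.grid, self.mask,
                          self.trials.loc[row_mask].reset_index(drop=True),
                          self.values[row_mask])

    def restrict(self, roi: Mask) -> "PatternSet":
        """Restrict columns to the voxels of ``roi`` (must lie in the mask)."""
        if not self.mask.contains(roi):
            raise ValueError("ROI extends outside the pattern mask")
        cols = np.isin(self.mask.flat_indices(), roi.flat_indices())
        return PatternSet(self.grid, roi, self.trials.copy(), self.values[:, cols])

    def unmask(self, fill: float = np.nan) -> np.ndarray:
        """(n_trials,) + grid.shape array with values scattered into volumes."""
        out = np.full((self.n_trials,) + self.grid.shape, fill, dtype=float)
        flat = out.reshape(self.n_trials, -1)
        flat[:, self.mask.flat_indices()] = self.values
        return flat.reshape(out.shape)


@dataclass
class StatMap:
    """A voxelwise statistic volume with grid metadata.

    ``stat_kind`` is one of ``searchlight_sum``, ``t``, ``F``, ``z``.  NaN is
    allowed (and expected) outside the analysis mask.
    """

    grid: VolumeGrid
    values: np.ndarray
    stat_kind: str = "searchlight_sum"
    df: float | tuple[float, float] | None = None

    _KINDS = frozenset({"searchlight_sum", "t", "F", "z"})

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"stat map shape {self.values.shape} != grid {self.grid.shape}")
        if self.stat_kind not in self._KINDS:
            raise ValueError(f"unknown stat_kind {self.stat_kind!r}")

    def masked(self, mask: Mask) -> np.ndarray:
        """Flat vector of values at mask voxels."""
        return self.values[mask.voxels]


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check trial-table invariants and return the table in canonical order.

    Enc/ImRet trials must be in runs 1-2, DelRet in run 3; (phase, video_id)
    unique per subject; video ids in 1..24 (or 1..n for smaller designs).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    t = table[TRIAL_COLUMNS].copy()
    bad_phase = set(t["phase"]) - set(PHASES)
    if bad_phase:
        raise ValueError(f"unknown phases: {sorted(bad_phase)}")
    day1 = t["phase"].isin(["Enc", "ImRet"])
    if not t.loc[day1, "run"].isin([1, 2]).all():
        raise ValueError("Enc/ImRet trials must have run in {1, 2}")
    if not (t.loc[t["phase"] == "DelRet", "run"] == 3).all():
        raise ValueError("DelRet trials must have run = 3")
    if t["video_id"].min() < 1:
        raise ValueError("video ids must be >= 1")
    dup = t.duplicated(subset=["subject_id", "phase", "video_id"])
    if dup.any():
        raise ValueError("duplicate (subject, phase, video) trials")
    return t


def read_trial_table(path: str | Path) -> pd.DataFrame:
    return validate_trial_table(pd.read_csv(path, sep="\t"))


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_trial_table(table).to_csv(path, sep="\t", index=False,
                                       float_format="%.6g")


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def _load_img(path: str | Path) -> nib.Nifti1Image:
    img = nib.load(str(path))
    return img


def read_mask(path: str | Path, space_label: str = "common") -> Mask:
    img = _load_img(path)
    grid = VolumeGrid.from_img(img, space_label)
    return Mask(grid, np.asanyarray(img.dataobj) > 0)


def write_mask(mask: Mask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine)
    img.to_filename(str(path))


def read_pattern_set(volume_paths: Sequence[str | Path],
                     mask_path: str | Path,
                     trial_table_path: str | Path) -> PatternSet:
    """Assemble a :class:`PatternSet` from per-trial NIfTI maps.

    All volumes must share one grid, and the trial table must align 1:1 with
    the volume list (row *i* describes volume *i*).
    """
    volume_paths = list(volume_paths)
    trials = read_trial_table(trial_table_path)
    if len(volume_paths) != len(trials):
        raise AlignmentError(
            f"{len(volume_paths)} volumes vs {len(trials)} trial rows")
    mask = read_mask(mask_path)
    flat = mask.flat_indices()
    rows = np.empty((len(volume_paths), flat.size), dtype=float)
    for i, p in enumerate(volume_paths):
        img = _load_img(p)
        grid = VolumeGrid.from_img(img)
        if not grid.matches(mask.grid):
            raise GridMismatchError(f"{p}: grid differs from mask grid")
        rows[i] = np.asanyarray(img.dataobj, dtype=float).ravel()[flat]
    return PatternSet(mask.grid, mask, trials, rows)


def write_pattern_set(patterns: PatternSet, out_dir: str | Path,
                      prefix: str = "trial") -> list[Path]:
    """Write one NIfTI per trial plus the trial table; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vols = patterns.unmask(fill=np.nan)
    paths = []
    for i in range(patterns.n_trials):
        p = out_dir / f"{prefix}_{i:03d}.nii.gz"
        nib.Nifti1Image(vols[i].astype(np.float64),
                        patterns.grid.affine).to_filename(str(p))
        paths.append(p)
    write_trial_table(patterns.trials, out_dir / f"{prefix}s.tsv")
    write_mask(patterns.mask, out_dir / "mask.nii.gz")
    return paths


def read_stat_map(path: str | Path, stat_kind: str = "searchlight_sum",
                  df=None) -> StatMap:
    img = _load_img(path)
    grid = VolumeGrid.from_img(img)
    return StatMap(grid, np.asanyarray(img.dataobj, dtype=float), stat_kind, df)


def write_stat_map(stat_map: StatMap, path: str | Path) -> None:
    """Write a :class:`StatMap` as NIfTI; float64 so re-read values are exact."""
    img = nib.Nifti1Image(stat_map.values.astype(np.float64),
                          stat_map.grid.affine)
    img.to_filename(str(path))
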