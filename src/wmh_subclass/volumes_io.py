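"""NIfTI volume and cohort-table I/O, and the single-grid contract.

Every per-subject analysis in this package assumes that all volumes
(WMH mask or probability map, white-matter PVE, extended ventricle mask,
brain mask, DTI metric maps) were registered to one common space upstream
and therefore live on one voxel grid.  Nothing here resamples or
transforms: a grid mismatch is an error, never a silent interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "SubjectBundle",
    "GridReport",
    "CohortSchema",
    "CohortTable",
    "GridMismatchError",
    "load_volume",
    "save_volume",
    "load_mask",
    "binarize",
    "assert_same_grid",
    "check_same_grid",
    "load_cohort_table",
]

#: tolerance (mm) under which two voxel dimensions count as equal
VOXEL_DIM_TOL_MM = 1e-4


class GridMismatchError(ValueError):
    """Two volumes that must share a voxel grid do not."""


@dataclass
class VoxelGrid:
    """A 3D scalar field with its voxel geometry.

    Parameters
    ----------
    data
        3D array of voxel values.
    affine
        4x4 voxel-to-world transform (NIfTI convention, mm).
    space_tag
        Free-text identifier of the registration space (e.g. ``"FLAIR"``).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got {self.data.ndim}D "
                f"(offending axis count {self.data.ndim})"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(np.asarray(self.voxel_dims) <= 0):
            raise ValueError(f"voxel dimensions must be positive, got {self.voxel_dims}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        """Voxel edge lengths (dx, dy, dz) in mm, from the affine columns."""
        d = np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
        return (float(d[0]), float(d[1]), float(d[2]))

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """New grid sharing this grid's geometry with different values."""
        return VoxelGrid(data=data, affine=self.affine.copy(), space_tag=self.space_tag)


@dataclass
class BinaryMask:
    """A VoxelGrid constrained to values {0, 1}."""

    grid: VoxelGrid

    def __post_init__(self) -> None:
        vals = np.unique(self.grid.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("BinaryMask values must be 0/1; use load_mask to coerce")
        if self.grid.data.dtype != np.uint8:
            self.grid = self.grid.with_data(self.grid.data.astype(np.uint8))

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)


@dataclass
class SubjectBundle:
    """All co-registered inputs for one subject.

    ``brain`` may be omitted when ``total_brain_volume_dm3`` is given
    directly (the downstream volumetrics only need the scalar).
    """

    wmh: BinaryMask | VoxelGrid
    wm_pve: VoxelGrid
    ventricle_ext: BinaryMask
    brain: BinaryMask | None = None
    total_brain_volume_dm3: float | None = None
    dti: Mapping[str, VoxelGrid] | None = None

    def named_grids(self) -> list[tuple[str, VoxelGrid]]:
        out: list[tuple[str, VoxelGrid]] = []
        wmh_grid = self.wmh.grid if isinstance(self.wmh, BinaryMask) else self.wmh
        out.append(("wmh", wmh_grid))
        out.append(("wm_pve", self.wm_pve))
        out.append(("ventricle_ext", self.ventricle_ext.grid))
        if self.brain is not None:
            out.append(("brain", self.brain.grid))
        if self.dti:
            for name, g in self.dti.items():
                out.append((f"dti:{name}", g))
        return out

    def brain_volume_dm3(self) -> float:
        if self.total_brain_volume_dm3 is not None:
            return float(self.total_brain_volume_dm3)
        if self.brain is None:
            raise ValueError("bundle has neither a brain mask nor a brain volume")
        return self.brain.n_voxels * self.brain.grid.voxel_volume_mm3 / 1e6


@dataclass
class GridReport:
    """Outcome of the single-grid check: one entry per mismatching pair."""

    mismatches: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.mismatches


def load_volume(path: str | Path) -> VoxelGrid:
    """Load a 3D NIfTI-1 volume, without any resampling.

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If the image is not 3D (the offending axis count is named).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises various ImageFileErrors
        raise OSError(f"cannot read NIfTI volume {path}: {exc}") from exc
    ndim = len(img.shape)
    if ndim != 3:
        raise ValueError(
            f"{path} is {ndim}D; this tool handles 3D volumes only "
            f"(offending axis: {ndim - 1} with length {img.shape[-1]})"
        )
    data = np.asanyarray(img.dataobj)
    return VoxelGrid(data=np.asarray(data), affine=np.asarray(img.affine))


def save_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a VoxelGrid as NIfTI-1, preserving dtype and affine."""
    img = nib.Nifti1Image(grid.data, grid.affine)
    nib.save(img, str(path))


def load_mask(path: str | Path) -> BinaryMask:
    """Load a binary mask, coercing any nonzero value to 1.

    Tolerates label maps saved as 0/255 or float.
    """
    grid = load_volume(path)
    data = (np.asarray(grid.data) != 0).astype(np.uint8)
    return BinaryMask(grid.with_data(data))


def binarize(
    grid: VoxelGrid,
    threshold: float = 0.9,
    strict: bool = True,
    probability_map: bool = True,
) -> BinaryMask:
    """Threshold a scalar map into a binary mask.

    A voxel becomes 1 iff its value *exceeds* the threshold (``value >
    threshold``; the default, matching the probability-0.9 rule used for
    WMH probability maps) or, with ``strict=False``, iff ``value >=
    threshold``.

    Parameters
    ----------
    threshold
        Cut value; must lie in [0, 1] when ``probability_map`` is true.
    strict
        Use ``>`` (default) rather than ``>=``.
    probability_map
        Declare the input a probability map, enabling the range check.
    """
    if probability_map and not 0.0 <= threshold <= 1.0:
        raise ValueError(
            f"threshold {threshold} outside [0, 1] for a probability map"
        )
    data = np.asarray(grid.data, dtype=float)
    if not np.isfinite(data).all():
        raise ValueError("cannot binarize a grid with non-finite values")
    mask = data > threshold if strict else data >= threshold
    return BinaryMask(grid.with_data(mask.astype(np.uint8)))


def check_same_grid(bundle: SubjectBundle) -> GridReport:
    """Check that every grid in the bundle shares shape and voxel dims.

    Voxel dimensions are compared with an absolute tolerance of
    ``VOXEL_DIM_TOL_MM`` (1e-4 mm); the comparison is symmetric.
    """
    report = GridReport()
    grids = bundle.named_grids()
    for i in range(len(grids)):
        for j in range(i + 1, len(grids)):
            name_a, a = grids[i]
            name_b, b = grids[j]
            if a.shape != b.shape:
                report.mismatches.append(
                    f"{name_a} vs {name_b}: shape {a.shape} != {b.shape}"
                )
            dims_a, dims_b = np.array(a.voxel_dims), np.array(b.voxel_dims)
            if np.any(np.abs(dims_a - dims_b) > VOXEL_DIM_TOL_MM):
                report.mismatches.append(
                    f"{name_a} vs {name_b}: voxel_dims {tuple(dims_a)} != {tuple(dims_b)}"
                )
    return report


def assert_same_grid(bundle: SubjectBundle) -> GridReport:
    """As :func:`check_same_grid`, but raise on any mismatch."""
    report = check_same_grid(bundle)
    if not report.ok:
        raise GridMismatchError("; ".join(report.mismatches))
    return report


def _require_same_grid(a: VoxelGrid, b: VoxelGrid, name_a: str, name_b: str) -> None:
    if a.shape != b.shape or np.any(
        np.abs(np.array(a.voxel_dims) - np.array(b.voxel_dims)) > VOXEL_DIM_TOL_MM
    ):
        raise GridMismatchError(
            f"{name_a} (shape {a.shape}, dims {a.voxel_dims}) and "
            f"{name_b} (shape {b.shape}, dims {b.voxel_dims}) are not on one grid"
        )


@dataclass
class CohortSchema:
    """Declares the typed columns expected in a cohort table.

    ``numeric`` covers covariates, volume predictors and cognitive scores;
    ``categorical`` maps a column name to its allowed levels.
    """

    numeric: Sequence[str] = ()
    categorical: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def required(self) -> list[str]:
        return list(self.numeric) + list(self.categorical)


@dataclass
class CohortTable:
    """A per-subject table plus a boolean missingness mask.

    Rows with missing values in schema columns are flagged in
    ``missing`` (same shape as ``df`` over schema columns), never dropped
    at load time; models apply listwise deletion themselves and report n.
    """

    df: pd.DataFrame
    missing: pd.DataFrame

    def flagged_rows(self) -> dict[int, list[str]]:
        """Row index -> names of columns missing in that row."""
        out: dict[int, list[str]] = {}
        for idx, row in self.missing.iterrows():
            cols = [c for c in self.missing.columns if row[c]]
            if cols:
                out[int(idx)] = cols
        return out


def load_cohort_table(
    path: str | Path,
    schema: CohortSchema,
    delimiter: str | None = None,
) -> CohortTable:
    """Load a delimited cohort table and type it against a schema.

    The delimiter is sniffed from the extension (``.tsv`` -> tab,
    otherwise comma) unless given explicitly.

    Raises
    ------
    ValueError
        If a required column is absent (named in the message) or a
        categorical value is outside its declared levels.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=delimiter)
    for col in schema.required():
        if col not in df.columns:
            raise ValueError(f"cohort table {path} is missing required column '{col}'")
    for col in schema.numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col, levels in schema.categorical.items():
        observed = df[col].dropna().astype(str)
        bad = sorted(set(observed) - set(map(str, levels)))
        if bad:
            raise ValueError(
                f"column '{col}' has values {bad} outside declared levels {list(levels)}"
            )
        df[col] = pd.Categorical(df[col].astype("string"), categories=list(map(str, levels)))
    cols = schema.required()
    missing = df[cols].isna()
    return CohortTable(df=df, missing=missing)
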