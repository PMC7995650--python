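"""Volumetrics and DTI-metric summaries.

Volumes are reported raw (cm^3), adjusted for total brain volume (a
dimensionless ratio: lesion cm^3 / brain cm^3) and log transformed
(natural log by default) for use as regression predictors.  DTI metrics
(FA, and MD/AD/RD in mm^2/s x 10^-3) are averaged within masks, one
value per subject per mask, and compared across subjects with paired
t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .location_classify import SUBCLASS_CODES, SubclassMap
from .volumes_io import BinaryMask, VoxelGrid, _require_same_grid

__all__ = [
    "VolumeReport",
    "DtiSummary",
    "PairedTResult",
    "compute_volumes",
    "summarize_dti",
    "paired_t_test",
]

ZeroPolicy = Literal["error", "epsilon", "missing"]

VOLUME_CLASSES = ("total",) + tuple(SUBCLASS_CODES)


@dataclass
class VolumeReport:
    """Raw, brain-volume-adjusted and log-transformed volumes per class."""

    raw_cm3: dict[str, float]
    brain_volume_dm3: float
    adjusted: dict[str, float]
    log_adjusted: dict[str, float]  # NaN where flagged missing
    log_base: str = "e"
    missing: list[str] = field(default_factory=list)


@dataclass
class DtiSummary:
    """Mean of one DTI metric over one mask; NaN mean marks an empty mask."""

    mean: float
    n_voxels: int

    @property
    def is_missing(self) -> bool:
        return self.n_voxels == 0


class PairedTResult(NamedTuple):
    t: float
    df: int
    p: float


def compute_volumes(
    subclass_map: SubclassMap,
    brain_volume_dm3: float,
    voxel_volume_mm3: float | None = None,
    log_base: str = "e",
    zero_policy: ZeroPolicy = "missing",
) -> VolumeReport:
    """Volumes of the total WMH mask and the four sub-classes.

    raw = voxel count x voxel volume, in cm^3; adjusted = raw(cm^3) /
    brain(cm^3); log_adjusted = log(adjusted).  Empty classes are handled
    per ``zero_policy``: ``error`` raises naming the class, ``epsilon``
    substitutes one voxel volume before the ratio, ``missing`` flags the
    class and records NaN.
    """
    if brain_volume_dm3 <= 0:
        raise ValueError(f"brain volume must be positive, got {brain_volume_dm3}")
    if log_base not in ("e", "10"):
        raise ValueError("log_base must be 'e' or '10'")
    if voxel_volume_mm3 is None:
        voxel_volume_mm3 = subclass_map.grid.voxel_volume_mm3

    counts = subclass_map.counts()
    counts["total"] = int((subclass_map.labels > 0).sum())
    brain_cm3 = brain_volume_dm3 * 1000.0
    log = math.log if log_base == "e" else math.log10

    raw: dict[str, float] = {}
    adjusted: dict[str, float] = {}
    log_adjusted: dict[str, float] = {}
    missing: list[str] = []
    for cls in VOLUME_CLASSES:
        vol_cm3 = counts[cls] * voxel_volume_mm3 / 1000.0
        raw[cls] = vol_cm3
        if vol_cm3 == 0.0:
            if zero_policy == "error":
                raise ValueError(f"class '{cls}' has zero volume (zero_policy=error)")
            if zero_policy == "epsilon":
                vol_cm3 = voxel_volume_mm3 / 1000.0
            else:
                adjusted[cls] = 0.0
                log_adjusted[cls] = float("nan")
                missing.append(cls)
                continue
        adjusted[cls] = vol_cm3 / brain_cm3
        log_adjusted[cls] = log(adjusted[cls])
    return VolumeReport(
        raw_cm3=raw,
        brain_volume_dm3=brain_volume_dm3,
        adjusted=adjusted,
        log_adjusted=log_adjusted,
        log_base=log_base,
        missing=missing,
    )


def summarize_dti(mask: BinaryMask, metric: VoxelGrid) -> DtiSummary:
    """Arithmetic mean of a metric over mask voxels with finite values.

    An empty mask (or one whose metric values are all non-finite) yields
    a missing summary (NaN mean, n=0), never a zero.
    """
    _require_same_grid(mask.grid, metric, "mask", "metric")
    vals = np.asarray(metric.data, dtype=float)[mask.as_bool()]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return DtiSummary(mean=float("nan"), n_voxels=0)
    return DtiSummary(mean=float(vals.mean()), n_voxels=int(vals.size))


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test on pairwise-complete observations.

    t = mean(d) / (sd(d)/sqrt(n)) with d = a - b and df = n - 1.  Pairs
    with a missing value on either side are dropped; n >= 2 must remain.
    Zero spread with a nonzero mean difference is a degenerate-variance
    error; zero spread with zero mean returns t = 0, p = 1.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if a_arr.shape != b_arr.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(a_arr) & np.isfinite(b_arr)
    d = a_arr[keep] - b_arr[keep]
    n = d.size
    if n == 0:
        raise ValueError("all pairs missing")
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() != 0.0:
            raise ValueError(
                "degenerate variance: constant nonzero difference "
                f"(mean {d.mean():g}, sd 0)"
            )
        return PairedTResult(t=0.0, df=n - 1, p=1.0)
    res = stats.ttest_rel(a_arr[keep], b_arr[keep])
    return PairedTResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue))
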