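"""Intensity criterion: split the WMH mask by white-matter partial volume.

A WMH voxel counts as *non* T1-hypointense when the co-registered
white-matter partial volume estimate (PVE) at that voxel is strictly
greater than the threshold (default 0.5); T1-hypointense voxels are the
remainder of the WMH mask.  The PVE acts as a proxy for T1 signal:
tissue segmentation assigns dark (hypointense) lesion voxels mostly to
grey matter or CSF, so their white-matter PVE drops at or below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes_io import BinaryMask, VoxelGrid, _require_same_grid

__all__ = ["IntensitySplit", "split_by_pve"]

#: PVE values outside [0,1] by at most this much are clamped (segmentation
#: outputs commonly carry float round-off); larger excursions are errors.
PVE_CLAMP_TOL = 1e-6


@dataclass
class IntensitySplit:
    """Disjoint partition of the WMH mask into intensity classes.

    Invariant: ``hypo`` and ``non_hypo`` are disjoint and their union is
    exactly the WMH mask the split was computed from.
    """

    hypo: BinaryMask
    non_hypo: BinaryMask
    pve_threshold: float = 0.5

    @property
    def n_hypo(self) -> int:
        return self.hypo.n_voxels

    @property
    def n_non_hypo(self) -> int:
        return self.non_hypo.n_voxels


def split_by_pve(
    wmh: BinaryMask,
    wm_pve: VoxelGrid,
    threshold: float = 0.5,
) -> IntensitySplit:
    """Partition WMH voxels into T1-hypointense and non-hypointense.

    ``non_hypo = wmh AND (wm_pve > threshold)``;
    ``hypo = wmh AND NOT non_hypo``.  The boundary value ``pve ==
    threshold`` therefore lands in the hypointense class (strict
    inequality).  Voxels outside the WMH mask are never labeled.

    Raises
    ------
    GridMismatchError
        If the mask and the PVE map are not on one grid.
    ValueError
        If the threshold is outside (0, 1), or PVE values stray from
        [0, 1] by more than ``PVE_CLAMP_TOL`` (the offending voxel count
        is reported).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"PVE threshold must lie in (0, 1), got {threshold}")
    _require_same_grid(wmh.grid, wm_pve, "wmh", "wm_pve")

    pve = np.asarray(wm_pve.data, dtype=float)
    out_of_range = (pve < -PVE_CLAMP_TOL) | (pve > 1.0 + PVE_CLAMP_TOL)
    if out_of_range.any():
        raise ValueError(
            f"wm_pve has {int(out_of_range.sum())} voxels outside [0, 1] "
            f"beyond the {PVE_CLAMP_TOL} clamp tolerance"
        )
    pve = np.clip(pve, 0.0, 1.0)

    wmh_bool = wmh.as_bool()
    non_hypo = wmh_bool & (pve > threshold)
    hypo = wmh_bool & ~non_hypo
    return IntensitySplit(
        hypo=BinaryMask(wmh.grid.with_data(hypo.astype(np.uint8))),
        non_hypo=BinaryMask(wmh.grid.with_data(non_hypo.astype(np.uint8))),
        pve_threshold=threshold,
    )
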