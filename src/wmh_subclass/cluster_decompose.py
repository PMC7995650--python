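"""Rim/core decomposition of WMH clusters.

Clusters are partitioned into those *with* T1-hypointense voxels and
those *without*.  Within a hypointense-containing cluster, the
hypointense voxels form the *core* and the remaining hyperintense voxels
the *rim*.  Two algebraic identities tie the decomposition back to the
intensity classes and are asserted on every run:

* non-hypointense volume = volume of clusters without hypointense voxels
  + rim volume
* hypointense volume = core volume
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intensity_classify import IntensitySplit
from .location_classify import ClusterLabeling

__all__ = [
    "ClusterRecord",
    "DecompositionSummary",
    "ReconciliationReport",
    "decompose",
    "component_volumes",
]


@dataclass
class ClusterRecord:
    cluster_id: int
    size_voxels: int
    volume_mm3: float
    has_hypo: bool
    core_voxels: int  # hypo voxels; 0 when not has_hypo
    rim_voxels: int  # non-hypo voxels of a has_hypo cluster; 0 otherwise
    location: str  # "peri" | "deep"


@dataclass
class DecompositionSummary:
    """Cohort-free, single-subject aggregate of the decomposition (cm^3)."""

    n_clusters_total: int
    n_with_hypo: int
    n_without_hypo: int
    volume_with_cm3: float
    volume_without_cm3: float
    volume_rims_cm3: float
    volume_cores_cm3: float
    fraction_clusters_with_hypo: float
    fraction_volume_with_hypo: float


@dataclass
class ReconciliationReport:
    """Voxel-count discrepancies of the two decomposition identities."""

    nonhypo_discrepancy_voxels: int
    hypo_discrepancy_voxels: int

    @property
    def ok(self) -> bool:
        return self.nonhypo_discrepancy_voxels == 0 and self.hypo_discrepancy_voxels == 0


def decompose(
    clusters: ClusterLabeling,
    split: IntensitySplit,
    peri_flags: np.ndarray,
    voxel_volume_mm3: float | None = None,
) -> tuple[list[ClusterRecord], DecompositionSummary]:
    """Per-cluster rim/core records and their aggregate.

    A cluster counts as "with T1-hypointense voxels" as soon as it
    contains a single hypointense voxel.  All counts are exact integer
    arithmetic; unit conversion to mm^3/cm^3 happens only afterwards.
    """
    if voxel_volume_mm3 is None:
        voxel_volume_mm3 = clusters.grid.voxel_volume_mm3
    hypo = split.hypo.as_bool()
    non_hypo = split.non_hypo.as_bool()
    wmh_bool = clusters.labels > 0
    if ((hypo | non_hypo) != wmh_bool).any():
        raise ValueError("intensity split inconsistent with the clustered WMH mask")
    k = clusters.n_clusters
    if len(peri_flags) != k:
        raise ValueError("peri_flags length does not match cluster count")

    flat = clusters.labels.ravel()
    hypo_per = np.bincount(flat, weights=hypo.ravel(), minlength=k + 1)[1:].astype(int)
    size_per = clusters.sizes.astype(int)

    records: list[ClusterRecord] = []
    for cid in range(1, k + 1):
        size = int(size_per[cid - 1])
        n_hypo = int(hypo_per[cid - 1])
        has_hypo = n_hypo > 0
        records.append(
            ClusterRecord(
                cluster_id=cid,
                size_voxels=size,
                volume_mm3=size * voxel_volume_mm3,
                has_hypo=has_hypo,
                core_voxels=n_hypo if has_hypo else 0,
                rim_voxels=(size - n_hypo) if has_hypo else 0,
                location="peri" if peri_flags[cid - 1] else "deep",
            )
        )

    with_mask = hypo_per > 0
    n_with = int(with_mask.sum())
    vox_with = int(size_per[with_mask].sum())
    vox_without = int(size_per[~with_mask].sum())
    vox_cores = int(hypo_per[with_mask].sum())
    vox_rims = vox_with - vox_cores
    total_vox = vox_with + vox_without
    to_cm3 = voxel_volume_mm3 / 1000.0
    summary = DecompositionSummary(
        n_clusters_total=k,
        n_with_hypo=n_with,
        n_without_hypo=k - n_with,
        volume_with_cm3=vox_with * to_cm3,
        volume_without_cm3=vox_without * to_cm3,
        volume_rims_cm3=vox_rims * to_cm3,
        volume_cores_cm3=vox_cores * to_cm3,
        fraction_clusters_with_hypo=n_with / k if k else 0.0,
        fraction_volume_with_hypo=vox_with / total_vox if total_vox else 0.0,
    )
    # identities hold by construction; assert to catch internal drift
    _reconcile_counts(summary, split, voxel_volume_mm3, raise_on_fail=True)
    return records, summary


def _reconcile_counts(
    summary: DecompositionSummary,
    split: IntensitySplit,
    voxel_volume_mm3: float,
    raise_on_fail: bool = False,
) -> ReconciliationReport:
    to_vox = 1000.0 / voxel_volume_mm3
    vox_without = round(summary.volume_without_cm3 * to_vox)
    vox_rims = round(summary.volume_rims_cm3 * to_vox)
    vox_cores = round(summary.volume_cores_cm3 * to_vox)
    rep = ReconciliationReport(
        nonhypo_discrepancy_voxels=abs(split.n_non_hypo - (vox_without + vox_rims)),
        hypo_discrepancy_voxels=abs(split.n_hypo - vox_cores),
    )
    if raise_on_fail and not rep.ok:
        raise ValueError(
            "decomposition identities violated: "
            f"non-hypo off by {rep.nonhypo_discrepancy_voxels} voxels, "
            f"hypo off by {rep.hypo_discrepancy_voxels} voxels"
        )
    return rep


def component_volumes(
    summary: DecompositionSummary,
    split: IntensitySplit,
    voxel_volume_mm3: float,
) -> ReconciliationReport:
    """Verify the decomposition against the intensity-class volumes.

    Checks that the non-hypointense volume equals the volume of clusters
    without hypointense voxels plus the rim volume, and that the
    hypointense volume equals the core volume.  Discrepancies must be
    zero voxels; any other value raises.
    """
    return _reconcile_counts(summary, split, voxel_volume_mm3, raise_on_fail=True)
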