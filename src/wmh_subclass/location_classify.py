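"""Location criterion: periventricular vs deep WMH clusters.

WMHs are grouped into 3D connected components ("clusters") under a
chosen voxel connectivity (6, 18 or 26 neighbours).  A cluster is
*periventricular* iff at least one of its voxels overlaps the extended
ventricle mask (lateral ventricles, thalami and fornix, thresholded at a
very low probability); all other clusters are *deep*.  Combining the
location of a voxel's cluster with the voxel's own intensity class gives
the four sub-classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .intensity_classify import IntensitySplit
from .volumes_io import BinaryMask, VoxelGrid, _require_same_grid

__all__ = [
    "ClusterLabeling",
    "SubclassMap",
    "SUBCLASS_CODES",
    "label_clusters",
    "classify_location",
    "build_extended_ventricle_mask",
    "combine_subclasses",
]

#: sub-class voxel codes used in the combined label map
SUBCLASS_CODES = {
    "peri_hypo": 1,
    "peri_nonhypo": 2,
    "deep_hypo": 3,
    "deep_nonhypo": 4,
}

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class ClusterLabeling:
    """Connected-component labeling of a WMH mask.

    ``labels`` holds 0 for background and 1..K for clusters; IDs are
    assigned in increasing order of each cluster's minimum linear
    (C-order) voxel index, so labelings are reproducible across runs
    and platforms.
    """

    labels: np.ndarray
    sizes: np.ndarray  # sizes[k-1] = voxel count of cluster k
    connectivity: int
    grid: VoxelGrid

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


@dataclass
class SubclassMap:
    """Voxelwise map of the four WMH sub-classes (codes 1-4, 0 background)."""

    labels: np.ndarray
    grid: VoxelGrid

    def mask_of(self, subclass: str) -> BinaryMask:
        code = SUBCLASS_CODES[subclass]
        return BinaryMask(self.grid.with_data((self.labels == code).astype(np.uint8)))

    def counts(self) -> dict[str, int]:
        return {
            name: int((self.labels == code).sum())
            for name, code in SUBCLASS_CODES.items()
        }


def label_clusters(wmh: BinaryMask, connectivity: int = 26) -> ClusterLabeling:
    """Label 3D connected components of the WMH mask.

    Parameters
    ----------
    connectivity
        6 (faces), 18 (faces+edges) or 26 (faces+edges+corners).
        26 matches common lesion-analysis practice and is the default.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    raw, k = ndimage.label(wmh.as_bool(), structure=structure)
    labels = _relabel_by_first_voxel(raw, k)
    sizes = np.bincount(labels.ravel(), minlength=k + 1)[1:]
    return ClusterLabeling(
        labels=labels, sizes=sizes, connectivity=connectivity, grid=wmh.grid
    )


def _relabel_by_first_voxel(raw: np.ndarray, k: int) -> np.ndarray:
    """Reassign IDs so cluster k has the k-th smallest first-voxel index."""
    if k == 0:
        return raw.astype(np.int32)
    flat = raw.ravel()
    nz = np.flatnonzero(flat)
    # first occurrence of each label in the C-order scan
    order = np.full(k + 1, flat.size, dtype=np.int64)
    # reversed so earlier occurrences overwrite later ones
    order[flat[nz[::-1]]] = nz[::-1]
    rank = np.empty(k + 1, dtype=np.int32)
    rank[np.argsort(order[1:], kind="stable") + 1] = np.arange(1, k + 1, dtype=np.int32)
    rank[0] = 0
    return rank[raw]


def classify_location(
    clusters: ClusterLabeling, ventricle_ext: BinaryMask
) -> np.ndarray:
    """Periventricular flag per cluster.

    Returns a boolean array of length K where entry ``k-1`` is True iff
    cluster ``k`` has at least one voxel inside the extended ventricle
    mask ("any part of the mask" counts); False means deep.
    """
    _require_same_grid(clusters.grid, ventricle_ext.grid, "clusters", "ventricle_ext")
    k = clusters.n_clusters
    if k == 0:
        return np.zeros(0, dtype=bool)
    overlap = np.bincount(
        clusters.labels.ravel(),
        weights=ventricle_ext.as_bool().ravel(),
        minlength=k + 1,
    )[1:]
    return overlap > 0


def build_extended_ventricle_mask(
    prob_maps: list[VoxelGrid], threshold: float = 0.05
) -> BinaryMask:
    """Union of low-thresholded probability maps.

    The field's reference mask combines lateral ventricles, thalami and
    fornix probability maps at a very low threshold; here any list of
    probability maps on one grid may be combined.  A voxel enters the
    mask iff any map exceeds the threshold.
    """
    if not prob_maps:
        raise ValueError("need at least one probability map")
    ref = prob_maps[0]
    out = np.zeros(ref.shape, dtype=bool)
    for i, pm in enumerate(prob_maps):
        _require_same_grid(ref, pm, "prob_maps[0]", f"prob_maps[{i}]")
        vals = np.asarray(pm.data, dtype=float)
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError(f"prob_maps[{i}] has values outside [0, 1]")
        out |= vals > threshold
    return BinaryMask(ref.with_data(out.astype(np.uint8)))


def combine_subclasses(
    clusters: ClusterLabeling,
    peri_flags: np.ndarray,
    split: IntensitySplit,
) -> SubclassMap:
    """Combine cluster location with voxel intensity into the four codes.

    Location is constant within a cluster; intensity may vary within a
    cluster (a deep cluster can contain both hypo and non-hypo voxels).

    Raises
    ------
    ValueError
        If the intensity split does not cover exactly the clustered WMH
        mask (internal consistency check).
    """
    wmh_bool = clusters.labels > 0
    hypo = split.hypo.as_bool()
    non_hypo = split.non_hypo.as_bool()
    covered = hypo | non_hypo
    if (covered != wmh_bool).any() or (hypo & non_hypo).any():
        raise ValueError(
            "intensity split does not partition the clustered WMH mask "
            f"({int((covered ^ wmh_bool).sum())} inconsistent voxels)"
        )
    if len(peri_flags) != clusters.n_clusters:
        raise ValueError("peri_flags length does not match cluster count")

    peri_lookup = np.zeros(clusters.n_clusters + 1, dtype=bool)
    peri_lookup[1:] = peri_flags
    voxel_peri = peri_lookup[clusters.labels]

    codes = np.zeros(clusters.labels.shape, dtype=np.uint8)
    codes[wmh_bool & voxel_peri & hypo] = SUBCLASS_CODES["peri_hypo"]
    codes[wmh_bool & voxel_peri & non_hypo] = SUBCLASS_CODES["peri_nonhypo"]
    codes[wmh_bool & ~voxel_peri & hypo] = SUBCLASS_CODES["deep_hypo"]
    codes[wmh_bool & ~voxel_peri & non_hypo] = SUBCLASS_CODES["deep_nonhypo"]
    return SubclassMap(labels=codes, grid=clusters.grid)
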