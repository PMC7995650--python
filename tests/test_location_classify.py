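import numpy as np
import pytest

from wmh_subclass.intensity_classify import split_by_pve
from wmh_subclass.location_classify import (
    SUBCLASS_CODES,
    build_extended_ventricle_mask,
    classify_location,
    combine_subclasses,
    label_clusters,
)
from wmh_subclass.phantom import PhantomSpec, generate_subject
from wmh_subclass.volumes_io import GridMismatchError

from _oracles import bfs_label
from conftest import make_grid, make_mask


class TestLabelClusters:
    def test_single_voxel(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 1
        lab = label_clusters(make_mask(data))
        assert lab.n_clusters == 1
        assert lab.sizes.tolist() == [1]

    def test_diagonal_pair_connectivity(self):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1] = 1
        data[2, 2, 2] = 1  # offset (1,1,1): corner neighbours
        assert label_clusters(make_mask(data), 26).n_clusters == 1
        assert label_clusters(make_mask(data), 18).n_clusters == 2
        assert label_clusters(make_mask(data), 6).n_clusters == 2

    def test_edge_pair_connectivity(self):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1] = 1
        data[2, 2, 1] = 1  # offset (1,1,0): edge neighbours
        assert label_clusters(make_mask(data), 18).n_clusters == 1
        assert label_clusters(make_mask(data), 6).n_clusters == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(10):
            mask = rng.random((10, 10, 10)) < 0.3
            lab = label_clusters(make_mask(mask), connectivity)
            _, oracle_sizes = bfs_label(mask, connectivity)
            assert lab.n_clusters == len(oracle_sizes)
            assert sorted(lab.sizes.tolist()) == sorted(oracle_sizes)

    def test_sizes_sum_to_mask(self, rng):
        mask = make_mask(rng.random((12, 12, 12)) < 0.4)
        lab = label_clusters(mask)
        assert int(lab.sizes.sum()) == mask.n_voxels

    def test_ids_ordered_by_first_voxel(self, rng):
        mask = make_mask(rng.random((12, 12, 12)) < 0.2)
        lab = label_clusters(mask)
        flat = lab.labels.ravel()
        first = [np.flatnonzero(flat == k)[0] for k in range(1, lab.n_clusters + 1)]
        assert first == sorted(first)

    def test_every_wmh_voxel_labeled_once(self, rng):
        mask = make_mask(rng.random((9, 9, 9)) < 0.5)
        lab = label_clusters(mask)
        assert np.array_equal(lab.labels > 0, mask.as_bool())

    def test_bad_connectivity(self):
        with pytest.raises(ValueError, match="connectivity"):
            label_clusters(make_mask(np.zeros((2, 2, 2))), 10)


class TestClassifyLocation:
    def test_fully_inside_is_periventricular(self):
        lesion = np.zeros((5, 5, 5))
        lesion[1:3, 1:3, 1:3] = 1
        lab = label_clusters(make_mask(lesion))
        flags = classify_location(lab, make_mask(np.ones((5, 5, 5))))
        assert flags.tolist() == [True]

    def test_zero_overlap_is_deep(self):
        lesion = np.zeros((5, 5, 5))
        lesion[3, 3, 3] = 1
        vent = np.zeros((5, 5, 5))
        vent[0, 0, 0] = 1
        lab = label_clusters(make_mask(lesion))
        assert classify_location(lab, make_mask(vent)).tolist() == [False]

    def test_single_overlap_voxel_suffices(self):
        """One voxel of a 50-voxel cluster inside the mask -> periventricular."""
        lesion = np.zeros((60, 3, 3))
        lesion[:50, 1, 1] = 1
        vent = np.zeros((60, 3, 3))
        vent[0, 1, 1] = 1  # exactly one overlapping voxel
        lab = label_clusters(make_mask(lesion))
        assert lab.sizes.tolist() == [50]
        assert classify_location(lab, make_mask(vent)).tolist() == [True]

    def test_growing_mask_is_monotone(self, rng):
        mask = make_mask(rng.random((12, 12, 12)) < 0.2)
        lab = label_clusters(mask)
        vent = rng.random((12, 12, 12)) < 0.1
        bigger = vent | (rng.random((12, 12, 12)) < 0.1)
        before = classify_location(lab, make_mask(vent))
        after = classify_location(lab, make_mask(bigger))
        assert (after | ~before).all()  # peri stays peri

    def test_grid_mismatch(self):
        lab = label_clusters(make_mask(np.zeros((3, 3, 3))))
        with pytest.raises(GridMismatchError):
            classify_location(lab, make_mask(np.zeros((4, 4, 4))))


class TestExtendedVentricleMask:
    def test_zero_threshold_gives_support(self, rng):
        pm = rng.random((6, 6, 6)) * (rng.random((6, 6, 6)) < 0.3)
        mask = build_extended_ventricle_mask([make_grid(pm)], threshold=0.0)
        assert np.array_equal(mask.as_bool(), pm > 0)

    def test_union_of_disjoint_maps(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0, 0, 0] = 0.9
        b[3, 3, 3] = 0.9
        mask = build_extended_ventricle_mask([make_grid(a), make_grid(b)], 0.05)
        assert mask.n_voxels == 2
        assert mask.data[0, 0, 0] == 1 and mask.data[3, 3, 3] == 1

    def test_matches_max_then_threshold_oracle(self, rng):
        maps = [rng.random((5, 5, 5)) for _ in range(3)]
        mask = build_extended_ventricle_mask([make_grid(m) for m in maps], 0.4)
        oracle = np.maximum.reduce(maps) > 0.4
        assert np.array_equal(mask.as_bool(), oracle)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            build_extended_ventricle_mask([], 0.05)


class TestCombineSubclasses:
    def test_all_peri_all_hypo(self):
        wmh = np.zeros((5, 5, 5))
        wmh[1:4, 1:4, 1:4] = 1
        mask = make_mask(wmh)
        split = split_by_pve(mask, make_grid(np.zeros((5, 5, 5))))  # all hypo
        lab = label_clusters(mask)
        flags = classify_location(lab, make_mask(np.ones((5, 5, 5))))
        smap = combine_subclasses(lab, flags, split)
        assert set(np.unique(smap.labels)) == {0, SUBCLASS_CODES["peri_hypo"]}

    def test_mixed_intensity_within_deep_cluster(self):
        wmh = np.zeros((5, 3, 3))
        wmh[1:4, 1, 1] = 1
        pve = np.zeros((5, 3, 3))
        pve[2, 1, 1] = 0.9  # middle voxel non-hypo
        mask = make_mask(wmh)
        split = split_by_pve(mask, make_grid(pve))
        lab = label_clusters(mask)
        flags = classify_location(lab, make_mask(np.zeros((5, 3, 3))))
        smap = combine_subclasses(lab, flags, split)
        counts = smap.counts()
        assert counts["deep_hypo"] == 2 and counts["deep_nonhypo"] == 1
        assert counts["peri_hypo"] == counts["peri_nonhypo"] == 0

    def test_phantom_ground_truth_recovery(self, small_phantom):
        from dataclasses import replace

        spec = replace(small_phantom, pve_noise_sd=0.0)
        bundle, truth = generate_subject(spec)
        split = split_by_pve(bundle.wmh, bundle.wm_pve)
        lab = label_clusters(bundle.wmh)
        flags = classify_location(lab, bundle.ventricle_ext)
        smap = combine_subclasses(lab, flags, split)
        assert np.array_equal(smap.labels, truth.subclass_codes)

    def test_subclass_counts_partition_wmh(self, rng):
        wmh = make_mask(rng.random((10, 10, 10)) < 0.3)
        split = split_by_pve(wmh, make_grid(rng.random((10, 10, 10))))
        lab = label_clusters(wmh)
        flags = classify_location(lab, make_mask(rng.random((10, 10, 10)) < 0.1))
        smap = combine_subclasses(lab, flags, split)
        assert sum(smap.counts().values()) == wmh.n_voxels

    def test_location_constant_within_cluster(self, rng):
        wmh = make_mask(rng.random((10, 10, 10)) < 0.3)
        split = split_by_pve(wmh, make_grid(rng.random((10, 10, 10))))
        lab = label_clusters(wmh)
        flags = classify_location(lab, make_mask(rng.random((10, 10, 10)) < 0.1))
        smap = combine_subclasses(lab, flags, split)
        peri_voxels = np.isin(smap.labels, [1, 2])
        deep_voxels = np.isin(smap.labels, [3, 4])
        for k in range(1, lab.n_clusters + 1):
            in_k = lab.labels == k
            assert not (peri_voxels[in_k].any() and deep_voxels[in_k].any())

    def test_inconsistent_split_rejected(self):
        wmh = make_mask(np.ones((2, 2, 2)))
        other = make_mask(np.zeros((2, 2, 2)))
        split = split_by_pve(other, make_grid(np.zeros((2, 2, 2))))
        lab = label_clusters(wmh)
        flags = classify_location(lab, make_mask(np.zeros((2, 2, 2))))
        with pytest.raises(ValueError, match="partition"):
            combine_subclasses(lab, flags, split)
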