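"""Panoptic instance decomposition: watershed splitting and assembly."""

import numpy as np
import pytest

from mammoseg import metrics, panoptic

from conftest import make_disc


def dumbbell(shape=(48, 64), c1=(24, 24), c2=(24, 40), r=10):
    """Two overlapping discs forming one connected component."""
    return (make_disc(shape, c1, r) | make_disc(shape, c2, r)).astype(np.uint8)


def random_blobs(rng, shape=(48, 48)):
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(0, 1, shape), 4)
    mask = field > np.percentile(field, 75)
    return mask.astype(np.uint8)


class TestComponentsAndDistance:
    def test_two_discs_two_components(self):
        m = (make_disc((48, 64), (24, 14), 8) | make_disc((48, 64), (24, 50), 8)).astype(np.uint8)
        comps = panoptic.connected_components(m)
        assert len(comps) == 2
        assert sum(c.sum() for c in comps) == m.sum()

    def test_empty_mask_no_components(self):
        assert panoptic.connected_components(np.zeros((16, 16))) == []

    def test_diagonal_touch_is_one_component(self):
        m = np.zeros((16, 16), dtype=np.uint8)
        m[4, 4] = m[5, 5] = m[6, 6] = 1
        assert len(panoptic.connected_components(m)) == 1

    def test_single_pixel_distance_one(self):
        m = np.zeros((16, 16))
        m[8, 8] = 1
        D = panoptic.distance_map(m)
        assert D[8, 8] == 1.0 and D.sum() == 1.0

    def test_square_center_distance(self):
        m = np.zeros((16, 16))
        m[5:10, 5:10] = 1  # 5x5 square
        D = panoptic.distance_map(m)
        assert D[7, 7] == 3.0  # center is 3 px from the nearest background

    def test_disc_max_distance_near_radius(self):
        D = panoptic.distance_map(make_disc((48, 48), (24, 24), 15))
        assert 14.0 <= D.max() <= 15.5

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            panoptic.distance_map(np.zeros((8, 8)))


class TestMarkers:
    def test_single_disc_one_central_marker(self):
        D = panoptic.distance_map(make_disc((48, 48), (24, 24), 15))
        markers = panoptic.instance_markers(D)
        assert len(markers) == 1
        assert np.hypot(*(markers[0] - np.array([24, 24]))) <= 2

    def test_dumbbell_two_markers(self):
        D = panoptic.distance_map(dumbbell())
        markers = panoptic.instance_markers(D)
        assert len(markers) == 2

    def test_huge_h_falls_back_to_single_marker(self):
        D = panoptic.distance_map(dumbbell())
        markers = panoptic.instance_markers(D, h=2 * float(D.max()))
        assert len(markers) == 1


class TestWatershed:
    def test_one_marker_whole_component(self):
        m = make_disc((48, 48), (24, 24), 12)
        D = panoptic.distance_map(m)
        lab = panoptic.watershed_instances(D, np.array([[24, 24]]), m)
        assert np.array_equal(lab > 0, m)

    def test_dumbbell_split_near_neck(self):
        m = dumbbell()
        D = panoptic.distance_map(m)
        markers = panoptic.instance_markers(D)
        lab = panoptic.watershed_instances(D, markers, m)
        assert set(np.unique(lab[m > 0])) == {1, 2}
        assert (lab > 0).sum() == m.sum()  # pixel conservation
        # dividing line within 1 px of the neck minimum (col 32)
        border_cols = np.nonzero((lab[:, :-1] == 1) & (lab[:, 1:] == 2))[1]
        assert np.all(np.abs(border_cols + 0.5 - 32) <= 1.5)
        # each disc center belongs to its own instance
        assert lab[24, 24] != lab[24, 40]

    def test_pixel_conservation_random_blobs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = random_blobs(rng)
            if not m.any():
                continue
            for comp in panoptic.connected_components(m):
                D = panoptic.distance_map(comp)
                markers = panoptic.instance_markers(D)
                lab = panoptic.watershed_instances(D, markers, comp)
                assert (lab > 0).sum() == comp.sum()


class TestMorphAndFilter:
    def test_hole_filled(self):
        m = make_disc((32, 32), (16, 16), 8).astype(np.uint8)
        m[16, 16] = 0
        out = panoptic.morph_regularize(m)
        assert out[16, 16] == 1

    def test_clean_disc_unchanged(self):
        m = make_disc((32, 32), (16, 16), 8).astype(np.uint8)
        assert metrics.dice(m, panoptic.morph_regularize(m)) >= 0.98

    def test_small_satellite_removed(self):
        m = make_disc((32, 32), (16, 12), 7).astype(np.uint8)
        m[4, 28] = m[5, 28] = 1  # 2-px satellite
        out = panoptic.morph_regularize(m)
        assert out[4, 28] == 0 and out[5, 28] == 0

    def test_size_filter_thresholds(self):
        lab = np.zeros((32, 32), dtype=np.int32)
        lab[2:3, 2:5] = 1  # area 3
        lab[10:15, 10:20] = 2  # area 50
        assert set(np.unique(panoptic.size_filter(lab, 5))) == {0, 2}
        assert np.array_equal(panoptic.size_filter(lab, 0), lab)
        with pytest.warns(UserWarning, match="all instances discarded"):
            out = panoptic.size_filter(lab, 51)
        assert out.max() == 0

    def test_tau_monotonicity(self):
        rng = np.random.default_rng(3)
        m = random_blobs(rng)
        counts = []
        for tau in (0, 10, 40, 100):
            pm = panoptic.panoptic_decompose(m, tau=tau)
            counts.append(pm.n_instances)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestMerging:
    def test_deep_separation_not_merged(self):
        # two discs connected by a 1-px bridge: saddle ~1 vs peaks ~8
        m = (make_disc((32, 64), (16, 14), 8) | make_disc((32, 64), (16, 48), 8)).astype(np.uint8)
        m[16, 14:49] = 1
        D = panoptic.distance_map(m)
        markers = panoptic.instance_markers(D)
        lab = panoptic.watershed_instances(D, markers, m)
        out = panoptic.merge_instances(lab, D)
        assert len(np.unique(out[out > 0])) == len(np.unique(lab[lab > 0]))

    def test_shallow_splits_undone(self):
        # one disc artificially cut into three stripes: saddles run through
        # the peak, so the split is maximally shallow
        m = make_disc((48, 48), (24, 24), 15)
        D = panoptic.distance_map(m)
        lab = np.zeros_like(m, dtype=np.int32)
        lab[m & (np.arange(48)[None, :] < 19)] = 1
        lab[m & (np.arange(48)[None, :] >= 19) & (np.arange(48)[None, :] < 29)] = 2
        lab[m & (np.arange(48)[None, :] >= 29)] = 3
        out = panoptic.merge_instances(lab, D)
        assert len(np.unique(out[out > 0])) == 1

    def test_dumbbell_survives_merging(self):
        m = dumbbell()
        pm = panoptic.panoptic_decompose(m, tau=0)
        assert pm.n_instances == 2

    def test_depth_ratio_one_merges_through_peak_splits(self):
        m = make_disc((48, 48), (24, 24), 15)
        D = panoptic.distance_map(m)
        lab = np.zeros_like(m, dtype=np.int32)
        lab[m & (np.arange(48)[None, :] < 24)] = 1
        lab[m & (np.arange(48)[None, :] >= 24)] = 2
        out = panoptic.merge_instances(lab, D, depth_ratio=1.0)
        assert len(np.unique(out[out > 0])) == 1


class TestAssembly:
    def test_consecutive_ids_and_union(self):
        a = make_disc((32, 64), (16, 14), 6)
        b = make_disc((32, 64), (16, 44), 6)
        pm = panoptic.assemble_panoptic((a | b).astype(np.uint8), [b, a])
        assert set(np.unique(pm.instance_ids)) == {0, 1, 2}
        assert metrics.dice(pm.semantic, a | b) == 1.0
        # raster order: the left disc appears first regardless of input order
        assert pm.instance_ids[16, 14] == 1

    def test_empty_instances_empty_map(self):
        pm = panoptic.assemble_panoptic(np.zeros((16, 16), dtype=np.uint8), [])
        assert pm.n_instances == 0 and not pm.semantic.any()

    def test_overlapping_instances_rejected(self):
        a = make_disc((32, 32), (16, 14), 6)
        b = make_disc((32, 32), (16, 18), 6)
        with pytest.raises(ValueError, match="overlapping"):
            panoptic.assemble_panoptic((a | b).astype(np.uint8), [a, b])


class TestDecompose:
    def test_semantic_preservation_exact(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = random_blobs(rng)
            pm = panoptic.panoptic_decompose(m, tau=0)
            assert metrics.dice(m, pm.semantic) == 1.0
            assert np.array_equal(pm.semantic > 0, pm.instance_ids > 0)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        m = random_blobs(rng)
        a = panoptic.panoptic_decompose(m)
        b = panoptic.panoptic_decompose(m)
        assert np.array_equal(a.instance_ids, b.instance_ids)

    def test_provenance_areas_match(self):
        m = dumbbell()
        pm = panoptic.panoptic_decompose(m, tau=0)
        for rec in pm.provenance:
            assert rec["area"] == int((pm.instance_ids == rec["id"]).sum())
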