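import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

import rcpquant as rq
from rcpquant.detect import boundary_perimeter
from rcpquant.scenes import NoiseModel

from conftest import flood_fill_objects


def disk_mask(radius: int, pad: int = 3) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    rr, cc = np.mgrid[0:n, 0:n]
    center = radius + pad
    return np.hypot(rr - center, cc - center) <= radius


class TestSegmentSignals:
    def test_background_only_gives_empty_list(self):
        assert rq.segment_signals(np.zeros((10, 10)), threshold=5.0) == []

    def test_solid_square(self):
        img = np.zeros((10, 10))
        img[3:6, 4:7] = 10.0
        objs = rq.segment_signals(img, threshold=5.0)
        assert len(objs) == 1
        o = objs[0]
        assert o.area_px == 9
        assert o.centroid == (4.0, 5.0)
        # 12 exposed 4-neighbor edges, times the pi/4 taxicab correction
        assert o.perimeter_px == pytest.approx(12 * np.pi / 4)
        assert o.peak_intensity == 10.0
        assert o.peak_location in o.pixels

    def test_diagonal_pixels_are_one_component(self):
        img = np.zeros((5, 5))
        img[1, 1] = img[2, 2] = 9.0
        assert len(rq.segment_signals(img, threshold=5.0)) == 1

    def test_matches_flood_fill_oracle(self, rng):
        """Areas, pixel sets and edge-count perimeters agree with a naive
        8-connected flood fill on random small binary images."""
        for _ in range(20):
            mask = rng.random((12, 14)) < 0.3
            img = mask.astype(float) * 10
            objs = rq.segment_signals(img, threshold=5.0)
            oracle = flood_fill_objects(mask)
            assert len(objs) == len(oracle)
            got = sorted(objs, key=lambda o: min(o.pixels))
            exp = sorted(oracle, key=lambda o: min(o["pixels"]))
            for g, e in zip(got, exp):
                assert set(g.pixels) == e["pixels"]
                assert g.area_px == e["area"]
                perim = np.pi / 4 * e["perimeter"]
                assert g.perimeter_px == pytest.approx(perim)
                circ = min(1.0, 4 * np.pi * e["area"] / perim ** 2)
                assert g.circularity == pytest.approx(circ)

    def test_scene_spots_recovered_at_true_centers(self, compact_scene):
        cfg, stacks, truth = compact_scene
        pair = rq.project(stacks[0])
        thr = rq.mode_threshold(pair.corrected)
        objs = [o for o in rq.segment_signals(pair.corrected, thr.threshold)
                if o.area_px >= 4]
        centers = truth.parent_centers(1)
        tree = cKDTree(centers)
        d, _ = tree.query([o.centroid for o in objs])
        matched = (d <= 1.0).sum()
        assert matched >= 0.95 * len(centers)
        assert (d > 3.0).sum() <= 0.02 * len(centers)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            rq.segment_signals(np.ones((4, 4)), threshold=0.0)


class TestFilterClusters:
    def _obj(self, area, circ):
        return rq.SignalObject(
            label=1, pixels=frozenset({(0, 0)}), centroid=(0.0, 0.0),
            area_px=area, perimeter_px=4.0, circularity=circ,
            peak_intensity=1.0, peak_location=(0, 0))

    @pytest.mark.parametrize("area,circ,kept", [
        (41, 0.9, False),   # larger than 40 px -> removed
        (40, 0.9, True),    # exactly 40 px -> kept
        (10, 0.49, False),  # below 0.5 circularity -> removed
        (10, 0.50, True),   # exactly 0.5 -> kept
    ])
    def test_boundary_rules(self, area, circ, kept):
        out = rq.filter_clusters([self._obj(area, circ)])
        assert (len(out) == 1) is kept

    def test_solid_disk_radius_3_kept(self):
        mask = disk_mask(3)
        assert mask.sum() == 29
        objs = rq.segment_signals(mask.astype(float) * 10, threshold=5.0)
        assert len(objs) == 1
        # oracle: brute-force 4-neighbor boundary edge count, pi/4-corrected
        perim = np.pi / 4 * flood_fill_objects(mask)[0]["perimeter"]
        expected_circ = min(1.0, 4 * np.pi * 29 / perim**2)
        assert objs[0].circularity == pytest.approx(expected_circ)
        assert expected_circ >= 0.5
        assert rq.filter_clusters(objs) == objs

    def test_idempotent_subset(self, rng):
        objs = [self._obj(int(a), float(c))
                for a, c in zip(rng.integers(1, 80, 30), rng.random(30))]
        once = rq.filter_clusters(objs)
        assert rq.filter_clusters(once) == once
        assert all(o in objs for o in once)


class TestDetectMaxima:
    def test_constant_image_no_maxima(self):
        pts = rq.detect_maxima(np.full((20, 20), 5.0))
        assert len(pts) == 0

    def test_single_blob_one_maximum(self):
        rr, cc = np.mgrid[0:41, 0:41]
        img = 100 * np.exp(-((rr - 20.0) ** 2 + (cc - 13.0) ** 2) / (2 * 2.0**2))
        pts = rq.detect_maxima(img, smoothing_sigma_px=1.0)
        assert len(pts) == 1
        assert pts.points[0, 0] == pytest.approx(20, abs=0.5)
        assert pts.points[0, 1] == pytest.approx(13, abs=0.5)

    def test_two_blobs_two_maxima_matching_brute_force(self):
        rr, cc = np.mgrid[0:40, 0:60]
        img = (100 * np.exp(-((rr - 20.0) ** 2 + (cc - 20.0) ** 2) / (2 * 1.5**2))
               + 80 * np.exp(-((rr - 20.0) ** 2 + (cc - 30.0) ** 2) / (2 * 1.5**2)))
        pts = rq.detect_maxima(img, smoothing_sigma_px=1.0)
        assert len(pts) == 2
        # brute-force oracle on the smoothed, median-subtracted array
        sm = ndimage.gaussian_filter(img, 1.0)
        sub = np.clip(sm - np.median(sm), 0, None)
        expected = []
        for r in range(1, 39):
            for c in range(1, 59):
                w = sub[r - 1:r + 2, c - 1:c + 2]
                if sub[r, c] > 0 and sub[r, c] == w.max() and (w < sub[r, c]).sum() == 8:
                    expected.append((r, c))
        got = sorted((round(p[0]), round(p[1])) for p in pts.points[:, :2])
        assert got == sorted(expected)

    def test_plateau_yields_single_centroid_point(self):
        img = np.zeros((11, 11))
        img[4:6, 4:6] = 7.0  # 2x2 flat plateau
        pts = rq.detect_maxima(img, smoothing_sigma_px=0.0)
        assert len(pts) == 1
        assert tuple(pts.points[0, :2]) == (4.5, 4.5)

    def test_min_prominence_suppresses_weak_maxima(self):
        rr, cc = np.mgrid[0:31, 0:31]
        img = (100 * np.exp(-((rr - 10.0) ** 2 + (cc - 10.0) ** 2) / (2 * 1.5**2))
               + 10 * np.exp(-((rr - 20.0) ** 2 + (cc - 20.0) ** 2) / (2 * 1.5**2)))
        strong = rq.detect_maxima(img, smoothing_sigma_px=1.0,
                                  min_prominence=20.0)
        weak = rq.detect_maxima(img, smoothing_sigma_px=1.0)
        assert len(strong) == 1
        assert len(weak) == 2

    def test_dispersed_scene_yields_more_maxima(self, compact_scene,
                                                dispersed_scene):
        """Signal disintegration: the dispersed rendering of the same truth
        produces at least as many local maxima as the compact one."""
        counts = {}
        for name, (_, stacks, _) in (("compact", compact_scene),
                                     ("dispersed", dispersed_scene)):
            pair = rq.project(stacks[0])
            prom = rq.robust_prominence(pair.corrected)
            counts[name] = len(rq.detect_maxima(pair.corrected,
                                                min_prominence=prom))
        assert counts["dispersed"] >= counts["compact"]


def test_colored_point_set_validation():
    with pytest.raises(ValueError):
        rq.ColoredPointSet(np.array([[5.0, 5.0, 3.0]]), (10, 10))
    with pytest.raises(ValueError):
        rq.ColoredPointSet(np.array([[11.0, 5.0, 1.0]]), (10, 10))
    merged = rq.ColoredPointSet.merge(
        rq.ColoredPointSet(np.array([[1.0, 1.0, 1.0]]), (10, 10)),
        rq.ColoredPointSet(np.array([[2.0, 2.0, 2.0]]), (10, 10)))
    assert len(merged) == 2
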