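import numpy as np
import pytest
from scipy import stats

import rcpquant as rq
from rcpquant.scenes import NoiseModel


class TestPixelOverlap:
    def test_identical_masks_full_overlap(self):
        img = np.zeros((20, 20))
        img[5:8, 5:8] = 10.0
        res = rq.pixel_overlap(img, img.copy(), binarization_threshold=5.0,
                               smoothing_sigma_px=0)
        assert res.overlap_fraction == 1.0

    def test_disjoint_masks_zero_overlap(self):
        a = np.zeros((20, 20)); a[2:5, 2:5] = 10.0
        b = np.zeros((20, 20)); b[10:13, 10:13] = 10.0
        res = rq.pixel_overlap(a, b, binarization_threshold=5.0,
                               smoothing_sigma_px=0)
        assert res.overlap_fraction == 0.0
        assert res.n_union_px == 18

    def test_toy_masks_match_set_arithmetic(self):
        a = np.zeros((4, 4)); b = np.zeros((4, 4))
        a[0, 0] = a[0, 1] = a[1, 0] = a[1, 1] = 10.0   # 4 px
        b[1, 1] = b[1, 0] = b[2, 2] = b[3, 3] = 10.0   # 4 px, 2 shared
        res = rq.pixel_overlap(a, b, binarization_threshold=5.0,
                               smoothing_sigma_px=0)
        assert res.n_intersection_px == 2
        assert res.n_union_px == 6
        assert res.overlap_fraction == pytest.approx(2 / 6)

    def test_random_masks_match_set_oracle(self, rng):
        """IoU equals explicit set arithmetic on 100 random <=16x16 masks."""
        for _ in range(100):
            h, w = rng.integers(4, 17, size=2)
            a = (rng.random((h, w)) < 0.3) * 10.0
            b = (rng.random((h, w)) < 0.3) * 10.0
            res = rq.pixel_overlap(a, b, binarization_threshold=5.0,
                                   smoothing_sigma_px=0)
            sa = {(r, c) for r, c in zip(*np.nonzero(a))}
            sb = {(r, c) for r, c in zip(*np.nonzero(b))}
            assert res.n_intersection_px == len(sa & sb)
            assert res.n_union_px == len(sa | sb)
            if sa | sb:
                assert res.overlap_fraction == len(sa & sb) / len(sa | sb)
            else:
                assert res.overlap_fraction == 0.0 and res.empty_union

    def test_symmetric_in_channels(self, rng):
        a = rng.uniform(0, 20, size=(30, 30))
        b = rng.uniform(0, 20, size=(30, 30))
        r1 = rq.pixel_overlap(a, b, binarization_threshold=10.0)
        r2 = rq.pixel_overlap(b, a, binarization_threshold=10.0)
        assert r1.overlap_fraction == r2.overlap_fraction

    def test_union_monotone_in_threshold(self, rng):
        a = rng.uniform(0, 20, size=(30, 30))
        b = rng.uniform(0, 20, size=(30, 30))
        unions = [rq.pixel_overlap(a, b, binarization_threshold=t).n_union_px
                  for t in (5.0, 10.0, 15.0)]
        assert unions[0] >= unions[1] >= unions[2]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rq.pixel_overlap(np.zeros((4, 4)), np.zeros((5, 5)), 1.0)


class TestClassifySolutionRCPs:
    def _pair(self):
        return np.zeros((40, 40)), np.zeros((40, 40))

    def test_single_pixel_rejected(self):
        ch1, ch2 = self._pair()
        ch1[5, 5] = 100.0
        entities, frac = rq.classify_solution_rcps(ch1, ch2)
        assert entities == [] and frac == 0.0

    @pytest.mark.parametrize("size,kept", [(2, True), (30, True), (31, False)])
    def test_size_gate_endpoints(self, size, kept):
        ch1, ch2 = np.zeros((10, 80)), np.zeros((10, 80))
        ch1[4, 5:5 + size] = 100.0
        entities, _ = rq.classify_solution_rcps(ch1, ch2)
        assert (len(entities) == 1) is kept

    def test_pmt_threshold_boundary(self):
        ch1, ch2 = self._pair()
        ch1[5, 5:8] = 34.0  # just below: background
        entities, _ = rq.classify_solution_rcps(ch1, ch2)
        assert entities == []
        ch1[5, 5:8] = 35.0  # at threshold: signal
        entities, _ = rq.classify_solution_rcps(ch1, ch2)
        assert len(entities) == 1
        assert entities[0].class_label == "ch1_only"

    def test_dual_entities_merged_across_channels(self):
        ch1, ch2 = self._pair()
        ch1[10, 10:14] = 50.0
        ch2[10, 12:16] = 50.0  # overlaps ch1 object at (10,12..13)
        entities, frac = rq.classify_solution_rcps(ch1, ch2)
        assert len(entities) == 1
        assert entities[0].class_label == "dual"
        assert entities[0].area_px == 6
        assert frac == 1.0

    def test_engineered_dual_fraction(self, rng):
        """100 single-channel objects + 10 engineered dual objects on a
        grid: dual fraction 10/110."""
        ch1 = np.zeros((140, 140))
        ch2 = np.zeros((140, 140))
        spots = [(r, c) for r in range(5, 140, 13) for c in range(5, 140, 13)]
        for i, (r, c) in enumerate(spots[:110]):
            if i < 50:
                ch1[r, c:c + 3] = 60.0
            elif i < 100:
                ch2[r, c:c + 3] = 60.0
            else:
                ch1[r, c:c + 3] = 60.0
                ch2[r, c:c + 3] = 60.0
        entities, frac = rq.classify_solution_rcps(ch1, ch2)
        assert len(entities) == 110
        assert frac == pytest.approx(10 / 110)

    def test_mean_positivity_flag(self):
        ch1, ch2 = self._pair()
        ch1[5, 5:9] = 100.0
        ch2[5, 5] = 100.0  # one hot pixel; mean over footprint 25 < 35
        ents_any, _ = rq.classify_solution_rcps(ch1, ch2, positivity="any")
        assert ents_any[0].class_label == "dual"
        ents_mean, _ = rq.classify_solution_rcps(ch1, ch2, positivity="mean")
        assert ents_mean[0].class_label == "ch1_only"


class TestDoseResponse:
    def test_identical_groups_f_near_zero(self):
        g = {"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [1.0, 2, 3]}
        res = rq.dose_response_test(g)
        assert res["anova_F"] == pytest.approx(0.0, abs=1e-12)
        assert res["anova_p"] == pytest.approx(1.0)

    def test_one_shifted_group_separated_by_lsd(self, rng):
        g = {
            "a": list(rng.normal(0, 1, 10)),
            "b": list(rng.normal(0, 1, 10)),
            "c": list(rng.normal(5, 1, 10)),
        }
        res = rq.dose_response_test(g)
        assert res["anova_p"] < 0.001
        assert res["post_hoc"]["a vs c"]["p_value"] < 0.001
        assert res["post_hoc"]["b vs c"]["p_value"] < 0.001
        assert res["post_hoc"]["a vs b"]["p_value"] > 0.05

    def test_two_groups_equals_pooled_t_test(self, rng):
        a = list(rng.normal(0, 1, 8))
        b = list(rng.normal(1, 1, 8))
        res = rq.dose_response_test({"a": a, "b": b})
        t_p = stats.ttest_ind(a, b).pvalue
        assert res["anova_p"] == pytest.approx(t_p, rel=1e-9)
        assert res["post_hoc"]["a vs b"]["p_value"] == pytest.approx(t_p,
                                                                     rel=1e-9)

    def test_zero_variance_pair_excluded(self):
        g = {"a": [2.0, 2.0], "b": [1.0, 2.0, 3.0], "c": [4.0, 5.0, 6.0]}
        res = rq.dose_response_test(g)
        assert res["excluded_from_post_hoc"] == ["a"]
        assert "b vs c" in res["post_hoc"]
        assert "a vs b" not in res["post_hoc"]

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            rq.dose_response_test({"a": [1.0, 2.0]})


def test_independent_compact_channels_overlap_below_one_percent(compact_scene):
    cfg, stacks, _ = compact_scene
    pairs = [rq.project(s) for s in stacks]
    thr = rq.mode_threshold(pairs[0].corrected)
    res = rq.pixel_overlap(pairs[0].corrected, pairs[1].corrected,
                           binarization_threshold=thr.threshold)
    assert res.overlap_fraction < 0.01


def test_forced_co_occupancy_raises_overlap():
    """Placing a fraction of the two colors' RCPs at shared positions
    produces detectably higher overlap than independent placement."""
    base = rq.SceneConfig(image_shape=(256, 256), n_spots_per_color=(40, 40),
                          seed=6)
    stacks, truth = rq.generate_scene(base)
    pairs = [rq.project(s) for s in stacks]
    thr = rq.mode_threshold(pairs[0].corrected)
    independent = rq.pixel_overlap(pairs[0].corrected, pairs[1].corrected,
                                   binarization_threshold=thr.threshold)
    # co-occupancy: render channel 2's spots at channel 1's positions by
    # reusing channel 1's stack for a fraction of the field
    forced = stacks[1].copy()
    forced[:, :, :128] = stacks[0][:, :, :128]
    pair2 = rq.project(forced)
    coforced = rq.pixel_overlap(pairs[0].corrected, pair2.corrected,
                                binarization_threshold=thr.threshold)
    assert coforced.overlap_fraction > independent.overlap_fraction + 0.05
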