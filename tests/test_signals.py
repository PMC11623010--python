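import numpy as np
import pytest
from skimage import draw

from sishscore.preprocess import RoiImage
from sishscore.signals import (
    CEP17,
    HER2,
    Spot,
    SpotDetectionConfig,
    detect_spots,
    remove_background,
    remove_faint,
)
from sishscore.synthetic import (
    BACKGROUND_RGB,
    CEP17_RGB,
    HER2_RGB,
    SyntheticSpec,
    generate_roi,
    rasterize_nucleus,
)

RES = 0.13


def blank_canvas(h=200, w=200):
    img = np.empty((h, w, 3))
    img[...] = BACKGROUND_RGB
    return img


def paint_disk(img, rc, radius_px, rgb):
    rr, cc = draw.disk(rc, radius_px, shape=img.shape[:2])
    img[rr, cc] = rgb


def as_roi(img, image_id="t"):
    return RoiImage((img * 255).astype(np.uint8), RES, image_id)


DOT_R = 0.45 / RES  # singleton dot radius in px


class TestRemoveBackground:
    def test_uniform_white_is_all_background(self):
        roi = RoiImage(np.full((32, 32, 3), 255, dtype=np.uint8))
        assert not remove_background(roi).any()

    def test_degenerate_thresholds(self):
        roi = RoiImage(np.full((32, 32, 3), 255, dtype=np.uint8))
        # nothing exceeds a whiteness threshold of 1 -> no background at all
        assert remove_background(roi, whiteness_threshold=1.0).all()
        # everything exceeds 0 -> all background
        assert not remove_background(roi, whiteness_threshold=0.0).any()

    def test_planted_nucleus_area_recovered(self):
        spec = SyntheticSpec(n_nuclei=1, image_size=(256, 256), seed=3)
        roi, truth = generate_roi(spec)
        mask = remove_background(roi)
        planted = rasterize_nucleus(truth.nuclei[0], (256, 256)).sum()
        assert abs(int(mask.sum()) - int(planted)) <= 0.05 * planted


class TestDetectSpots:
    def test_blank_image_yields_no_spots(self):
        roi = as_roi(blank_canvas())
        assert detect_spots(roi, HER2) == []
        assert detect_spots(roi, CEP17) == []

    def test_planted_isolated_dots_recovered_with_centroids(self):
        img = blank_canvas(260, 260)
        her2_at = [(40, 40), (40, 120), (40, 200), (120, 40), (120, 120)]
        cep17_at = [(200, 60), (200, 130), (200, 200)]
        for rc in her2_at:
            paint_disk(img, rc, DOT_R, HER2_RGB)
        for rc in cep17_at:
            paint_disk(img, rc, DOT_R, CEP17_RGB)
        roi = as_roi(img)
        her2 = detect_spots(roi, HER2)
        cep17 = detect_spots(roi, CEP17)
        assert len(her2) == 5 and len(cep17) == 3
        for spots, planted in ((her2, her2_at), (cep17, cep17_at)):
            for s in spots:
                d = min(np.hypot(s.centroid_rc[0] - r, s.centroid_rc[1] - c)
                        for r, c in planted)
                assert d <= 2.0

    def test_cluster_decomposed_by_area_ratio(self):
        img = blank_canvas(260, 260)
        for rc in [(40, 40), (40, 120), (40, 200), (120, 40), (120, 120)]:
            paint_disk(img, rc, DOT_R, HER2_RGB)
        paint_disk(img, (200, 130), DOT_R * np.sqrt(3), HER2_RGB)  # 3x area
        spots = detect_spots(as_roi(img), HER2,
                             SpotDetectionConfig(cluster_split=True))
        counts = sorted(s.signal_count for s in spots)
        assert counts == [1, 1, 1, 1, 1, 3]
        no_split = detect_spots(as_roi(img), HER2,
                                SpotDetectionConfig(cluster_split=False))
        assert all(s.signal_count == 1 for s in no_split)

    def test_size_bounds_exclude_out_of_range_components(self):
        img = blank_canvas()
        paint_disk(img, (60, 60), 1.0, HER2_RGB)    # below 0.4 µm diameter
        paint_disk(img, (140, 140), 18.0, HER2_RGB)  # above 2.5 µm equivalent
        assert detect_spots(as_roi(img), HER2) == []

    def test_missing_resolution_is_an_error(self):
        cfg = SpotDetectionConfig()
        with pytest.raises(ValueError, match="resolution"):
            cfg.area_bounds_px(0)

    def test_channel_exclusivity_on_pure_color_dots(self):
        spec = SyntheticSpec(
            n_nuclei=10, image_size=(512, 512), seed=21,
            per_nucleus_her2=("fixed", 3), per_nucleus_cep17=("fixed", 2),
        )
        roi, truth = generate_roi(spec)
        her2 = detect_spots(roi, HER2)
        cep17 = detect_spots(roi, CEP17)
        planted_her2 = [d.center_rc for n in truth.nuclei for d in n.her2_dots]
        planted_cep17 = [d.center_rc for n in truth.nuclei for d in n.cep17_dots]

        def nearest(spot, planted):
            return min(np.hypot(spot.centroid_rc[0] - r, spot.centroid_rc[1] - c)
                       for r, c in planted)

        assert all(nearest(s, planted_her2) <= 2 for s in her2)
        assert all(nearest(s, planted_cep17) <= 2 for s in cep17)
        # no red dot reported as HER2 and vice versa
        assert all(nearest(s, planted_cep17) > 2 for s in her2)
        assert all(nearest(s, planted_her2) > 2 for s in cep17)

    def test_count_conserved_under_concatenation(self):
        spec_a = SyntheticSpec(n_nuclei=5, image_size=(320, 320), seed=31,
                               per_nucleus_her2=("fixed", 4))
        spec_b = SyntheticSpec(n_nuclei=5, image_size=(320, 320), seed=32,
                               per_nucleus_her2=("fixed", 4))
        roi_a, _ = generate_roi(spec_a)
        roi_b, _ = generate_roi(spec_b)
        combined = RoiImage(
            np.concatenate([roi_a.pixels, roi_b.pixels], axis=1), RES, "ab"
        )
        for channel in (HER2, CEP17):
            n_a = len(detect_spots(roi_a, channel))
            n_b = len(detect_spots(roi_b, channel))
            n_ab = len(detect_spots(combined, channel))
            assert n_ab == n_a + n_b


class TestRemoveFaint:
    def _spots(self, contrasts):
        return [
            Spot(HER2, (5.0, 5.0), 40, 1, c) for c in contrasts
        ]

    def test_zero_threshold_is_vacuous(self):
        spots = self._spots([0.1, 0.5, 0.9])
        assert remove_faint(spots, 0.0) == spots

    def test_maximal_threshold_removes_everything(self):
        assert remove_faint(self._spots([0.1, 0.5, 0.99]), 1.0) == []

    def test_planted_faint_dots_removed_at_intermediate_threshold(self):
        img = blank_canvas(260, 260)
        strong_at = [(40, 40), (40, 130), (130, 40), (130, 130)]
        faint_rgb = (0.28, 0.28, 0.29)  # still dark enough to be a candidate
        for rc in strong_at:
            paint_disk(img, rc, DOT_R, HER2_RGB)
        for rc in [(200, 80), (200, 180)]:
            paint_disk(img, rc, DOT_R, faint_rgb)
        spots = detect_spots(as_roi(img), HER2)
        assert len(spots) == 6
        contrasts = sorted(s.contrast for s in spots)
        threshold = (contrasts[1] + contrasts[2]) / 2  # between the two levels
        kept = remove_faint(spots, threshold)
        assert len(kept) == 4

    def test_filter_is_monotone_subset(self):
        spots = self._spots([0.2, 0.4, 0.6, 0.8])
        prev = spots
        for threshold in (0.1, 0.3, 0.5, 0.7, 0.9):
            kept = remove_faint(spots, threshold)
            assert set(id(s) for s in kept) <= set(id(s) for s in prev)
            prev = kept
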