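import numpy as np
import pytest
from skimage import draw

from sishscore.nuclei import (
    NucleusRecord,
    assign_spots,
    filter_by_cep17,
    filter_overlapping,
    filter_truncated,
    qualify_nuclei,
    segment_nuclei,
)
from sishscore.preprocess import RoiImage
from sishscore.signals import CEP17, HER2, Spot, detect_all_spots
from sishscore.synthetic import (
    BACKGROUND_RGB,
    NUCLEUS_RGB,
    SyntheticSpec,
    generate_roi,
    rasterize_nucleus,
)

RES = 0.13


def record(label, her2=0, cep17=0, area=1000):
    return NucleusRecord(label, area, (10.0, 10.0), her2, cep17)


class TestSegmentation:
    def test_blank_image_gives_empty_label_map(self):
        roi = RoiImage(np.full((96, 96, 3), 255, dtype=np.uint8), RES)
        assert segment_nuclei(roi).max() == 0

    def test_well_separated_nuclei_each_get_one_label(self):
        spec = SyntheticSpec(n_nuclei=12, image_size=(512, 512), seed=4)
        roi, truth = generate_roi(spec)
        labels = segment_nuclei(roi)
        assert labels.max() == 12
        hit = [
            labels[int(round(n.center_rc[0])), int(round(n.center_rc[1]))]
            for n in truth.nuclei
        ]
        assert len(set(hit)) == 12 and 0 not in hit

    def test_touching_pair_separated_by_watershed(self):
        img = np.empty((256, 256, 3))
        img[...] = BACKGROUND_RGB
        r = 34
        centers = [(128, 100), (128, 100 + int(1.5 * r))]
        for rc in centers:
            rr, cc = draw.disk(rc, r, shape=(256, 256))
            img[rr, cc] = NUCLEUS_RGB
        roi = RoiImage((img * 255).astype(np.uint8), RES)
        labels = segment_nuclei(roi)
        assert labels.max() == 2
        assert labels[centers[0]] != labels[centers[1]] != 0

    def test_segmentation_is_deterministic(self):
        spec = SyntheticSpec(n_nuclei=8, image_size=(448, 448), seed=9,
                             noise_sd=3.0)
        roi, _ = generate_roi(spec)
        assert np.array_equal(segment_nuclei(roi), segment_nuclei(roi))


class TestAssignSpots:
    def _label_disk(self, shape=(100, 100), center=(50, 50), radius=20, label=1):
        labels = np.zeros(shape, dtype=np.int32)
        rr, cc = draw.disk(center, radius, shape=shape)
        labels[rr, cc] = label
        return labels

    def test_background_spot_contributes_nowhere(self):
        labels = self._label_disk()
        spots = [Spot(HER2, (5.0, 5.0), 40)]
        records = assign_spots(labels, spots)
        assert len(records) == 1 and records[0].her2_count == 0

    def test_planted_counts_and_differentiation(self):
        spec = SyntheticSpec(n_nuclei=6, image_size=(448, 448), seed=14,
                             per_nucleus_her2=("fixed", 6),
                             per_nucleus_cep17=("fixed", 2))
        roi, truth = generate_roi(spec)
        labels = segment_nuclei(roi)
        records = assign_spots(labels, detect_all_spots(roi))
        assert len(records) == 6
        for rec in records:
            assert (rec.her2_count, rec.cep17_count) == (6, 2)
            assert rec.differentiation == 4

    def test_cluster_spot_contributes_its_multiplicity(self):
        labels = self._label_disk()
        spots = [Spot(HER2, (50.0, 50.0), 120, signal_count=3)]
        records = assign_spots(labels, spots)
        assert records[0].her2_count == 3

    def test_out_of_bounds_spot_is_an_error(self):
        labels = self._label_disk()
        with pytest.raises(ValueError, match="outside"):
            assign_spots(labels, [Spot(HER2, (500.0, 500.0), 40)])

    def test_assignment_conserves_signal_mass(self):
        spec = SyntheticSpec(n_nuclei=8, image_size=(448, 448), seed=15,
                             per_nucleus_her2=("uniform", 2, 6))
        roi, _ = generate_roi(spec)
        labels = segment_nuclei(roi)
        spots = detect_all_spots(roi)
        records = assign_spots(labels, spots)
        total = sum(s.signal_count for s in spots if s.channel == HER2)
        assigned = sum(r.her2_count for r in records)
        ignored = sum(
            s.signal_count
            for s in spots
            if s.channel == HER2
            and labels[int(round(s.centroid_rc[0])), int(round(s.centroid_rc[1]))] == 0
        )
        assert assigned + ignored == total


class TestFilterTruncated:
    def test_interior_kept_edge_touching_excluded(self):
        labels = np.zeros((50, 50), dtype=np.int32)
        labels[0:10, 20:30] = 1   # touches row 0
        labels[20:30, 20:30] = 2  # interior
        records = [record(1), record(2)]
        kept = filter_truncated(records, labels)
        assert [r.label for r in kept] == [2]
        assert records[0].touches_border and not records[1].touches_border

    def test_planted_edge_clipped_nuclei_excluded(self):
        spec = SyntheticSpec(n_nuclei=13, image_size=(576, 576), seed=33,
                             edge_clip_fraction=3 / 13)
        roi, truth = generate_roi(spec)
        labels = segment_nuclei(roi)
        records = assign_spots(labels, detect_all_spots(roi))
        kept = filter_truncated(records, labels)
        interior_centers = [
            n.center_rc for n in truth.nuclei if not n.truncated
        ]
        assert len(interior_centers) == 10
        kept_labels = {r.label for r in kept}
        for r, c in interior_centers:
            assert labels[int(round(r)), int(round(c))] in kept_labels
        for n in truth.nuclei:
            if n.truncated:
                lab = labels[
                    min(575, max(0, int(round(n.center_rc[0])))),
                    min(575, max(0, int(round(n.center_rc[1])))),
                ]
                assert lab not in kept_labels


class TestFilterOverlapping:
    def test_disjoint_nuclei_retained(self):
        m1 = np.zeros((40, 40), dtype=bool)
        m2 = np.zeros((40, 40), dtype=bool)
        m1[5:15, 5:15] = True
        m2[25:35, 25:35] = True
        records = [record(1), record(2)]
        kept = filter_overlapping(records, {1: m1, 2: m2})
        assert len(kept) == 2
        assert all(r.max_overlap_fraction == 0.0 for r in kept)

    def test_asymmetric_overlap_rule(self):
        # A: 100 px with 60 px intersecting B (300 px): A removed, B kept
        m_a = np.zeros((60, 60), dtype=bool)
        m_b = np.zeros((60, 60), dtype=bool)
        m_a[0:10, 0:10] = True          # 100 px
        m_b[4:10, 0:50] = True          # 300 px, intersection 6x10 = 60 px
        records = [record(1, area=100), record(2, area=300)]
        kept = filter_overlapping(records, {1: m_a, 2: m_b})
        assert [r.label for r in kept] == [2]
        assert records[0].max_overlap_fraction == pytest.approx(0.6)
        assert records[1].max_overlap_fraction == pytest.approx(0.2)

    def test_mutual_excess_removes_both(self):
        m1 = np.zeros((30, 30), dtype=bool)
        m2 = np.zeros((30, 30), dtype=bool)
        m1[0:10, 0:10] = True
        m2[0:10, 4:14] = True  # 60/100 both ways
        kept = filter_overlapping([record(1), record(2)], {1: m1, 2: m2})
        assert kept == []

    def test_random_ellipse_pairs_match_rasterized_oracle(self, rng):
        from sishscore.synthetic import NucleusTruth

        for _ in range(100):
            c1 = rng.uniform(30, 70, size=2)
            c2 = c1 + rng.uniform(-25, 25, size=2)
            n1 = NucleusTruth(tuple(c1), tuple(rng.uniform(8, 16, size=2)),
                              float(rng.uniform(0, 180)))
            n2 = NucleusTruth(tuple(c2), tuple(rng.uniform(8, 16, size=2)),
                              float(rng.uniform(0, 180)))
            m1 = rasterize_nucleus(n1, (100, 100))
            m2 = rasterize_nucleus(n2, (100, 100))
            records = [record(1, area=int(m1.sum())), record(2, area=int(m2.sum()))]
            kept = filter_overlapping(records, {1: m1, 2: m2})
            inter = np.logical_and(m1, m2).sum()
            expect = [
                lab for lab, m in ((1, m1), (2, m2))
                if inter / m.sum() <= 0.5
            ]
            assert [r.label for r in kept] == expect

    def test_no_masks_passes_through(self):
        records = [record(1), record(2)]
        assert filter_overlapping(records, None) == records


class TestFilterByCep17:
    def test_strict_filter(self):
        records = [record(i + 1, cep17=c) for i, c in enumerate([0, 1, 2, 3])]
        kept, fallback = filter_by_cep17(records)
        assert [r.cep17_count for r in kept] == [2, 3]
        assert fallback is False

    def test_single_cep17_fallback(self):
        records = [record(i + 1, cep17=1) for i in range(5)]
        kept, fallback = filter_by_cep17(records)
        assert len(kept) == 5 and fallback is True

    def test_fallback_with_nothing_to_admit(self):
        records = [record(i + 1, cep17=0) for i in range(3)]
        kept, fallback = filter_by_cep17(records)
        assert kept == [] and fallback is True

    def test_fallback_disabled(self):
        records = [record(1, cep17=1)]
        kept, fallback = filter_by_cep17(records, allow_fallback=False)
        assert kept == [] and fallback is False


class TestQualificationChain:
    def test_filters_return_subsets_and_are_relabel_invariant(self):
        spec = SyntheticSpec(n_nuclei=10, image_size=(512, 512), seed=41,
                             edge_clip_fraction=0.2)
        roi, _ = generate_roi(spec)
        labels = segment_nuclei(roi)
        spots = detect_all_spots(roi)
        records = assign_spots(labels, spots)
        qualified, _ = qualify_nuclei(records, labels)
        assert {r.label for r in qualified} <= {r.label for r in records}

        # permute instance IDs; the qualified set must be the same nuclei
        perm = np.zeros(labels.max() + 1, dtype=np.int32)
        perm[1:] = np.random.default_rng(0).permutation(labels.max()) + 1
        relabeled = perm[labels]
        records2 = assign_spots(relabeled, spots)
        qualified2, _ = qualify_nuclei(records2, relabeled)
        key = lambda recs: sorted(
            (r.area_px, r.her2_count, r.cep17_count) for r in recs
        )
        assert key(qualified) == key(qualified2)
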