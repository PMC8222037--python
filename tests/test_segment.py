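import numpy as np
import pandas as pd
import pytest

import msiquant as mq
from msiquant.design import CalibrationDesign, SectionRole
from msiquant.images import IonImage
from msiquant.segment import (
    AnnotationError,
    NoTissueError,
    annotate_rois,
    combine_maps,
    detect_spots,
    jaccard,
    segment_tissue,
)


def log_image(values):
    return IonImage(np.asarray(values, float), 616.1767, 0.005, "log10")


class TestSegmentTissue:
    def test_two_squares_found(self):
        img = np.full((30, 30), 1.0)
        img[2:12, 2:12] = 6.0
        img[15:25, 15:25] = 6.0
        out = segment_tissue(log_image(img), min_area_px=20)
        assert len(out) == 2
        assert sorted(r.pixel_count for r in out.rois) == [100, 100]

    def test_uniform_image_raises_no_tissue(self):
        with pytest.raises(NoTissueError):
            segment_tissue(log_image(np.full((20, 20), 3.0)))

    def test_fixed_threshold_method(self):
        img = np.full((20, 20), 1.0)
        img[5:15, 5:15] = 6.0
        out = segment_tissue(log_image(img), min_area_px=10, method="fixed", threshold=4.0)
        assert len(out) == 1 and out.rois[0].pixel_count == 100

    def test_min_area_filter_drops_specks(self):
        img = np.full((30, 30), 1.0)
        img[2:12, 2:12] = 6.0
        img[20:24, 20:24] = 6.0  # 16 px blob
        out = segment_tissue(log_image(img), min_area_px=20)
        assert len(out) == 1

    def test_labels_ordered_row_major(self):
        img = np.full((40, 40), 1.0)
        img[25:35, 2:12] = 6.0   # lower-left
        img[2:12, 25:35] = 6.0   # upper-right
        out = segment_tissue(log_image(img), min_area_px=20)
        assert out.rois[0].centroid[0] < out.rois[1].centroid[0]

    def test_otsu_invariant_to_additive_shift(self):
        """Adding a constant to the log image (global intensity scaling on
        the linear scale) leaves the re-estimated segmentation unchanged."""
        img = np.full((30, 30), 1.0)
        img[2:12, 2:12] = 6.0
        img[15:25, 15:25] = 6.0
        a = segment_tissue(log_image(img), min_area_px=20)
        b = segment_tissue(log_image(img + 2.7), min_area_px=20)
        assert np.array_equal(a.labels, b.labels)

    def test_generator_slide_recovered_against_ground_truth(self):
        grid, truth = mq.generate_slide(mq.default_calibration_spec(seed=1))
        heme = mq.log_transform(
            mq.extract_ion_image(grid, mq.builtin_targets()["hemeB"].mz)
        )
        tissue = segment_tissue(heme)
        assert len(tissue) == len(truth.sections)
        for i in range(len(truth.sections)):
            gt = truth.section_mask(i)
            best = max(jaccard(tissue.mask(r.id), gt) for r in tissue.rois)
            assert best >= 0.95


class TestDetectSpots:
    def test_blob_above_threshold_detected(self):
        img = np.full((10, 10), np.nan)
        img[4, 4:7] = 6.0
        img[5, 4:6] = 6.0
        out = detect_spots(log_image(img), threshold=5.6, min_area_px=3)
        assert len(out) == 1
        assert out.rois[0].pixel_count == 5
        assert out.rois[0].kind == "calibration-spot"

    def test_threshold_monotone(self):
        img = np.full((10, 10), np.nan)
        img[4, 4:7] = 6.0
        img[5, 4:6] = 6.0
        assert len(detect_spots(log_image(img), threshold=6.5, min_area_px=3)) == 0

    def test_raising_threshold_never_adds_spots(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(4.0, 7.0, size=(30, 30))
        counts = [
            len(detect_spots(log_image(img), threshold=t, min_area_px=1))
            for t in np.linspace(4.0, 7.0, 12)
        ]
        # spot count can merge/split, but the masked area is monotone
        areas = [
            sum(r.pixel_count for r in detect_spots(log_image(img), t, 1).rois)
            for t in np.linspace(4.0, 7.0, 12)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_area_filter(self):
        img = np.full((20, 20), np.nan)
        img[2:12, 2:12] = 6.0  # 100 px, too big
        out = detect_spots(log_image(img), min_area_px=3, max_area_px=50)
        assert len(out) == 0

    def test_empty_result_is_not_an_error(self):
        out = detect_spots(log_image(np.full((5, 5), 1.0)))
        assert len(out) == 0


class TestAnnotate:
    def grid_design(self):
        rows = []
        for i in range(4):
            for j in range(5):
                rows.append(
                    dict(
                        spot_id=f"R{i}C{j}",
                        row_hint=5.0 + 7 * i,
                        col_hint=5.0 + 7 * j,
                        conc_ng_per_ul=[0.2, 2, 5, 20, 40][j],
                        drop_volume_ul=0.5,
                        lipid_mg_per_g=0.0,
                        replicate=i + 1,
                    )
                )
        return CalibrationDesign(spots=pd.DataFrame(rows))

    def detected(self, jitter=0.0, drop=None, rng=None):
        img = np.full((40, 40), np.nan)
        centers = []
        while True:  # keep jittered blobs disjoint so 20 spots stay 20 blobs
            centers = [
                (
                    5 + 7 * i + (rng.normal(0, jitter) if jitter else 0),
                    5 + 7 * j + (rng.normal(0, jitter) if jitter else 0),
                )
                for i in range(4)
                for j in range(5)
                if drop != (i, j)
            ]
            d = [
                np.hypot(a[0] - b[0], a[1] - b[1])
                for k, a in enumerate(centers)
                for b in centers[k + 1:]
            ]
            if not jitter or min(d) > 5.5:
                break
        for r, c in centers:
            rr, cc = np.ogrid[:40, :40]
            img[(rr - r) ** 2 + (cc - c) ** 2 <= 4] = 6.0
        return detect_spots(log_image(img), min_area_px=3)

    def test_bijective_assignment(self):
        out = annotate_rois(self.detected(), self.grid_design())
        ids = {r.annotation["spot_id"] for r in out.rois}
        assert len(ids) == 20
        amounts = {r.annotation["amount_ng"] for r in out.rois}
        assert amounts == {0.1, 1.0, 2.5, 10.0, 20.0}

    def test_missing_spot_strict_errors_with_cell_name(self):
        with pytest.raises(AnnotationError, match="R2C3"):
            annotate_rois(self.detected(drop=(2, 3)), self.grid_design())

    def test_jittered_centers_still_bijective(self):
        rng = np.random.default_rng(17)
        out = annotate_rois(self.detected(jitter=0.5, rng=rng), self.grid_design())
        for r in out.rois:
            i, j = int(r.annotation["replicate"]) - 1, None
            # recover design position from id and check it is the nearest
            sid = r.annotation["spot_id"]
            i, j = int(sid[1]), int(sid[3])
            assert abs(r.centroid[0] - (5 + 7 * i)) < 3.5
            assert abs(r.centroid[1] - (5 + 7 * j)) < 3.5

    def test_ambiguous_match_errors(self):
        img = np.full((20, 20), np.nan)
        img[4:6, 4:6] = 6.0
        img[8:10, 4:6] = 6.0  # both nearest to the single design cell
        spots = detect_spots(log_image(img), min_area_px=3)
        design = CalibrationDesign(
            spots=pd.DataFrame(
                [
                    dict(spot_id="only", row_hint=6.0, col_hint=5.0,
                         conc_ng_per_ul=5.0, drop_volume_ul=0.5,
                         lipid_mg_per_g=0.0, replicate=1),
                    dict(spot_id="far", row_hint=50.0, col_hint=50.0,
                         conc_ng_per_ul=5.0, drop_volume_ul=0.5,
                         lipid_mg_per_g=0.0, replicate=2),
                ]
            )
        )
        with pytest.raises(AnnotationError, match="ambiguous"):
            annotate_rois(spots, design)

    def test_section_roles_assigned(self):
        img = np.full((30, 60), 1.0)
        img[5:15, 5:15] = 6.0
        img[5:15, 30:40] = 6.0
        tissue = segment_tissue(log_image(img), min_area_px=20)
        design = CalibrationDesign(
            spots=pd.DataFrame(
                {c: [] for c in ["spot_id", "row_hint", "col_hint", "conc_ng_per_ul",
                                  "drop_volume_ul", "lipid_mg_per_g", "replicate"]}
            ),
            sections=[SectionRole("sample", 10, 10), SectionRole("control-2.5ng", 10, 35)],
        )
        out = annotate_rois(tissue, design)
        roles = {r.annotation["role"] for r in out.rois}
        assert roles == {"sample", "control-2.5ng"}


def test_combine_maps_carves_spots_out_of_tissue():
    img = np.full((20, 20), 1.0)
    img[2:12, 2:12] = 6.0
    tissue = segment_tissue(log_image(img), min_area_px=20)
    spot_img = np.full((20, 20), np.nan)
    spot_img[5:8, 5:8] = 6.0
    spots = detect_spots(log_image(spot_img), min_area_px=3)
    combined = combine_maps(tissue, spots)
    kinds = [r.kind for r in combined.rois]
    assert kinds == ["tissue-section", "calibration-spot"]
    assert combined.rois[0].pixel_count == 100 - 9
    assert combined.rois[1].pixel_count == 9


def test_roi_label_map_invariants():
    from msiquant.segment import Roi, RoiLabelMap

    labels = np.zeros((4, 4), int)
    labels[0, 0] = 1
    with pytest.raises(ValueError, match="dense"):
        RoiLabelMap(labels, [Roi(2, "calibration-spot", 1, (0.0, 0.0))])
    with pytest.raises(ValueError, match="cardinality"):
        RoiLabelMap(labels, [Roi(1, "calibration-spot", 5, (0.0, 0.0))])
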