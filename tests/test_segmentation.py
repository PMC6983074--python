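"""Pupil segmentation, centroid, corners, ROI partition, eye gate."""

import numpy as np
import pytest

from icpcv import segmentation as seg
from icpcv import synth

from conftest import random_eye_geometry


def brute_force_centroid(mask: np.ndarray):
    """Independent double-loop center-of-gravity accumulation."""
    sx = sy = n = 0.0
    for y in range(mask.shape[0]):
        for x in range(mask.shape[1]):
            if mask[y, x]:
                sx += x
                sy += y
                n += 1
    return sx / n, sy / n


class TestPartition:
    def test_stated_four_by_five_partition(self):
        left, right = seg.partition_face_rois(seg.RoiBox(0, 0, 100, 100))
        assert (left.y0, left.y1) == (25, 50)
        assert (left.x0, left.x1) == (20, 40)
        assert (right.x0, right.x1) == (60, 80)

    def test_translation_equivariance(self):
        base = seg.partition_face_rois(seg.RoiBox(0, 0, 100, 100))
        moved = seg.partition_face_rois(seg.RoiBox(10, 10, 110, 110))
        for b, m in zip(base, moved):
            assert m == b.shift(10, 10)

    def test_boxes_disjoint_and_contained(self, rng):
        for _ in range(20):
            x0, y0 = rng.integers(0, 50, 2)
            w, h = rng.integers(20, 200, 2)
            face = seg.RoiBox(int(x0), int(y0), int(x0 + w), int(y0 + h))
            left, right = seg.partition_face_rois(face)
            for box in (left, right):
                assert face.x0 <= box.x0 < box.x1 <= face.x1
                assert face.y0 <= box.y0 < box.y1 <= face.y1
            assert left.x1 <= right.x0  # disjoint columns
            # the two eye columns cover 2/5 of the band width (floor division)
            assert left.width == right.width == face.width // 5

    def test_too_small_face_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            seg.partition_face_rois(seg.RoiBox(0, 0, 4, 3))

    def test_ground_truth_eye_centers_inside_rois(self):
        frame, truth = synth.render_face()
        left, right = seg.partition_face_rois(seg.RoiBox(*truth.face_box))
        for box, eye in ((left, truth.left), (right, truth.right)):
            x, y = eye.pupil_center
            assert box.x0 <= x < box.x1 and box.y0 <= y < box.y1


class TestCropEyebrow:
    @pytest.mark.parametrize(
        "roi, expected",
        [
            (seg.RoiBox(0, 0, 10, 30), (10, 20)),
            (seg.RoiBox(0, 25, 10, 50), (33, 41)),
        ],
    )
    def test_middle_third(self, roi, expected):
        out = seg.crop_eyebrow(roi)
        assert (out.y0, out.y1) == expected
        assert (out.x0, out.x1) == (roi.x0, roi.x1)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            seg.crop_eyebrow(seg.RoiBox(0, 0, 10, 2))

    def test_excludes_rendered_eyebrow(self):
        # band proportions mirror the face partition: the eye sits mid-band
        # with the brow in the top third
        geom = synth.EyeGeometry(
            eye_center=(40.0, 24.0),
            eye_half_width=20.0,
            eye_half_height=8.0,
            pupil_center=(40.0, 24.0),
            pupil_radius=4.0,
            eyebrow=True,
        )
        frame = synth.render_eye_region(geom, frame_shape=(48, 80))
        roi = seg.crop_eyebrow(seg.RoiBox(0, 0, 80, 48))
        patch = roi.crop(frame)
        assert (frame == geom.eyebrow_intensity).any()  # brow was rendered
        assert not (patch == geom.eyebrow_intensity).any()


class TestSegmentPupil:
    def test_uniform_roi_raises_no_pupil(self):
        frame = np.full((40, 40), 200, dtype=np.uint8)
        with pytest.raises(seg.NoPupilError):
            seg.segment_pupil(frame, seg.RoiBox(0, 0, 40, 40))

    def test_disk_area_recovered(self):
        frame = np.full((60, 60), 220, dtype=np.uint8)
        yy, xx = np.mgrid[0:60, 0:60]
        frame[(xx - 30) ** 2 + (yy - 30) ** 2 <= 36] = 20
        mask = seg.segment_pupil(frame, seg.RoiBox(0, 0, 60, 60))
        area = mask.mask.sum()
        assert abs(area - np.pi * 36) / (np.pi * 36) < 0.15

    def test_largest_component_kept(self):
        frame = np.full((40, 80), 220, dtype=np.uint8)
        frame[10:15, 10:20] = 20  # 50 px blob
        frame[25:29, 50:55] = 20  # 20 px blob
        mask = seg.segment_pupil(frame, seg.RoiBox(0, 0, 80, 40))
        ys, xs = np.nonzero(mask.mask)
        assert xs.max() < 30  # only the larger blob survives

    def test_idempotent_on_own_output(self):
        frame = np.full((60, 60), 220, dtype=np.uint8)
        yy, xx = np.mgrid[0:60, 0:60]
        frame[(xx - 30) ** 2 + (yy - 30) ** 2 <= 64] = 20
        first = seg.segment_pupil(frame, seg.RoiBox(0, 0, 60, 60))
        binary = np.where(first.mask, 0, 255).astype(np.uint8)
        second = seg.segment_pupil(binary, seg.RoiBox(0, 0, 60, 60))
        assert np.array_equal(first.mask, second.mask)


class TestPupilCentroid:
    def test_single_pixel(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[7, 5] = True
        np.testing.assert_allclose(
            seg.pupil_centroid(seg.PupilMask(mask, (0, 0))), (5.0, 7.0)
        )

    def test_symmetric_block(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[9:12, 9:12] = True
        np.testing.assert_allclose(
            seg.pupil_centroid(seg.PupilMask(mask, (0, 0))), (10.0, 10.0)
        )

    def test_matches_brute_force_on_random_masks(self, rng):
        """Center of gravity equals the double-loop oracle exactly."""
        for _ in range(100):
            mask = rng.random((20, 20)) < 0.3
            if not mask.any():
                mask[0, 0] = True
            ox, oy = rng.integers(0, 50, 2)
            got = seg.pupil_centroid(seg.PupilMask(mask, (int(ox), int(oy))))
            ex, ey = brute_force_centroid(mask)
            assert got[0] == ex + ox and got[1] == ey + oy

    def test_empty_mask_raises(self):
        with pytest.raises(seg.NoPupilError):
            seg.pupil_centroid(seg.PupilMask(np.zeros((5, 5), dtype=bool), (0, 0)))


class TestEyeCorners:
    def test_ellipse_extremes(self, centered_eye):
        frame = synth.render_eye_region(centered_eye)
        roi = seg.RoiBox(0, 0, frame.shape[1], frame.shape[0])
        left, right = seg.detect_eye_corners(frame, roi)
        assert np.linalg.norm(left - (20, 25)) <= 1.5
        assert np.linalg.norm(right - (60, 25)) <= 1.5

    def test_vertical_edge_midpoint_rule(self):
        """Full-height vertical contour runs resolve to the run's vertical
        midpoint row on both sides."""
        frame = np.full((21, 40), 220, dtype=np.uint8)
        frame[:, 18:22] = 20  # dark vertical bar, two vertical contours
        roi = seg.RoiBox(0, 0, 40, 21)
        left, right = seg.detect_eye_corners(frame, roi)
        assert 15 <= left[0] <= 18 and 21 <= right[0] <= 25
        assert 8 <= left[1] <= 12 and 8 <= right[1] <= 12

    def test_no_contour_raises(self):
        frame = np.full((30, 30), 128, dtype=np.uint8)
        with pytest.raises(seg.NoCornerError):
            seg.detect_eye_corners(frame, seg.RoiBox(0, 0, 30, 30))

    def test_translation_equivariance(self, centered_eye):
        frame = synth.render_eye_region(centered_eye, frame_shape=(80, 120))
        dx, dy = 15, 9
        shifted = np.full_like(frame, frame[0, 0])
        shifted[dy:, dx:] = frame[:-dy, :-dx]
        roi = seg.RoiBox(5, 5, 75, 45)
        base_c = seg.pupil_centroid(seg.segment_pupil(frame, roi))
        move_c = seg.pupil_centroid(
            seg.segment_pupil(shifted, roi.shift(dx, dy))
        )
        np.testing.assert_allclose(move_c, base_c + (dx, dy))
        bl, br = seg.detect_eye_corners(frame, roi)
        ml, mr = seg.detect_eye_corners(shifted, roi.shift(dx, dy))
        np.testing.assert_allclose(ml, bl + (dx, dy))
        np.testing.assert_allclose(mr, br + (dx, dy))


class TestEyeGate:
    def test_frontal_face_detected_with_true_box(self):
        frame, truth = synth.render_face()
        ok, box = seg.detect_eyes_present(frame)
        assert ok
        got = np.array([box.x0, box.y0, box.x1, box.y1])
        assert np.abs(got - np.array(truth.face_box)).max() <= 10

    def test_blank_frame_not_detected(self):
        frame = np.full((480, 640), 128, dtype=np.uint8)
        ok, box = seg.detect_eyes_present(frame)
        assert not ok and box is None

    def test_fixture_detector_returns_truth(self):
        frame, truth = synth.render_face()
        ok, box = seg.detect_eyes_present(frame, seg.FixtureDetector(truth))
        assert ok and (box.x0, box.y0, box.x1, box.y1) == truth.face_box

    def test_yaw_sweep_flags_match_rotation_ground_truth(self):
        """Detection succeeds exactly where the inter-pupil tilt stays
        within the detector's tolerance."""
        det = seg.PupilPairDetector()
        for yaw in np.arange(-10, 10.1, 2.5):
            frame, truth = synth.render_face(yaw=yaw)
            ok, _ = seg.detect_eyes_present(frame, det)
            assert ok == (abs(yaw) <= det.max_tilt_deg)


class TestEndToEndLandmarks:
    def test_mirror_flag_swaps_corner_roles(self):
        frame, truth = synth.render_face()
        face = seg.RoiBox(*truth.face_box)
        normal = seg.extract_landmarks(frame, face)
        mirrored = seg.extract_landmarks(
            frame, face, seg.SegmentationConfig(mirror_view=True)
        )
        np.testing.assert_allclose(
            normal.inner_corner["left"], mirrored.outer_corner["left"]
        )

    def test_landmarks_recover_face_ground_truth(self):
        frame, truth = synth.render_face()
        lm = seg.extract_landmarks(frame, seg.RoiBox(*truth.face_box))
        for eye, t in (("left", truth.left), ("right", truth.right)):
            assert np.linalg.norm(lm.pupil_center[eye] - t.pupil_center) <= 1.0
            assert np.linalg.norm(lm.inner_corner[eye] - t.inner_corner) <= 2.0
            assert np.linalg.norm(lm.outer_corner[eye] - t.outer_corner) <= 2.0
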