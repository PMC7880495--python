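"""Geometric calibration: lens fit, homography, rectification."""

import numpy as np
import pytest

from scintdose.camera import CameraModel, FieldSpec, SceneConfig, make_chessboard_image, project_to_frame, make_dose_field
from scintdose.geometry import (
    GeometryCalibration,
    Homography,
    LensModel,
    calibrate_geometry,
    detect_chessboard_corners,
    fit_homography,
    fit_lens_model,
    rectify,
)
from scintdose.pipeline import (
    calibrate_geometry_synthetic,
    default_camera,
    _board_cameras,
)


class TestHomography:
    def test_identity_from_identical_points(self, rng):
        pts = rng.uniform(0, 100, (20, 2))
        hom = fit_homography(pts, pts)
        assert np.allclose(hom.matrix, np.eye(3), atol=1e-9)

    def test_exact_minimal_solve_reproduces_warp(self, rng):
        true = np.array([[1.2, 0.1, 5.0], [-0.05, 0.9, -3.0], [1e-3, -2e-3, 1.0]])
        src = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 80.0], [100.0, 80.0]])
        dst = Homography(true).apply(src)
        hom = fit_homography(src, dst)
        probe = rng.uniform(0, 100, (50, 2))
        assert np.abs(hom.apply(probe) - Homography(true).apply(probe)).max() < 1e-6

    def test_noisy_correspondences_reprojection(self, rng):
        true = Homography(np.array([[0.9, 0.2, 10.0], [-0.1, 1.1, 4.0],
                                    [5e-4, -8e-4, 1.0]]))
        src = np.stack(np.meshgrid(np.linspace(0, 200, 11),
                                   np.linspace(0, 140, 8)), -1).reshape(-1, 2)
        assert len(src) == 88
        dst = true.apply(src) + rng.normal(0, 0.3, (88, 2))
        hom = fit_homography(src, dst)
        err = np.linalg.norm(hom.apply(src) - true.apply(src), axis=1)
        assert err.mean() <= 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_homography(np.zeros((3, 2)), np.zeros((3, 2)))

    def test_degenerate_configuration_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError):
            fit_homography(src, src * 2)

    def test_composition(self, rng):
        h1 = Homography(np.array([[1.0, 0.1, 3.0], [0.0, 1.2, -2.0], [0, 0, 1.0]]))
        h2 = Homography(np.array([[0.8, 0.0, 1.0], [0.05, 1.0, 4.0], [1e-4, 0, 1.0]]))
        pts = rng.uniform(-50, 50, (30, 2))
        assert np.allclose(h2.compose(h1).apply(pts), h2.apply(h1.apply(pts)))

    def test_normalization_and_invertibility(self):
        hom = Homography(np.diag([2.0, 2.0, 2.0]))
        assert hom.matrix[2, 2] == 1.0
        with pytest.raises(ValueError):
            Homography(np.ones((3, 3)))


class TestLensModel:
    def test_undistort_distort_identity_on_sensor(self):
        lens = LensModel(350, 350, 159.5, 119.5, k1=-0.2, k2=0.01,
                         p1=5e-4, p2=-5e-4)
        uu, vv = np.meshgrid(np.linspace(0, 319, 24), np.linspace(0, 239, 18))
        px = np.stack([uu.ravel(), vv.ravel()], -1)
        back = lens.distort_points(lens.undistort_points(px))
        assert np.abs(back - px).max() < 0.05

    def test_zero_distortion_board_fit(self):
        cam = default_camera(k1=0.0, k2=0.0, p1=0.0, p2=0.0)
        views = _board_cameras(cam, 3)
        boards = [make_chessboard_image(c) for c in views]
        fit = fit_lens_model([b.corners_px for b in boards],
                             boards[0].corners_mm, cam.sensor_shape,
                             init_focal_px=cam.fx)
        assert abs(fit.lens.k1) < 1e-3
        assert abs(fit.lens.k2) < 1e-3
        assert fit.rms_px < 0.1

    def test_k1_recovery_within_5_percent(self):
        cam = default_camera(k1=-0.2)
        views = _board_cameras(cam, 3)
        boards = [make_chessboard_image(c) for c in views]
        fit = fit_lens_model([b.corners_px for b in boards],
                             boards[0].corners_mm, cam.sensor_shape,
                             init_focal_px=cam.fx)
        assert fit.lens.k1 == pytest.approx(-0.2, rel=0.05)

    def test_undistorted_true_corners_match_pinhole(self):
        cam = default_camera()
        board = make_chessboard_image(cam)
        fitcam = CameraModel(cam.fx, cam.fy, cam.cx, cam.cy,
                             position_mm=cam.position_mm, rotation=cam.rotation,
                             sensor_shape=cam.sensor_shape)  # no distortion
        ideal = fitcam.project(board.corners_mm)
        lens = LensModel(cam.fx, cam.fy, cam.cx, cam.cy, cam.k1, cam.k2,
                         cam.p1, cam.p2)
        undist = lens.undistort_points(board.corners_px)
        assert np.abs(undist - ideal).max() < 0.1

    def test_too_few_corners_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_lens_model([np.zeros((4, 2))], np.zeros((4, 2)), (240, 320))


class TestRectify:
    def test_default_grid_pitch_is_0p086_mm(self):
        hom = Homography(np.eye(3))
        calib = GeometryCalibration(LensModel(350, 350, 159.5, 119.5), hom)
        assert calib.pitch_mm == 176.0 / 2048
        assert round(calib.pitch_mm, 3) == 0.086

    def test_constant_frame_rectifies_to_constant(self, geometry_calib):
        frame = np.full((240, 320), 7.5)
        plane = rectify(frame, geometry_calib)
        inside = plane.values[plane.mask]
        assert inside.size > 0
        assert np.allclose(inside, 7.5, atol=1e-6)

    def test_square_field_edges_at_true_positions(self, bench_camera, geometry_calib):
        cfg = SceneConfig(
            poisson_gain=0.0, read_noise_sd=0.0, hot_pixel_rate=0.0,
            background=0.0, inhom_amplitude=0.0, optical_blur_sigma_px=0.0,
        )
        plane100 = make_dose_field(
            FieldSpec(width_mm=100, height_mm=100, penumbra_mm=0, dose_cgy=100.0)
        )
        frame = project_to_frame(plane100, bench_camera, cfg).mean(axis=-1)
        rect = rectify(frame, geometry_calib)
        pos, prof = rect.profile("x")
        half = prof[np.argmin(np.abs(pos))] / 2
        left = np.interp(half, prof[pos < 0], pos[pos < 0])
        right = np.interp(-half, -prof[pos > 0], pos[pos > 0])
        assert abs(left - (-50.0)) < geometry_calib.pitch_mm
        assert abs(right - 50.0) < geometry_calib.pitch_mm

    def test_out_of_view_flagged_not_raised(self, geometry_calib):
        # the full sensor covers the whole output grid ...
        full = rectify(np.ones((240, 320)), geometry_calib)
        assert full.mask.all()
        # ... a cropped frame leaves part of the grid out of view: flagged
        # and zeroed, never an exception
        cropped = rectify(np.ones((120, 320)), geometry_calib)
        assert not cropped.mask.all()
        assert cropped.mask.any()
        assert np.all(cropped.values[~cropped.mask] == 0.0)

    def test_rotated_detector_gives_same_field_mask(self, bench_camera, geometry_calib):
        # rotating the delivered pattern 90 deg about the beam axis must not
        # change the rectified, brightness-corrected field shape (rotational
        # invariance of the geometric calibration); binary masks at the 50%
        # cut must agree on >= 99.8% of pixels
        cfg = SceneConfig(poisson_gain=0.0, read_noise_sd=0.0,
                          hot_pixel_rate=0.0, background=0.0,
                          inhom_amplitude=0.0, optical_blur_sigma_px=0.0)
        cam, calib = bench_camera, geometry_calib
        flat = make_dose_field(
            FieldSpec(width_mm=220, height_mm=220, penumbra_mm=0, dose_cgy=100.0)
        )
        rflat = rectify(project_to_frame(flat, cam, cfg).mean(-1), calib).values

        specs = [((0.0, -30.0), 100.0, 10.0), ((0.0, 0.0), 100.0, 20.0),
                 ((0.0, 35.0), 100.0, 40.0)]
        rot90 = np.array([[0.0, -1.0], [1.0, 0.0]])
        stripes = make_dose_field([FieldSpec(c, w, h, 4.0, 100.0)
                                   for c, w, h in specs])
        stripes_rot = make_dose_field([FieldSpec(tuple(rot90 @ c), h, w, 4.0, 100.0)
                                       for c, w, h in specs])
        r1 = rectify(project_to_frame(stripes, cam, cfg).mean(-1), calib).values / rflat
        r2 = rectify(project_to_frame(stripes_rot, cam, cfg).mean(-1), calib).values / rflat
        # undo the physical rotation in the rectified frame: with y
        # increasing along rows, (x, y) -> (-y, x) unmaps as rot90
        r2 = np.rot90(r2, k=1)
        m1 = r1 >= 0.5 * r1.max()
        m2 = r2 >= 0.5 * r2.max()
        assert np.mean(m1 == m2) >= 0.998


def test_calibration_json_roundtrip(tmp_path, geometry_calib):
    path = tmp_path / "geometry.json"
    geometry_calib.to_json(path)
    back = GeometryCalibration.from_json(path)
    assert np.allclose(back.homography.matrix, geometry_calib.homography.matrix)
    assert back.lens == geometry_calib.lens
    assert back.pitch_mm == geometry_calib.pitch_mm


def test_image_based_corner_detection_matches_truth():
    cam = default_camera()
    board = make_chessboard_image(cam)
    detected = detect_chessboard_corners(board.image, board.n_corners)
    # same set of corners, in some consistent grid order
    d2 = ((detected[:, None, :] - board.corners_px[None, :, :]) ** 2).sum(-1)
    nearest = d2.min(axis=1)
    assert np.sqrt(nearest).max() < 1.0


def test_production_mode_calibration_close_to_test_mode(bench_camera):
    test_mode = calibrate_geometry_synthetic(bench_camera, grid_pixels=256,
                                             use_true_corners=True)
    prod_mode = calibrate_geometry_synthetic(bench_camera, grid_pixels=256,
                                             use_true_corners=False)
    assert prod_mode.lens.k1 == pytest.approx(test_mode.lens.k1, rel=0.15)
    # both map the isocenter to nearly the same sensor position
    iso_test = test_mode.homography.inverse().apply([[0.0, 0.0]])
    iso_prod = prod_mode.homography.inverse().apply([[0.0, 0.0]])
    assert np.linalg.norm(iso_test - iso_prod) < 1.0
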