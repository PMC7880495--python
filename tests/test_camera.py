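"""Synthetic scene generator: dose fields, projection physics, acquisitions."""

import numpy as np
import pytest

from scintdose.camera import (
    CameraModel,
    FieldSpec,
    SceneConfig,
    inhomogeneity_map,
    make_chessboard_image,
    make_dose_field,
    project_to_frame,
    render_acquisition,
)
from scintdose.pipeline import default_camera


class TestMakeDoseField:
    def test_hard_edged_field_pixel_exact(self):
        plane = make_dose_field(
            FieldSpec(width_mm=100, height_mm=100, penumbra_mm=0, dose_cgy=100),
            side_mm=300, pitch_mm=1.0,
        )
        assert np.count_nonzero(plane.values == 100.0) == 100 * 100
        assert np.count_nonzero(plane.values) == 100 * 100

    def test_penumbra_width_matches_80_20_distance(self):
        plane = make_dose_field(
            FieldSpec(penumbra_mm=6.0, dose_cgy=100.0), side_mm=300, pitch_mm=0.1
        )
        pos, prof = plane.profile("x")
        d0 = prof[np.argmin(np.abs(pos))]
        right = prof[pos > 0]
        xr = pos[pos > 0]
        x80 = np.interp(-0.8 * d0, -right, xr)
        x20 = np.interp(-0.2 * d0, -right, xr)
        assert x20 - x80 == pytest.approx(6.0, abs=0.1)

    def test_pyramid_superposition_center_dose(self):
        sizes = [20.0, 50.0, 100.0, 200.0]
        fields = [
            FieldSpec(width_mm=s, height_mm=s, penumbra_mm=5.0, dose_cgy=100.0)
            for s in sizes
        ]
        pyramid = make_dose_field(fields, side_mm=300, pitch_mm=1.0)
        separate = [make_dose_field(f, side_mm=300, pitch_mm=1.0) for f in fields]
        assert np.allclose(
            pyramid.values, np.sum([p.values for p in separate], axis=0)
        )
        assert pyramid.central_value() == pytest.approx(
            sum(p.central_value() for p in separate), rel=1e-9
        )

    def test_field_exceeding_grid_is_rejected_by_index(self):
        with pytest.raises(ValueError, match="field 1"):
            make_dose_field(
                [FieldSpec(width_mm=50, height_mm=50),
                 FieldSpec(center_mm=(140, 0), width_mm=50, height_mm=50)],
                side_mm=300,
            )


class TestCameraModel:
    def test_project_backproject_roundtrip(self):
        cam = default_camera()
        pts = np.array([[0.0, 0.0], [70.0, 55.0], [-88.0, 30.0], [95.0, -95.0]])
        px = cam.project(pts)
        back, dist, valid = cam.pixel_to_plane(px[:, 0], px[:, 1])
        assert valid.all()
        assert np.abs(back - pts).max() < 1e-9
        assert np.allclose(dist, np.linalg.norm(
            np.hstack([pts, np.zeros((4, 1))]) - cam.position_mm, axis=1))

    def test_undistort_inverts_distort(self):
        cam = default_camera()
        xy = np.random.default_rng(0).uniform(-0.4, 0.4, (200, 2))
        assert np.abs(cam.undistort_normalized(cam.distort_normalized(xy)) - xy).max() < 1e-10

    def test_pose_off_plane_required(self):
        with pytest.raises(ValueError, match="off the scintillator"):
            CameraModel(fx=300, fy=300, cx=100, cy=100,
                        position_mm=np.array([0.0, -100.0, 0.0]))

    def test_pose_viewing_away_rejected(self):
        cam = CameraModel.look_at((0.0, -260.0, 180.0), (0.0, -260.0, 400.0),
                                  fx=350, fy=350, cx=159.5, cy=119.5)
        with pytest.raises(ValueError, match="does not view"):
            cam.check_views_plane()


class TestProjectToFrame:
    def _small_field_cfg(self, **over):
        base = dict(
            intervals=[(0.0, 1.0)],
            field_sets=[[FieldSpec(width_mm=20, height_mm=20, penumbra_mm=0,
                                   dose_cgy=100.0)]],
            inhom_amplitude=0.0, optical_blur_sigma_px=0.0,
            poisson_gain=0.0, read_noise_sd=0.0, hot_pixel_rate=0.0,
            background=0.0,
        )
        base.update(over)
        return SceneConfig(**base)

    def test_inverse_square_intensity_ratio(self):
        # the same plane viewed from twice the distance is 4x dimmer
        plane = make_dose_field(
            FieldSpec(width_mm=30, height_mm=30, penumbra_mm=0, dose_cgy=100.0)
        )
        d0 = 400.0
        cfg = self._small_field_cfg(reference_distance_mm=d0)
        near = CameraModel.look_at((0, 0, 300.0), fx=700, fy=700, cx=159.5, cy=119.5)
        far = CameraModel.look_at((0, 0, 600.0), fx=1400, fy=1400, cx=159.5, cy=119.5)
        f_near = project_to_frame(plane, near, cfg)
        f_far = project_to_frame(plane, far, cfg)
        # doubled focal length keeps the pixel footprint identical
        center = (slice(110, 130), slice(150, 170))
        ratio = f_near[center].sum() / f_far[center].sum()
        assert ratio == pytest.approx(4.0, rel=0.02)

    def test_zero_dose_frame_is_background_plus_read_noise(self):
        plane = make_dose_field(FieldSpec(dose_cgy=0.0))
        cfg = self._small_field_cfg(background=5.0, read_noise_sd=0.4)
        rng = np.random.default_rng(0)
        frame = project_to_frame(plane, default_camera(), cfg, rng)
        n = frame.size
        assert abs(frame.mean() - 5.0) < 3 * 0.4 / np.sqrt(n)

    def test_channel_split_fractions(self):
        plane = make_dose_field(FieldSpec(width_mm=80, height_mm=80, dose_cgy=200.0))
        cfg = self._small_field_cfg()
        frame = project_to_frame(plane, default_camera(), cfg)
        fractions = frame.sum(axis=(0, 1)) / frame.sum()
        assert np.allclose(fractions, [0.105, 0.515, 0.380], atol=0.01)

    def test_linearity_in_dose(self):
        cam = default_camera()
        cfg = self._small_field_cfg()
        p1 = make_dose_field(FieldSpec(width_mm=50, height_mm=50, dose_cgy=50.0))
        p2 = make_dose_field(FieldSpec(width_mm=50, height_mm=50, dose_cgy=150.0))
        f1 = project_to_frame(p1, cam, cfg)
        f2 = project_to_frame(p2, cam, cfg)
        assert np.allclose(f2, 3.0 * f1, atol=1e-4)


class TestRenderAcquisition:
    def test_three_bursts_give_three_segments(self):
        cfg = SceneConfig(
            intervals=[(0.2, 0.6), (1.0, 1.4), (1.8, 2.2)],
            field_sets=[[FieldSpec(dose_cgy=50.0)]] * 3,
            duration_s=2.5,
        )
        stack, truth = render_acquisition(cfg, default_camera(), seed=0)
        assert len(truth.segments) == 3
        assert stack.n_frames == 60
        total = np.sum([p.values for p in truth.segment_planes], axis=0)
        assert np.allclose(total, truth.cumulative.values)

    def test_hot_pixel_count_is_poisson(self):
        lam = 20.0
        cfg = SceneConfig(
            intervals=[], field_sets=[], duration_s=200 / 24.0,
            hot_pixel_rate=lam, poisson_gain=0.0, read_noise_sd=0.0,
        )
        _, truth = render_acquisition(cfg, default_camera(), seed=5)
        counts = np.array(truth.hot_pixel_counts)
        assert len(counts) == 200
        assert abs(counts.mean() - lam) < 3 * np.sqrt(lam / 200)

    def test_same_seed_bit_identical(self):
        cfg = SceneConfig(duration_s=1.0)
        cam = default_camera()
        s1, _ = render_acquisition(cfg, cam, seed=9)
        s2, _ = render_acquisition(cfg, cam, seed=9)
        assert np.array_equal(s1.frames, s2.frames)

    def test_empty_timeline_is_background_stack(self):
        cfg = SceneConfig(intervals=[], field_sets=[], duration_s=0.5,
                          hot_pixel_rate=0.0)
        stack, truth = render_acquisition(cfg, default_camera(), seed=0)
        assert truth.segments == []
        assert stack.n_frames == 12
        assert float(stack.frames.mean()) < 5 * 0.2 + 1.0


class TestChessboard:
    def test_identity_camera_gives_equally_spaced_corners(self):
        cam = CameraModel.look_at((0.0, 0.0, 400.0), fx=500, fy=500,
                                  cx=159.5, cy=119.5)
        board = make_chessboard_image(cam, n_squares=(5, 7))
        grid = board.corners_px.reshape(4, 6, 2)
        dx = np.diff(grid[..., 0], axis=1)
        dy = np.diff(grid[..., 1], axis=0)
        assert np.allclose(dx, dx.flat[0], atol=1e-9)
        assert np.allclose(dy, dy.flat[0], atol=1e-9)

    def test_radial_distortion_grows_with_radius(self):
        pos, f = (0.0, 0.0, 400.0), 500.0
        straight = CameraModel.look_at(pos, fx=f, fy=f, cx=159.5, cy=119.5)
        bent = CameraModel.look_at(pos, fx=f, fy=f, cx=159.5, cy=119.5, k1=-0.2)
        b0 = make_chessboard_image(straight, n_squares=(5, 7))
        b1 = make_chessboard_image(bent, n_squares=(5, 7))
        shift = np.linalg.norm(b1.corners_px - b0.corners_px, axis=1)
        radius = np.linalg.norm(b0.corners_px - [159.5, 119.5], axis=1)
        order = np.argsort(radius)
        # monotone trend: largest-radius corners move the most
        assert shift[order][-5:].min() > shift[order][:5].max()

    def test_true_corners_lie_on_rendered_edges(self):
        cam = default_camera()
        board = make_chessboard_image(cam)
        img = board.image
        grad = np.hypot(*np.gradient(img))
        # every true corner must sit within 0.5 px of a strong edge
        for u, v in board.corners_px:
            r, c = int(round(v)), int(round(u))
            window = grad[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
            assert window.max() > 0.2 * grad.max()

    def test_board_not_in_view_rejected(self):
        cam = CameraModel.look_at((0.0, 0.0, 120.0), fx=800, fy=800,
                                  cx=159.5, cy=119.5)
        with pytest.raises(ValueError, match="does not fit"):
            make_chessboard_image(cam, n_squares=(9, 11))


def test_inhomogeneity_map_properties():
    cfg = SceneConfig(inhom_amplitude=0.05)
    inhom = inhomogeneity_map(cfg)
    dev = np.abs(inhom.values - 1.0)
    assert dev.max() == pytest.approx(0.05, rel=1e-9)
    # reproducible from the seed
    assert np.array_equal(inhom.values, inhomogeneity_map(cfg).values)


def test_scene_config_validation():
    with pytest.raises(ValueError):
        SceneConfig(intervals=[(0.0, 1.0), (0.5, 2.0)],
                    field_sets=[[FieldSpec()], [FieldSpec()]])
    with pytest.raises(ValueError):
        SceneConfig(channel_weights=(0.5, 0.4, 0.2))
    with pytest.raises(ValueError):
        SceneConfig(fps=0.0)
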