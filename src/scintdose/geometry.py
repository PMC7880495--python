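"""One-time geometric calibration and per-frame rectification.

The tilted camera introduces two distortions: lens (Brown radial/tangential)
and perspective.  Calibration uses a chessboard placed at the scintillator
position: first a planar bundle adjustment recovers the intrinsics and lens
coefficients from one or more board views, then a projective homography maps
undistorted sensor coordinates onto physical scintillator-plane millimetres.
Rectification resamples a raw frame onto a square output grid — by default
176 mm over 2048 px, a pitch of 176/2048 = 0.0859375 mm (0.086 mm at three
decimals).

The calibration is persisted once as a JSON file and reused for every frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation
from skimage import transform as sktransform

from .planes import DosePlane


def _distort(xy: np.ndarray, k1: float, k2: float, p1: float, p2: float) -> np.ndarray:
    x, y = xy[..., 0], xy[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2 * r2
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    return np.stack([xd, yd], axis=-1)


def _undistort(xy_d: np.ndarray, k1, k2, p1, p2, iters: int = 25) -> np.ndarray:
    xd, yd = xy_d[..., 0], xy_d[..., 1]
    x, y = xd.copy(), yd.copy()
    for _ in range(iters):
        r2 = x * x + y * y
        radial = 1.0 + k1 * r2 + k2 * r2 * r2
        dx = 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
        dy = p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
        x = (xd - dx) / radial
        y = (yd - dy) / radial
    return np.stack([x, y], axis=-1)


@dataclass
class LensModel:
    """Intrinsics + Brown distortion of the camera lens."""

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def _norm(self, points_px: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_px, dtype=float)
        return np.stack(
            [(pts[..., 0] - self.cx) / self.fx, (pts[..., 1] - self.cy) / self.fy],
            axis=-1,
        )

    def _denorm(self, xy: np.ndarray) -> np.ndarray:
        return np.stack(
            [self.fx * xy[..., 0] + self.cx, self.fy * xy[..., 1] + self.cy], axis=-1
        )

    def undistort_points(self, points_px: np.ndarray) -> np.ndarray:
        """Distorted sensor (u, v) -> ideal-pinhole sensor (u, v)."""
        return self._denorm(_undistort(self._norm(points_px), self.k1, self.k2, self.p1, self.p2))

    def distort_points(self, points_px: np.ndarray) -> np.ndarray:
        """Ideal-pinhole sensor (u, v) -> distorted sensor (u, v)."""
        return self._denorm(_distort(self._norm(points_px), self.k1, self.k2, self.p1, self.p2))


@dataclass
class Homography:
    """3x3 projective map, normalized so the bottom-right element is 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if abs(m[2, 2]) < 1e-15:
            raise ValueError("homography cannot be normalized (H[2,2] = 0)")
        m = m / m[2, 2]
        if np.linalg.matrix_rank(m) < 3:
            raise ValueError("homography must be invertible")
        self.matrix = m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.hstack([pts, np.ones((len(pts), 1))]) @ self.matrix.T
        return hom[:, :2] / hom[:, 2:3]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def compose(self, other: "Homography") -> "Homography":
        """Return self after other: x -> self(other(x))."""
        return Homography(self.matrix @ other.matrix)


def fit_homography(src: np.ndarray, dst: np.ndarray) -> Homography:
    """Least-squares projective transform src -> dst (normalized DLT).

    Requires at least 4 non-collinear correspondences.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if len(src) < 4 or len(dst) != len(src):
        raise ValueError("at least 4 point correspondences are required")
    if hasattr(sktransform.ProjectiveTransform, "from_estimate"):
        tf = sktransform.ProjectiveTransform.from_estimate(src, dst)
        if not tf or not np.all(np.isfinite(tf.params)):
            raise ValueError("degenerate point configuration for homography")
    else:  # scikit-image < 0.26
        tf = sktransform.ProjectiveTransform()
        if not tf.estimate(src, dst) or not np.all(np.isfinite(tf.params)):
            raise ValueError("degenerate point configuration for homography")
    return Homography(tf.params)


@dataclass
class LensFit:
    """Result of the planar lens calibration."""

    lens: LensModel
    rms_px: float
    rotations: list[np.ndarray]
    translations: list[np.ndarray]


def _pose_from_homography(h: np.ndarray, k: np.ndarray):
    """Planar pose (R, t) from a board->pixel homography given intrinsics."""
    m = np.linalg.solve(k, h)
    lam = 2.0 / (np.linalg.norm(m[:, 0]) + np.linalg.norm(m[:, 1]))
    r1, r2, t = lam * m[:, 0], lam * m[:, 1], lam * m[:, 2]
    if t[2] < 0:
        r1, r2, t = -r1, -r2, -t
    r3 = np.cross(r1, r2)
    q = np.stack([r1, r2, r3], axis=1)
    u, _, vt = np.linalg.svd(q)
    r = u @ vt
    if np.linalg.det(r) < 0:
        r = u @ np.diag([1, 1, -1]) @ vt
    return r, t


def fit_lens_model(
    corner_sets: list[np.ndarray],
    board_mm: np.ndarray,
    image_shape: tuple[int, int],
    init_focal_px: float | None = None,
) -> LensFit:
    """Recover intrinsics and lens distortion from chessboard corner sets.

    ``corner_sets[i]`` holds the detected (distorted) pixel coordinates of the
    board's interior corners in view ``i``; ``board_mm`` the matching planar
    board coordinates (shared across views).  A joint non-linear
    least-squares refinement over intrinsics, 2 radial + 2 tangential
    distortion terms and one 6-dof pose per view minimizes the reprojection
    error; the RMS reprojection error is reported.
    """
    if len(corner_sets) < 1:
        raise ValueError("at least 1 chessboard view is required")
    board_mm = np.asarray(board_mm, dtype=float)
    n_pts = len(board_mm)
    n_views = len(corner_sets)
    min_pts = (8 + 6 * n_views + 2) // (2 * n_views) + 1
    if n_pts < max(min_pts, 9):
        raise ValueError(
            f"too few corners per view ({n_pts}); at least {max(min_pts, 9)} are required"
        )
    h_img, w_img = image_shape
    f0 = init_focal_px if init_focal_px is not None else 1.1 * max(h_img, w_img)
    k0 = np.array([[f0, 0, (w_img - 1) / 2.0], [0, f0, (h_img - 1) / 2.0], [0, 0, 1]])

    board3 = np.hstack([board_mm, np.zeros((n_pts, 1))])
    rvecs, tvecs = [], []
    for corners in corner_sets:
        h = fit_homography(board_mm, np.asarray(corners, dtype=float)).matrix
        r, t = _pose_from_homography(h, k0)
        rvecs.append(Rotation.from_matrix(r).as_rotvec())
        tvecs.append(t)

    def unpack(params):
        fx, fy, cx, cy, k1, k2, p1, p2 = params[:8]
        poses = params[8:].reshape(n_views, 6)
        return (fx, fy, cx, cy, k1, k2, p1, p2), poses

    def residuals(params):
        (fx, fy, cx, cy, k1, k2, p1, p2), poses = unpack(params)
        res = []
        for i, corners in enumerate(corner_sets):
            r = Rotation.from_rotvec(poses[i, :3]).as_matrix()
            t = poses[i, 3:]
            pc = board3 @ r.T + t
            xy = pc[:, :2] / pc[:, 2:3]
            xyd = _distort(xy, k1, k2, p1, p2)
            proj = np.stack([fx * xyd[:, 0] + cx, fy * xyd[:, 1] + cy], axis=-1)
            res.append((proj - corners).ravel())
        return np.concatenate(res)

    x0 = np.concatenate(
        [[f0, f0, k0[0, 2], k0[1, 2], 0.0, 0.0, 0.0, 0.0]]
        + [np.concatenate([rv, tv]) for rv, tv in zip(rvecs, tvecs)]
    )
    sol = optimize.least_squares(residuals, x0, x_scale="jac", max_nfev=400)
    (fx, fy, cx, cy, k1, k2, p1, p2), poses = unpack(sol.x)
    res = sol.fun.reshape(-1, 2)
    rms = float(np.sqrt((res ** 2).sum(axis=1).mean()))
    rots = [Rotation.from_rotvec(p[:3]).as_matrix() for p in poses]
    return LensFit(
        LensModel(fx, fy, cx, cy, k1, k2, p1, p2),
        rms,
        rots,
        [p[3:].copy() for p in poses],
    )


@dataclass
class GeometryCalibration:
    """Lens model + homography + rectified output grid specification.

    The homography maps undistorted sensor pixels to scintillator-plane mm.
    The output grid is square: ``grid_side_mm`` over ``grid_pixels``, pitch
    exactly ``grid_side_mm / grid_pixels`` with the isocenter at the grid
    center.
    """

    lens: LensModel
    homography: Homography
    grid_side_mm: float = 176.0
    grid_pixels: int = 2048

    def __post_init__(self) -> None:
        if self.grid_side_mm <= 0 or self.grid_pixels <= 0:
            raise ValueError("output grid must be positive")

    @property
    def pitch_mm(self) -> float:
        return self.grid_side_mm / self.grid_pixels

    @property
    def isocenter_px(self) -> tuple[float, float]:
        c = (self.grid_pixels - 1) / 2.0
        return (c, c)

    # -- persistence -----------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        lens = self.lens
        payload = {
            "lens": {k: getattr(lens, k) for k in
                     ("fx", "fy", "cx", "cy", "k1", "k2", "p1", "p2")},
            "homography": self.homography.matrix.tolist(),
            "grid_side_mm": self.grid_side_mm,
            "grid_pixels": self.grid_pixels,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeometryCalibration":
        payload = json.loads(Path(path).read_text())
        return cls(
            LensModel(**payload["lens"]),
            Homography(np.array(payload["homography"])),
            float(payload["grid_side_mm"]),
            int(payload["grid_pixels"]),
        )


def calibrate_geometry(
    corner_sets: list[np.ndarray],
    board_mm: np.ndarray,
    image_shape: tuple[int, int],
    *,
    reference_view: int = 0,
    grid_side_mm: float = 176.0,
    grid_pixels: int = 2048,
    init_focal_px: float | None = None,
) -> GeometryCalibration:
    """Full calibration: lens fit, then homography from the reference view.

    ``reference_view`` indexes the board image taken with the board at the
    scintillator position; its corners anchor the sensor-to-plane homography.
    """
    fit = fit_lens_model(corner_sets, board_mm, image_shape, init_focal_px)
    undist = fit.lens.undistort_points(np.asarray(corner_sets[reference_view], float))
    hom = fit_homography(undist, np.asarray(board_mm, float))
    return GeometryCalibration(fit.lens, hom, grid_side_mm, grid_pixels)


def rectify(
    frame: np.ndarray,
    calib: GeometryCalibration,
    *,
    order: int = 1,
) -> DosePlane:
    """Resample a raw grayscale frame onto the physical output grid.

    For each output grid point (mm) the inverse homography gives undistorted
    sensor coordinates, the lens model re-applies the distortion, and the
    frame is sampled there (bilinear by default, nearest with ``order=0``).
    Grid points falling outside the sensor are zero and flagged invalid in
    the returned plane's mask.  The undistortion and perspective correction
    are composed into a single resampling pass to interpolate only once.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("rectify expects a 2D grayscale frame")
    n = calib.grid_pixels
    pitch = calib.pitch_mm
    c = (n - 1) / 2.0
    idx = np.arange(n)
    x = (idx - c) * pitch
    y = (idx - c) * pitch
    xx, yy = np.meshgrid(x, y)
    mm = np.stack([xx.ravel(), yy.ravel()], axis=-1)
    undist_px = calib.homography.inverse().apply(mm)
    dist_px = calib.lens.distort_points(undist_px)
    u = dist_px[:, 0].reshape(n, n)
    v = dist_px[:, 1].reshape(n, n)
    h_img, w_img = frame.shape
    valid = (u >= 0) & (u <= w_img - 1) & (v >= 0) & (v <= h_img - 1)
    values = ndimage.map_coordinates(
        frame, [v.ravel(), u.ravel()], order=order, mode="constant", cval=0.0
    ).reshape(n, n)
    values[~valid] = 0.0
    return DosePlane(values, pitch, mask=valid, unit="intensity")


# -- image-based corner detection (production mode) -----------------------------


def detect_chessboard_corners(
    image: np.ndarray, n_corners: tuple[int, int]
) -> np.ndarray:
    """Detect and order interior chessboard corners in an image.

    Harris corners are refined to sub-pixel accuracy and ordered row-major by
    anchoring a projective transform on the four outermost corners.  Suited
    to the moderate tilts of the detector geometry; the synthetic generator's
    exact corners remain available for test-mode calibration.
    """
    from skimage.feature import corner_harris, corner_peaks, corner_subpix

    rows, cols = n_corners
    n_expected = rows * cols
    img = np.asarray(image, dtype=float)
    response = corner_harris(img, sigma=2.0)
    peaks = corner_peaks(response, min_distance=5, threshold_rel=0.01)

    # The board outline against the dark surround also fires the corner
    # detector; interior corners are recognizable by a neighbourhood that
    # contains both square shades but no background.
    floor = 0.05 * img.max()
    keep = []
    for r, c in peaks:
        win = img[max(r - 4, 0):r + 5, max(c - 4, 0):c + 5]
        if win.min() > floor:
            keep.append((r, c))
    peaks = np.asarray(keep, dtype=int)
    if len(peaks) < n_expected:
        raise ValueError(
            f"found only {len(peaks)} interior corners, expected {n_expected}"
        )
    strength = response[peaks[:, 0], peaks[:, 1]]
    peaks = peaks[np.argsort(strength)[::-1][:n_expected]]
    sub = corner_subpix(img, peaks, window_size=9)
    bad = ~np.isfinite(sub).all(axis=1)
    sub[bad] = peaks[bad]
    pts = sub[:, ::-1]  # (row, col) -> (u, v)

    # Anchor an initial projective map on the four extreme corners.
    s, d = pts.sum(axis=1), pts[:, 0] - pts[:, 1]
    quad_px = np.array(
        [pts[np.argmin(s)], pts[np.argmax(d)], pts[np.argmin(d)], pts[np.argmax(s)]]
    )
    quad_grid = np.array(
        [[0, 0], [cols - 1, 0], [0, rows - 1], [cols - 1, rows - 1]], dtype=float
    )
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    grid = np.stack([jj.ravel(), ii.ravel()], axis=-1).astype(float)

    order = None
    hom = fit_homography(quad_grid, quad_px)
    for _ in range(2):
        pred = hom.apply(grid)
        d2 = ((pred[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
        order = np.argmin(d2, axis=1)
        if len(set(order.tolist())) != n_expected:
            raise ValueError("could not order detected corners into a grid")
        hom = fit_homography(grid, pts[order])
    return pts[order]
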