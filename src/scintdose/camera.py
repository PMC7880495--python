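"""Physics-based synthetic generator of scintillation acquisitions.

Emulates a mirrorless detector: a pinhole camera with Brown lens distortion
mounted off to the side of a flat scintillator sheet, facing it at an angle.
The rendered brightness of each scintillator point falls off with the inverse
square of its distance to the lens, is modulated by a smooth multiplicative
scintillator-inhomogeneity field, split into R/G/B channels according to the
phosphor's emission (defaults 10.5 / 51.5 / 38.0 %), blurred by the optics,
and corrupted by Poisson + read noise and transient hot pixels.  A beam
timeline at a fixed frame rate (24 fps default) yields a step-and-shoot
acquisition: one rectangular-field set per beam-on interval.

Everything is deterministic given a seed, and the generator returns the
ground truth (per-segment dose planes, timeline, true camera and
inhomogeneity map) alongside the frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .frames import BeamSegment, FrameStack
from .planes import DosePlane

_LOG4 = math.log(4.0)


# -- dose fields ---------------------------------------------------------------


@dataclass(frozen=True)
class FieldSpec:
    """A rectangular radiation field on the scintillator plane.

    center_mm : (x, y) field center relative to the isocenter
    width_mm / height_mm : field dimensions at the 50% dose level
    penumbra_mm : 80-20% edge distance of the sigmoid field edge
    dose_cgy : dose delivered inside the field
    """

    center_mm: tuple[float, float] = (0.0, 0.0)
    width_mm: float = 100.0
    height_mm: float = 100.0
    penumbra_mm: float = 5.0
    dose_cgy: float = 100.0

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("field dimensions must be positive")
        if self.penumbra_mm < 0 or self.dose_cgy < 0:
            raise ValueError("penumbra and dose must be non-negative")


def _edge(x: np.ndarray, lo: float, hi: float, penumbra: float) -> np.ndarray:
    """1D field edge profile: 1 inside [lo, hi], sigmoid shoulders.

    The logistic slope is chosen so the 80-20% lateral distance equals the
    penumbra parameter exactly (for edges separated by >> penumbra).
    """
    if penumbra == 0:
        return ((x > lo) & (x < hi)).astype(float)
    s = penumbra / (2.0 * _LOG4)
    from scipy.special import expit

    return expit((x - lo) / s) * expit((hi - x) / s)


def make_dose_field(
    fields: FieldSpec | list[FieldSpec],
    side_mm: float = 300.0,
    pitch_mm: float = 1.0,
    background: float = 0.0,
) -> DosePlane:
    """Superpose rectangular fields onto a square dose grid (cGy).

    Each field contributes ``dose_cgy`` inside its 50% outline with a
    monotone sigmoid edge whose 80-20% distance equals ``penumbra_mm``.
    A field extending beyond the grid is rejected.
    """
    if isinstance(fields, FieldSpec):
        fields = [fields]
    n = int(round(side_mm / pitch_mm))
    coords = (np.arange(n) - (n - 1) / 2.0) * pitch_mm
    half = side_mm / 2.0
    values = np.full((n, n), float(background))
    for i, f in enumerate(fields):
        cx, cy = f.center_mm
        if (
            abs(cx) + f.width_mm / 2 > half or abs(cy) + f.height_mm / 2 > half
        ):
            raise ValueError(
                f"field {i} ({f.width_mm} x {f.height_mm} mm at {f.center_mm}) "
                f"exceeds the {side_mm} mm grid extent"
            )
        ex = _edge(coords, cx - f.width_mm / 2, cx + f.width_mm / 2, f.penumbra_mm)
        ey = _edge(coords, cy - f.height_mm / 2, cy + f.height_mm / 2, f.penumbra_mm)
        values += f.dose_cgy * np.outer(ey, ex)
    return DosePlane(values, pitch_mm)


# -- camera --------------------------------------------------------------------


@dataclass
class CameraModel:
    """Pinhole camera with Brown radial/tangential distortion.

    ``rotation`` maps world to camera coordinates (rows are the camera axes
    expressed in world coordinates); ``position_mm`` is the lens center in
    world mm.  The world frame has the scintillator in the z = 0 plane with
    the isocenter at the origin.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    position_mm: np.ndarray = field(default_factory=lambda: np.array([0.0, -260.0, 180.0]))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    sensor_shape: tuple[int, int] = (240, 320)  # (H, W)

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.sensor_shape[0] <= 0 or self.sensor_shape[1] <= 0:
            raise ValueError("sensor dimensions must be positive")
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if abs(self.position_mm[2]) < 1e-9:
            raise ValueError("camera must sit off the scintillator plane")

    @classmethod
    def look_at(
        cls,
        position_mm,
        target_mm=(0.0, 0.0, 0.0),
        **kwargs,
    ) -> "CameraModel":
        """Build a camera at ``position_mm`` whose optical axis hits ``target_mm``."""
        pos = np.asarray(position_mm, dtype=float)
        z = np.asarray(target_mm, dtype=float) - pos
        nz = np.linalg.norm(z)
        if nz == 0:
            raise ValueError("camera position coincides with target")
        z = z / nz
        down = np.array([0.0, 0.0, -1.0])
        x = np.cross(down, z)
        if np.linalg.norm(x) < 1e-9:  # looking straight down: pick world +x
            x = np.array([1.0, 0.0, 0.0])
        x = x / np.linalg.norm(x)
        y = np.cross(z, x)
        rot = np.vstack([x, y, z])
        return cls(position_mm=pos, rotation=rot, **kwargs)

    # -- distortion ------------------------------------------------------------

    def distort_normalized(self, xy: np.ndarray) -> np.ndarray:
        x, y = xy[..., 0], xy[..., 1]
        r2 = x * x + y * y
        radial = 1.0 + self.k1 * r2 + self.k2 * r2 * r2
        xd = x * radial + 2 * self.p1 * x * y + self.p2 * (r2 + 2 * x * x)
        yd = y * radial + self.p1 * (r2 + 2 * y * y) + 2 * self.p2 * x * y
        return np.stack([xd, yd], axis=-1)

    def undistort_normalized(self, xy_d: np.ndarray, iters: int = 25) -> np.ndarray:
        """Invert the Brown model by fixed-point iteration."""
        xd, yd = xy_d[..., 0], xy_d[..., 1]
        x, y = xd.copy(), yd.copy()
        for _ in range(iters):
            r2 = x * x + y * y
            radial = 1.0 + self.k1 * r2 + self.k2 * r2 * r2
            dx = 2 * self.p1 * x * y + self.p2 * (r2 + 2 * x * x)
            dy = self.p1 * (r2 + 2 * y * y) + 2 * self.p2 * x * y
            x = (xd - dx) / radial
            y = (yd - dy) / radial
        return np.stack([x, y], axis=-1)

    # -- projection --------------------------------------------------------------

    def project(self, points_mm: np.ndarray) -> np.ndarray:
        """World points (N, 2 or 3; z = 0 assumed for 2D) -> distorted pixel (u, v)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        if pts.shape[-1] == 2:
            pts = np.hstack([pts, np.zeros((len(pts), 1))])
        pc = (pts - self.position_mm) @ self.rotation.T
        if np.any(pc[:, 2] <= 0):
            raise ValueError("points behind the camera cannot be projected")
        xy = pc[:, :2] / pc[:, 2:3]
        xyd = self.distort_normalized(xy)
        return np.stack(
            [self.fx * xyd[:, 0] + self.cx, self.fy * xyd[:, 1] + self.cy], axis=-1
        )

    def pixel_to_plane(self, u: np.ndarray, v: np.ndarray):
        """Back-project sensor pixels to the z = 0 plane.

        Returns ``(points_mm (..., 2), distance_mm, valid)`` where ``valid``
        marks rays that actually hit the plane in front of the camera.
        """
        xy_d = np.stack(
            [(np.asarray(u, float) - self.cx) / self.fx,
             (np.asarray(v, float) - self.cy) / self.fy], axis=-1
        )
        xy = self.undistort_normalized(xy_d)
        dirs_cam = np.concatenate([xy, np.ones(xy.shape[:-1] + (1,))], axis=-1)
        dirs = dirs_cam @ self.rotation  # R^T applied to each direction
        with np.errstate(divide="ignore", invalid="ignore"):
            s = -self.position_mm[2] / dirs[..., 2]
        valid = np.isfinite(s) & (s > 0)
        s = np.where(valid, s, 0.0)
        pts = self.position_mm + s[..., None] * dirs
        dist = s * np.linalg.norm(dirs, axis=-1)
        return pts[..., :2], dist, valid

    def check_views_plane(self) -> None:
        axis = self.rotation[2]  # optical axis in world coordinates
        if axis[2] == 0 or -self.position_mm[2] / axis[2] <= 0:
            raise ValueError("camera pose does not view the scintillator plane")


# -- scene configuration -------------------------------------------------------


@dataclass
class SceneConfig:
    """Everything about the scene except the camera.

    ``intervals`` are non-overlapping, sorted beam-on windows in seconds and
    ``field_sets[i]`` is the list of rectangular fields delivered during
    interval ``i`` (their ``dose_cgy`` is the total dose of that segment).
    ``gain`` is the noiseless brightness per cGy at the isocenter distance.
    """

    intervals: list[tuple[float, float]] = field(default_factory=lambda: [(0.5, 2.5)])
    field_sets: list[list[FieldSpec]] = field(default_factory=lambda: [[FieldSpec()]])
    fps: float = 24.0
    duration_s: float | None = None
    plane_side_mm: float = 300.0
    plane_pitch_mm: float = 1.0
    inhom_seed: int = 7
    inhom_amplitude: float = 0.05
    inhom_corr_mm: float = 25.0
    poisson_gain: float = 0.25
    read_noise_sd: float = 0.3
    hot_pixel_rate: float = 2.0
    hot_pixel_amplitude: float = 2000.0
    hot_pixel_frames: int = 1
    channel_weights: tuple[float, float, float] = (0.105, 0.515, 0.380)
    gain: float = 400.0
    background: float = 0.2
    optical_blur_sigma_px: float = 1.5
    reference_distance_mm: float | None = None

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if len(self.intervals) != len(self.field_sets):
            raise ValueError("intervals and field_sets must pair up")
        last_end = -math.inf
        for t0, t1 in self.intervals:
            if t1 <= t0:
                raise ValueError("intervals must have positive duration")
            if t0 < last_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            last_end = t1
        if abs(sum(self.channel_weights) - 1.0) > 1e-9:
            raise ValueError("channel weights must sum to 1")
        if self.hot_pixel_frames not in (1, 2):
            raise ValueError("hot pixels last 1 or 2 frames")

    def total_duration(self) -> float:
        if self.duration_s is not None:
            return self.duration_s
        return (self.intervals[-1][1] + 0.5) if self.intervals else 1.0


def inhomogeneity_map(cfg: SceneConfig) -> DosePlane:
    """Smooth multiplicative scintillator-inhomogeneity field, mean ~ 1.

    Gaussian-filtered white noise scaled so the peak deviation from unity
    equals ``inhom_amplitude``; correlation length ``inhom_corr_mm``.
    """
    n = int(round(cfg.plane_side_mm / cfg.plane_pitch_mm))
    rng = np.random.default_rng(cfg.inhom_seed)
    noise = rng.standard_normal((n, n))
    sigma = cfg.inhom_corr_mm / cfg.plane_pitch_mm
    smooth = ndimage.gaussian_filter(noise, sigma, mode="reflect")
    peak = np.abs(smooth).max()
    dev = smooth / peak if peak > 0 else smooth
    return DosePlane(1.0 + cfg.inhom_amplitude * dev, cfg.plane_pitch_mm, unit="relative")


class _SceneSampler:
    """Precomputed per-pixel geometry shared by all frames of an acquisition."""

    def __init__(self, cam: CameraModel, cfg: SceneConfig):
        cam.check_views_plane()
        h, w = cam.sensor_shape
        v, u = np.mgrid[0:h, 0:w].astype(float)
        pts, dist, valid = cam.pixel_to_plane(u, v)
        d0 = cfg.reference_distance_mm
        if d0 is None:
            d0 = float(np.linalg.norm(cam.position_mm))
        with np.errstate(divide="ignore", invalid="ignore"):
            atten = np.where(valid, (d0 / dist) ** 2, 0.0)
        inhom_plane = inhomogeneity_map(cfg)
        inhom = np.where(
            valid,
            _sample_plane(inhom_plane, pts[..., 0], pts[..., 1], cval=1.0),
            1.0,
        )
        self.cam, self.cfg = cam, cfg
        self.points = pts
        self.valid = valid
        self.weight = atten * inhom  # geometric x material response per pixel

    def signal(self, plane: DosePlane, scale: float = 1.0) -> np.ndarray:
        """Noiseless grayscale sensor signal for a dose plane (pre channel split)."""
        dose = _sample_plane(plane, self.points[..., 0], self.points[..., 1])
        sig = self.cfg.gain * scale * dose * self.weight
        if self.cfg.optical_blur_sigma_px > 0:
            sig = ndimage.gaussian_filter(sig, self.cfg.optical_blur_sigma_px)
        return sig


def _sample_plane(plane: DosePlane, x_mm, y_mm, cval: float = 0.0) -> np.ndarray:
    row, col = plane.mm_to_index(x_mm, y_mm)
    return ndimage.map_coordinates(
        plane.values, [np.ravel(row), np.ravel(col)], order=1, mode="constant",
        cval=cval,
    ).reshape(np.shape(row))


def _add_noise(rgb: np.ndarray, cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    out = rgb
    if cfg.poisson_gain > 0:
        out = rng.poisson(np.maximum(out, 0.0) / cfg.poisson_gain) * cfg.poisson_gain
    if cfg.read_noise_sd > 0:
        out = out + rng.normal(0.0, cfg.read_noise_sd, size=out.shape)
    return np.maximum(out, 0.0)


def project_to_frame(
    plane: DosePlane,
    cam: CameraModel,
    cfg: SceneConfig,
    rng: np.random.Generator | None = None,
    scale: float = 1.0,
) -> np.ndarray:
    """Render one RGB frame of a dose plane through the camera.

    The noiseless signal is split into channels by ``cfg.channel_weights``,
    the background level is added per channel, then Poisson/read noise and
    hot pixels.  Deterministic given the generator state.
    """
    sampler = _SceneSampler(cam, cfg)
    sig = sampler.signal(plane, scale)
    weights = np.asarray(cfg.channel_weights)
    rgb = sig[..., None] * weights + cfg.background
    if rng is None:
        return np.maximum(rgb, 0.0).astype(np.float32)
    rgb = _add_noise(rgb, cfg, rng)
    rgb, _ = _inject_hot_pixels(rgb, cfg, rng)
    return rgb.astype(np.float32)


def _inject_hot_pixels(
    rgb: np.ndarray, cfg: SceneConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    positions: list[tuple[int, int]] = []
    if cfg.hot_pixel_rate > 0:
        n = int(rng.poisson(cfg.hot_pixel_rate))
        h, w = rgb.shape[:2]
        for _ in range(n):
            r, c = int(rng.integers(h)), int(rng.integers(w))
            rgb[r, c, :] += cfg.hot_pixel_amplitude
            positions.append((r, c))
    return rgb, positions


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    segments: list[BeamSegment]
    segment_planes: list[DosePlane]
    cumulative: DosePlane
    camera: CameraModel
    inhomogeneity: DosePlane
    hot_pixel_counts: list[int]

    def __post_init__(self) -> None:
        if self.segment_planes:
            total = self.segment_planes[0].values.copy()
            for p in self.segment_planes[1:]:
                total += p.values
            if not np.allclose(total, self.cumulative.values, rtol=1e-9, atol=1e-12):
                raise ValueError("cumulative plane must equal the sum of segments")


def render_acquisition(
    cfg: SceneConfig, cam: CameraModel, seed: int = 0
) -> tuple[FrameStack, GroundTruth]:
    """Render the full timeline: one RGB frame per 1/fps tick.

    Frames whose midpoints fall inside a beam-on interval carry that
    segment's signal (the segment dose spread uniformly over its frames);
    all frames carry background, noise and hot pixels.
    """
    rng = np.random.default_rng(seed)
    sampler = _SceneSampler(cam, cfg)
    n_frames = max(int(round(cfg.total_duration() * cfg.fps)), 1)
    midpoints = (np.arange(n_frames) + 0.5) / cfg.fps

    # Map frames to segments.
    seg_of_frame = np.full(n_frames, -1)
    segments: list[BeamSegment] = []
    seg_planes: list[DosePlane] = []
    seg_signals: list[np.ndarray] = []
    for i, ((t0, t1), fields) in enumerate(zip(cfg.intervals, cfg.field_sets)):
        members = np.flatnonzero((midpoints >= t0) & (midpoints < t1))
        if members.size == 0:
            continue
        seg_of_frame[members] = len(segments)
        segments.append(BeamSegment(int(members[0]), int(members[-1]), cfg.fps))
        plane = make_dose_field(fields, cfg.plane_side_mm, cfg.plane_pitch_mm)
        seg_planes.append(plane)
        seg_signals.append(sampler.signal(plane, scale=1.0 / members.size))

    weights = np.asarray(cfg.channel_weights)
    h, w = cam.sensor_shape
    frames = np.empty((n_frames, h, w, 3), dtype=np.float32)
    hot_counts: list[int] = []
    carry: list[tuple[int, int]] = []
    for f in range(n_frames):
        s = seg_of_frame[f]
        sig = seg_signals[s] if s >= 0 else 0.0
        rgb = np.asarray(sig)[..., None] * weights + cfg.background
        rgb = np.broadcast_to(rgb, (h, w, 3)).astype(float).copy()
        rgb = _add_noise(rgb, cfg, rng)
        for r, c in carry:  # hot pixels persisting from the previous frame
            rgb[r, c, :] += cfg.hot_pixel_amplitude
        rgb, fresh = _inject_hot_pixels(rgb, cfg, rng)
        hot_counts.append(len(fresh))
        carry = fresh if cfg.hot_pixel_frames == 2 else []
        frames[f] = rgb

    if seg_planes:
        cumulative = seg_planes[0]
        for p in seg_planes[1:]:
            cumulative = cumulative + p
    else:
        n = int(round(cfg.plane_side_mm / cfg.plane_pitch_mm))
        cumulative = DosePlane(np.zeros((n, n)), cfg.plane_pitch_mm)
    truth = GroundTruth(
        segments=segments,
        segment_planes=seg_planes,
        cumulative=cumulative,
        camera=cam,
        inhomogeneity=inhomogeneity_map(cfg),
        hot_pixel_counts=hot_counts,
    )
    return FrameStack(frames, cfg.fps), truth


# -- calibration imagery -------------------------------------------------------


@dataclass
class ChessboardImage:
    """Rendered calibration board with its ground-truth corner locations."""

    image: np.ndarray            # (H, W) grayscale
    corners_px: np.ndarray       # (N, 2) distorted sensor (u, v), row-major
    corners_mm: np.ndarray       # (N, 2) board-plane coordinates
    n_corners: tuple[int, int]   # interior corners (rows, cols)


def make_chessboard_image(
    cam: CameraModel,
    square_mm: float = 22.0,
    n_squares: tuple[int, int] = (7, 9),
    light: float = 200.0,
    dark: float = 20.0,
    supersample: int = 3,
) -> ChessboardImage:
    """Render a centered chessboard through the camera's projection + lens.

    Returns the image together with the true image coordinates of the
    interior corners (projected through the same model), enabling both a
    test-mode calibration from exact corners and validation of an
    image-based detector.
    """
    cam.check_views_plane()
    rows_sq, cols_sq = n_squares
    bw, bh = cols_sq * square_mm, rows_sq * square_mm

    # True interior corners, row-major from the board's (-x, -y) corner.
    jj, ii = np.meshgrid(np.arange(1, cols_sq), np.arange(1, rows_sq))
    corners_mm = np.stack(
        [jj.ravel() * square_mm - bw / 2, ii.ravel() * square_mm - bh / 2], axis=-1
    )
    corners_px = cam.project(corners_mm)
    h, w = cam.sensor_shape
    if (
        corners_px[:, 0].min() < 0 or corners_px[:, 0].max() > w - 1
        or corners_px[:, 1].min() < 0 or corners_px[:, 1].max() > h - 1
    ):
        raise ValueError("chessboard does not fit inside the camera view")

    ss = supersample
    v, u = np.mgrid[0:h * ss, 0:w * ss]
    # Supersampled pixel centers in original pixel units.
    u = (u + 0.5) / ss - 0.5
    v = (v + 0.5) / ss - 0.5
    pts, _, valid = cam.pixel_to_plane(u, v)
    x, y = pts[..., 0], pts[..., 1]
    on_board = valid & (np.abs(x) < bw / 2) & (np.abs(y) < bh / 2)
    parity = (
        np.floor((x + bw / 2) / square_mm) + np.floor((y + bh / 2) / square_mm)
    ).astype(int) % 2
    img = np.where(on_board, np.where(parity == 0, dark, light), 0.0)
    img = img.reshape(h, ss, w, ss).mean(axis=(1, 3))
    return ChessboardImage(img, corners_px, corners_mm, (rows_sq - 1, cols_sq - 1))
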