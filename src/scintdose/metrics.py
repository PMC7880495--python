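"""Validation metrics: 2D gamma analysis, beam-profile statistics, PDD.

The gamma index combines a dose-difference (DD, % of the reference maximum —
global normalization) and a distance-to-agreement (DTA, mm) tolerance:

    gamma(r_ref) = min over eval positions r of
        sqrt( (D_eval(r) - D_ref(r_ref))^2 / DD^2 + |r - r_ref|^2 / DTA^2 )

A reference point passes when gamma <= 1.  Only reference pixels above a
low-dose threshold (default 5% of the reference maximum) are scored.  The
evaluated plane is interpolated bilinearly on a search disc of radius
3 x DTA sampled at a step of DTA/10; an exhaustive brute-force twin serves
as an independent oracle on small grids.

Beam-profile flatness, symmetry and penumbra follow the TG-45 conventions:
over the central 80% of the field width, flatness = 100 (Dmax - Dmin) /
(Dmax + Dmin) and symmetry = 100 max|D(x) - D(-x)| / D(0); the penumbra is
the 80%-20% lateral distance relative to the central-axis dose on each edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import BeamSegment, FrameStack
from .planes import DosePlane


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma test tolerances (global normalization to the reference maximum)."""

    dose_diff_pct: float = 3.0
    dta_mm: float = 3.0
    threshold_pct: float = 5.0

    def __post_init__(self) -> None:
        if self.dose_diff_pct <= 0 or self.dta_mm <= 0 or self.threshold_pct <= 0:
            raise ValueError("gamma criteria must be strictly positive")


@dataclass
class GammaResult:
    """Gamma map (NaN below threshold), pass rate over scored pixels, criteria."""

    gamma_map: np.ndarray
    pass_rate_pct: float
    criteria: GammaCriteria

    @property
    def max_gamma(self) -> float:
        scored = self.gamma_map[np.isfinite(self.gamma_map)]
        return float(scored.max()) if scored.size else 0.0


def _search_offsets(crit: GammaCriteria) -> np.ndarray:
    """(dx, dy, (r/DTA)^2) rows sorted by radius; step DTA/10, radius 3 DTA."""
    step = crit.dta_mm / 10.0
    n = int(np.ceil(3.0 * crit.dta_mm / step))
    k = np.arange(-n, n + 1) * step
    dx, dy = np.meshgrid(k, k)
    r2 = dx ** 2 + dy ** 2
    keep = r2 <= (3.0 * crit.dta_mm) ** 2 + 1e-12
    rows = np.stack(
        [dx[keep], dy[keep], r2[keep] / crit.dta_mm ** 2], axis=-1
    )
    return rows[np.argsort(rows[:, 2], kind="stable")]


def _check_overlap(eval_plane: DosePlane, ref: DosePlane) -> None:
    ex = eval_plane.extent_mm()
    rx = ref.extent_mm()
    if ex[1] < rx[0] or rx[1] < ex[0] or ex[3] < rx[2] or rx[3] < ex[2]:
        raise ValueError("evaluated and reference planes do not overlap")


def gamma_index(
    eval_plane: DosePlane, ref: DosePlane, crit: GammaCriteria = GammaCriteria()
) -> GammaResult:
    """Accelerated 2D gamma analysis of ``eval_plane`` against ``ref``.

    Search offsets are visited in order of increasing radius and reference
    pixels are retired as soon as their running minimum cannot improve
    (gamma^2 <= (r/DTA)^2 for all remaining offsets), which is exact.
    Spacings of the two planes may differ; the evaluated plane is
    interpolated at reference positions plus each offset.
    """
    _check_overlap(eval_plane, ref)
    ref_max = float(ref.values.max())
    if ref_max <= 0:
        raise ValueError("reference plane has no positive dose")
    dd_abs = crit.dose_diff_pct / 100.0 * ref_max
    scored = ref.values >= crit.threshold_pct / 100.0 * ref_max
    ridx, cidx = np.nonzero(scored)
    x = ref.x_coords[cidx]
    y = ref.y_coords[ridx]
    ref_dose = ref.values[ridx, cidx]

    best = np.full(ref_dose.shape, np.inf)
    active = np.arange(ref_dose.size)
    for dx, dy, r2n in _search_offsets(crit):
        if active.size == 0:
            break
        vals = _bilinear(eval_plane, x[active] + dx, y[active] + dy)
        cand = ((vals - ref_dose[active]) / dd_abs) ** 2 + r2n
        np.minimum.at(best, active, np.where(np.isnan(cand), np.inf, cand))
        active = active[best[active] > r2n]

    gamma = np.sqrt(best)
    gmap = np.full(ref.values.shape, np.nan)
    gmap[ridx, cidx] = gamma
    finite = np.isfinite(gamma)
    pass_rate = 100.0 * float(np.count_nonzero(gamma[finite] <= 1.0)) / max(
        gamma.size, 1
    )
    return GammaResult(gmap, pass_rate, crit)


def _bilinear(plane: DosePlane, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
    """Bilinear interpolation; NaN outside the plane's pixel-center extent."""
    row, col = plane.mm_to_index(x_mm, y_mm)
    h, w = plane.values.shape
    out = np.full(np.shape(row), np.nan)
    if h < 2 or w < 2:
        raise ValueError("bilinear sampling needs at least a 2 x 2 plane")
    ok = (row >= 0) & (row <= h - 1) & (col >= 0) & (col <= w - 1)
    if not np.any(ok):
        return out
    r, c = row[ok], col[ok]
    r0 = np.clip(np.floor(r).astype(int), 0, h - 2)
    c0 = np.clip(np.floor(c).astype(int), 0, w - 2)
    fr, fc = r - r0, c - c0
    v = plane.values
    out[ok] = (
        v[r0, c0] * (1 - fr) * (1 - fc)
        + v[r0 + 1, c0] * fr * (1 - fc)
        + v[r0, c0 + 1] * (1 - fr) * fc
        + v[r0 + 1, c0 + 1] * fr * fc
    )
    return out


def gamma_bruteforce(
    eval_plane: DosePlane, ref: DosePlane, crit: GammaCriteria = GammaCriteria()
) -> GammaResult:
    """Exhaustive-search gamma oracle for small grids (<= 128 x 128).

    Evaluates every search-disc sample for every scored reference pixel with
    its own plain bilinear interpolation; no pruning, no shared internals
    with :func:`gamma_index`.
    """
    _check_overlap(eval_plane, ref)
    if max(ref.values.shape) > 128:
        raise ValueError("brute-force gamma is restricted to grids <= 128 px")
    ref_max = float(ref.values.max())
    if ref_max <= 0:
        raise ValueError("reference plane has no positive dose")
    dd_abs = crit.dose_diff_pct / 100.0 * ref_max
    thr = crit.threshold_pct / 100.0 * ref_max

    offsets = _search_offsets(crit)
    dxs, dys, r2n = offsets[:, 0], offsets[:, 1], offsets[:, 2]
    ev = eval_plane.values
    h, w = ev.shape
    sx = eval_plane.spacing_mm
    x0 = eval_plane.x_coords[0]
    y0 = eval_plane.y_coords[0]

    gmap = np.full(ref.values.shape, np.nan)
    n_pass = 0
    n_scored = 0
    xs, ys = ref.x_coords, ref.y_coords
    for i in range(ref.values.shape[0]):
        for j in range(ref.values.shape[1]):
            d_ref = ref.values[i, j]
            if d_ref < thr:
                continue
            n_scored += 1
            col = (xs[j] + dxs - x0) / sx
            row = (ys[i] + dys - y0) / sx
            ok = (row >= 0) & (row <= h - 1) & (col >= 0) & (col <= w - 1)
            g2 = np.inf
            if np.any(ok):
                r, c = row[ok], col[ok]
                r0 = np.minimum(np.floor(r).astype(int), h - 2)
                c0 = np.minimum(np.floor(c).astype(int), w - 2)
                fr, fc = r - r0, c - c0
                vals = (
                    ev[r0, c0] * (1 - fr) * (1 - fc)
                    + ev[r0 + 1, c0] * fr * (1 - fc)
                    + ev[r0, c0 + 1] * (1 - fr) * fc
                    + ev[r0 + 1, c0 + 1] * fr * fc
                )
                g2 = float(np.min(((vals - d_ref) / dd_abs) ** 2 + r2n[ok]))
            gmap[i, j] = np.sqrt(g2)
            if gmap[i, j] <= 1.0:
                n_pass += 1
    pass_rate = 100.0 * n_pass / max(n_scored, 1)
    return GammaResult(gmap, pass_rate, crit)


# -- beam profiles ---------------------------------------------------------------


@dataclass(frozen=True)
class ProfileStats:
    flatness_pct: float
    symmetry_pct: float
    penumbra_left_mm: float
    penumbra_right_mm: float


def profile_metrics(
    profile: np.ndarray, spacing_mm: float, field_width_mm: float
) -> ProfileStats:
    """TG-45 flatness, symmetry and 80-20% penumbra of a 1D beam profile.

    The profile is assumed centered on the beam axis with uniform sample
    spacing; it must extend beyond both field edges so that the 20% crossing
    exists on each side.
    """
    d = np.asarray(profile, dtype=float)
    n = d.size
    x = (np.arange(n) - (n - 1) / 2.0) * spacing_mm
    d0 = float(np.interp(0.0, x, d))
    if d0 <= 0:
        raise ValueError("central-axis dose must be positive")

    central = np.abs(x) <= 0.8 * field_width_mm / 2.0
    if not np.any(central):
        raise ValueError("profile does not cover the central field region")
    dc = d[central]
    flatness = 100.0 * (dc.max() - dc.min()) / (dc.max() + dc.min())
    xc = x[central]
    mirrored = np.interp(-xc, x, d)
    symmetry = 100.0 * float(np.max(np.abs(dc - mirrored))) / d0

    pen_l = _crossing(x, d, 0.8 * d0, "left") - _crossing(x, d, 0.2 * d0, "left")
    pen_r = _crossing(x, d, 0.2 * d0, "right") - _crossing(x, d, 0.8 * d0, "right")
    return ProfileStats(float(flatness), float(symmetry), float(pen_l), float(pen_r))


def _crossing(x: np.ndarray, d: np.ndarray, level: float, side: str) -> float:
    """Outermost linear-interpolated crossing of ``level`` on one edge."""
    mid = int(np.argmin(np.abs(x)))
    if side == "left":
        idx = range(0, mid)
        for i in idx:
            if d[i] < level <= d[i + 1]:
                f = (level - d[i]) / (d[i + 1] - d[i])
                return float(x[i] + f * (x[i + 1] - x[i]))
    else:
        for i in range(len(x) - 2, mid - 1, -1):
            if d[i + 1] < level <= d[i]:
                f = (level - d[i]) / (d[i + 1] - d[i])
                return float(x[i] + f * (x[i + 1] - x[i]))
    raise ValueError(f"profile does not cross {level:.3g} on the {side} edge")


# -- percent depth dose ----------------------------------------------------------


def pdd_compare(
    measured, reference, norm_depth_cm: float = 5.0
) -> pd.Series:
    """Per-depth relative errors (%) after normalizing at ``norm_depth_cm``.

    ``measured`` holds (depth cm, dose) pairs and ``reference`` (depth cm,
    percent) pairs; the measured series is rescaled so its value at the
    normalization depth equals the reference value there, then errors are
    reported at the common depths.
    """
    meas = np.asarray(measured, dtype=float)
    ref = np.asarray(reference, dtype=float)
    m_at = _value_at_depth(meas, norm_depth_cm, "measured")
    r_at = _value_at_depth(ref, norm_depth_cm, "reference")
    if m_at == 0:
        raise ValueError("measured dose at the normalization depth is zero")
    scale = r_at / m_at
    ref_by_depth = {round(dep, 6): val for dep, val in ref}
    errors = {}
    for dep, val in meas:
        key = round(dep, 6)
        if key in ref_by_depth and ref_by_depth[key] != 0:
            errors[dep] = 100.0 * (val * scale - ref_by_depth[key]) / ref_by_depth[key]
    return pd.Series(errors, name="relative_error_pct").sort_index()


def _value_at_depth(series: np.ndarray, depth: float, label: str) -> float:
    hit = np.isclose(series[:, 0], depth)
    if not np.any(hit):
        raise ValueError(f"{label} series does not contain the {depth} cm depth")
    return float(series[hit, 1][0])


# -- time-resolved accumulation ---------------------------------------------------


def cumulative_series(
    stack: FrameStack, segments: list[BeamSegment], chain
) -> list[tuple[float, DosePlane]]:
    """Running cumulative dose sampled at segment end boundaries.

    ``chain`` is any object with an ``intensity_to_dose(accumulated_frame)
    -> DosePlane`` method (the pipeline's reconstruction chain); if it also
    carries FBNR parameters in an ``fbnr`` attribute, each segment is
    noise-filtered as its own sub-stack before accumulation.  The returned
    times are the segment end boundaries in seconds; finer 1/fps granularity
    is available by accumulating sub-segments.
    """
    from .fbnr import fbnr_filter

    fbnr_params = getattr(chain, "fbnr", None)
    series: list[tuple[float, DosePlane]] = []
    total: DosePlane | None = None
    for seg in segments:
        sub = FrameStack(stack.frames[seg.start:seg.end + 1], stack.fps)
        if fbnr_params is not None:
            sub = fbnr_filter(sub, fbnr_params)
        plane = chain.intensity_to_dose(sub.frames.sum(axis=0, dtype=np.float64))
        total = plane if total is None else total + plane
        series.append(((seg.end + 1) / stack.fps, total))
    return series
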