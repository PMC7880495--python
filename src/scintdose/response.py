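"""Brightness-domain corrections and the brightness-to-dose calibration.

Two multiplicative effects make raw rectified brightness non-uniform even for
a flat dose: the inverse-square falloff with scintillator-point-to-lens
distance, and the chemical inhomogeneity of the scintillator sheet.  Both are
removed at once with a 2D correction map built from a 20 x 20 cm2 open-field
acquisition: the rectified flat-field is normalized to its isocenter value
and inverted elementwise.  After correction, brightness is proportional to
dose and a linear calibration (ordinary least squares over a 20-200 cGy
range) converts corrected brightness to absorbed dose in cGy.

Output factors — central doses per field size relative to the 10 x 10 cm2
reference field — are provided for detector characterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .planes import DosePlane, _and_masks

ISO_PATCH_PX = 5  # isocenter neighbourhood averaged for noise robustness


@dataclass
class CorrectionMap:
    """Multiplicative 2D flat-field map on the rectified grid, unity at isocenter."""

    values: np.ndarray
    spacing_mm: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        region = self.values if self.mask is None else self.values[self.mask]
        if region.size and (not np.all(np.isfinite(region)) or region.min() <= 0):
            raise ValueError("correction map must be finite and positive")
        h, w = self.values.shape
        center = self.values[h // 2, w // 2]
        if abs(center - 1.0) > 1e-9:
            raise ValueError("correction map must be 1 at the isocenter pixel")

    def save(self, path) -> None:
        DosePlane(self.values, self.spacing_mm, self.mask, unit="relative").save(path)

    @classmethod
    def load(cls, path) -> "CorrectionMap":
        plane = DosePlane.load(path)
        return cls(plane.values, plane.spacing_mm, plane.mask)


def build_correction_map(
    flatfield: DosePlane,
    reference: DosePlane | None = None,
    *,
    field_threshold_rel: float = 0.2,
    smooth_sigma_px: float = 0.0,
) -> CorrectionMap:
    """Invert a rectified open-field acquisition into a correction map.

    The flat-field is normalized to its isocenter value (mean over a
    5 x 5 px patch) and inverted elementwise; pixels below
    ``field_threshold_rel`` of the isocenter value lie outside the open field
    and are masked (map value 1 there).  If a relative ``reference`` plane of
    the true open-field shape is supplied (e.g. an ion-chamber-array
    measurement), the map becomes reference / flat-field so the known
    non-flatness of the beam is not imprinted on later measurements.
    Optional Gaussian smoothing is applied to the flat-field before
    inversion.  Non-positive pixels inside the field region are rejected.
    """
    ff = flatfield.values.astype(float)
    if smooth_sigma_px > 0:
        ff = ndimage.gaussian_filter(ff, smooth_sigma_px)
    iso = _patch_mean(ff)
    if iso <= 0:
        raise ValueError("flat-field has non-positive isocenter value")
    region = ff >= field_threshold_rel * iso
    if flatfield.mask is not None:
        region &= flatfield.mask
    n_bad = int(np.count_nonzero(region & ~(ff > 0)))
    if n_bad:
        raise ValueError(f"{n_bad} non-positive pixels inside the flat-field region")

    ff_rel = ff / iso
    if reference is not None:
        if reference.values.shape != ff.shape:
            raise ValueError("reference plane must match the flat-field grid")
        ref_rel = reference.values / _patch_mean(reference.values)
        ratio = np.ones_like(ff)
        ratio[region] = ref_rel[region] / ff_rel[region]
    else:
        ratio = np.ones_like(ff)
        ratio[region] = 1.0 / ff_rel[region]

    # Exact unity at the isocenter pixel (the patch mean got us within noise).
    h, w = ratio.shape
    ratio = ratio / ratio[h // 2, w // 2]
    return CorrectionMap(ratio, flatfield.spacing_mm, region)


def _patch_mean(values: np.ndarray, patch: int = ISO_PATCH_PX) -> float:
    h, w = values.shape
    r0, c0 = h // 2 - patch // 2, w // 2 - patch // 2
    return float(values[r0:r0 + patch, c0:c0 + patch].mean())


def apply_correction(plane: DosePlane, cmap: CorrectionMap) -> DosePlane:
    """Elementwise product of a plane with the correction map."""
    if plane.values.shape != cmap.values.shape or not np.isclose(
        plane.spacing_mm, cmap.spacing_mm
    ):
        raise ValueError("plane and correction map are on different grids")
    mask = _and_masks(plane.mask, cmap.mask)
    return DosePlane(plane.values * cmap.values, plane.spacing_mm, mask, plane.unit)


@dataclass
class DoseCalibration:
    """Linear brightness -> dose model with fit diagnostics."""

    slope: float          # cGy per brightness unit
    intercept: float      # cGy
    r_squared: float
    rmse: float           # cGy
    dose_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("R^2 must lie in [0, 1]")

    def to_json(self, path) -> None:
        import json

        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "dose_range": list(self.dose_range),
        }
        from pathlib import Path

        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "DoseCalibration":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        return cls(
            payload["slope"], payload["intercept"], payload["r_squared"],
            payload["rmse"], tuple(payload["dose_range"]),
        )


def fit_dose_calibration(points) -> DoseCalibration:
    """Ordinary least-squares line through (brightness, dose cGy) pairs.

    The intercept is free (not forced through zero).  Needs at least two
    distinct brightness values.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least 2 (brightness, dose) pairs")
    b, d = pts[:, 0], pts[:, 1]
    if np.ptp(b) == 0:
        raise ValueError("all brightness values are equal; cannot calibrate")
    fit = stats.linregress(b, d)
    pred = fit.slope * b + fit.intercept
    rmse = float(np.sqrt(np.mean((pred - d) ** 2)))
    ss_res = float(((d - pred) ** 2).sum())
    ss_tot = float(((d - d.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return DoseCalibration(
        float(fit.slope), float(fit.intercept), min(r2, 1.0), rmse,
        (float(d.min()), float(d.max())),
    )


def to_dose(plane: DosePlane, cal: DoseCalibration) -> DosePlane:
    """Convert corrected brightness to absorbed dose, clipped at 0 cGy."""
    dose = np.maximum(cal.slope * plane.values + cal.intercept, 0.0)
    return DosePlane(dose, plane.spacing_mm, plane.mask, unit="cGy")


def output_factors(central_doses: dict[float, float]) -> pd.Series:
    """Central doses per square field size, normalized to the 10 cm field.

    ``central_doses`` maps side length (cm) to central dose; the 10 x 10 cm2
    reference field must be present.
    """
    sizes = sorted(central_doses)
    ref = None
    for s in sizes:
        if np.isclose(s, 10.0):
            ref = central_doses[s]
    if ref is None:
        raise ValueError("the 10 x 10 cm2 reference field is missing")
    if ref <= 0:
        raise ValueError("reference-field dose must be positive")
    return pd.Series(
        {s: central_doses[s] / ref for s in sizes}, name="output_factor"
    )
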