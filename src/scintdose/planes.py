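"""Physical 2D dose/intensity grids and their on-disk representation.

A :class:`DosePlane` is a square-pixel 2D grid of absorbed dose (cGy) or
raw brightness with a known pixel pitch in mm.  The isocenter sits at the
grid center; physical coordinates are

    x_mm = (col - (W - 1) / 2) * spacing_mm
    y_mm = (row - (H - 1) / 2) * spacing_mm

i.e. both axes increase with the array index (image convention).  Planes are
persisted as a plain CSV grid next to a small JSON header, and can be
imported from / exported to DICOM RT Dose for interoperability with
treatment-planning systems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage


@dataclass
class DosePlane:
    """A 2D dose (cGy) or intensity grid with square pixels.

    Parameters
    ----------
    values :
        ``(H, W)`` array.  Doses are non-negative; raw intensity planes may
        carry any finite values.
    spacing_mm :
        Pixel pitch in mm (square pixels).
    mask :
        Optional boolean validity mask, ``True`` where the value is trusted
        (e.g. inside the camera's field of view after rectification).
    unit :
        Free-form unit label, ``"cGy"`` for calibrated planes.
    """

    values: np.ndarray
    spacing_mm: float
    mask: np.ndarray | None = None
    unit: str = "cGy"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DosePlane values must be 2D")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def x_coords(self) -> np.ndarray:
        w = self.values.shape[1]
        return (np.arange(w) - (w - 1) / 2.0) * self.spacing_mm

    @property
    def y_coords(self) -> np.ndarray:
        h = self.values.shape[0]
        return (np.arange(h) - (h - 1) / 2.0) * self.spacing_mm

    def extent_mm(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of pixel centers."""
        x, y = self.x_coords, self.y_coords
        return float(x[0]), float(x[-1]), float(y[0]), float(y[-1])

    def mm_to_index(self, x_mm, y_mm) -> tuple[np.ndarray, np.ndarray]:
        """Fractional (row, col) indices for physical coordinates."""
        h, w = self.values.shape
        col = np.asarray(x_mm, dtype=float) / self.spacing_mm + (w - 1) / 2.0
        row = np.asarray(y_mm, dtype=float) / self.spacing_mm + (h - 1) / 2.0
        return row, col

    def sample(self, x_mm, y_mm, *, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Interpolate the plane at physical coordinates (bilinear default)."""
        row, col = self.mm_to_index(x_mm, y_mm)
        return ndimage.map_coordinates(
            self.values, np.vstack([np.ravel(row), np.ravel(col)]),
            order=order, mode="constant", cval=cval,
        ).reshape(np.shape(row))

    def central_value(self, patch_px: int = 5) -> float:
        """Mean over the central ``patch_px x patch_px`` pixels."""
        h, w = self.values.shape
        r0 = max(h // 2 - patch_px // 2, 0)
        c0 = max(w // 2 - patch_px // 2, 0)
        return float(self.values[r0:r0 + patch_px, c0:c0 + patch_px].mean())

    def profile(self, axis: str = "x", offset_mm: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """1D profile through the isocenter (or offset from it).

        Returns ``(positions_mm, doses)`` sampled at grid pitch along the
        requested axis.
        """
        if axis == "x":
            pos = self.x_coords
            vals = self.sample(pos, np.full_like(pos, offset_mm))
        elif axis == "y":
            pos = self.y_coords
            vals = self.sample(np.full_like(pos, offset_mm), pos)
        else:
            raise ValueError("axis must be 'x' or 'y'")
        return pos, vals

    # -- arithmetic helpers --------------------------------------------------

    def _check_same_grid(self, other: "DosePlane") -> None:
        if self.values.shape != other.values.shape or not np.isclose(
            self.spacing_mm, other.spacing_mm
        ):
            raise ValueError("planes are on different grids")

    def __add__(self, other: "DosePlane") -> "DosePlane":
        self._check_same_grid(other)
        mask = _and_masks(self.mask, other.mask)
        return DosePlane(self.values + other.values, self.spacing_mm, mask, self.unit)

    def scaled(self, factor: float) -> "DosePlane":
        return DosePlane(self.values * factor, self.spacing_mm, self.mask, self.unit)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write as ``<path>.csv`` grid plus ``<path>.json`` header."""
        path = Path(path)
        base = path.with_suffix("") if path.suffix in {".csv", ".json"} else path
        np.savetxt(base.with_suffix(".csv"), self.values, delimiter=",", fmt="%.8g")
        header = {
            "spacing_mm": self.spacing_mm,
            "shape": list(self.values.shape),
            "unit": self.unit,
            "origin": "isocenter at grid center",
        }
        if self.mask is not None:
            header["mask_rle"] = _mask_to_rle(self.mask)
        base.with_suffix(".json").write_text(json.dumps(header, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "DosePlane":
        path = Path(path)
        base = path.with_suffix("") if path.suffix in {".csv", ".json"} else path
        values = np.loadtxt(base.with_suffix(".csv"), delimiter=",", ndmin=2)
        header = json.loads(base.with_suffix(".json").read_text())
        mask = None
        if "mask_rle" in header:
            mask = _rle_to_mask(header["mask_rle"], tuple(header["shape"]))
        return cls(values, float(header["spacing_mm"]), mask, header.get("unit", "cGy"))


def resample_to_grid(plane: DosePlane, side_mm: float, pixels: int) -> DosePlane:
    """Bilinearly resample a plane onto a centered square grid.

    The output pitch is exactly ``side_mm / pixels``; points outside the
    source extent are zero.
    """
    pitch = side_mm / pixels
    coords = (np.arange(pixels) - (pixels - 1) / 2.0) * pitch
    xx, yy = np.meshgrid(coords, coords)
    return DosePlane(plane.sample(xx, yy), pitch, unit=plane.unit)


def _and_masks(a: np.ndarray | None, b: np.ndarray | None) -> np.ndarray | None:
    if a is None:
        return None if b is None else b.copy()
    if b is None:
        return a.copy()
    return a & b


def _mask_to_rle(mask: np.ndarray) -> list[int]:
    """Run lengths of the flattened mask, starting with a run of False."""
    flat = mask.ravel()
    if flat.size == 0:
        return []
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0]:  # convention: first run counts False pixels
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_to_mask(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for r in runs:
        if val:
            flat[pos:pos + r] = True
        pos += r
        val = not val
    return flat.reshape(shape)


# -- DICOM RT Dose interoperability ------------------------------------------


def plane_from_rtdose(path: str | Path) -> DosePlane:
    """Read the first frame of a DICOM RT Dose file as a :class:`DosePlane`."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    if arr.ndim == 3:
        arr = arr[0]
    scale = float(getattr(ds, "DoseGridScaling", 1.0))
    spacing = ds.PixelSpacing
    if not np.isclose(float(spacing[0]), float(spacing[1])):
        raise ValueError("non-square RT Dose pixels are not supported")
    # DoseUnits GY -> cGy
    unit = str(getattr(ds, "DoseUnits", "GY")).upper()
    factor = 100.0 if unit == "GY" else 1.0
    return DosePlane(arr * scale * factor, float(spacing[0]), unit="cGy")


def plane_to_rtdose(plane: DosePlane, path: str | Path) -> None:
    """Write a plane as a minimal single-frame DICOM RT Dose (GY units)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.2")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    gray = plane.values / 100.0  # cGy -> Gy
    vmax = float(gray.max()) if gray.size else 0.0
    scaling = vmax / 65535.0 if vmax > 0 else 1.0
    pixels = np.round(gray / scaling).astype(np.uint16) if vmax > 0 else gray.astype(np.uint16)
    ds.DoseGridScaling = scaling
    ds.Rows, ds.Columns = plane.values.shape
    ds.PixelSpacing = [plane.spacing_mm, plane.spacing_mm]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = pixels.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
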