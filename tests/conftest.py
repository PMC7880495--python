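"""Shared fixtures: the synthetic bench (camera + calibration artifacts).

The bench is built once per session at a desk-scale rectified grid
(256 px over 176 mm) and reused by the pipeline, metrics and acceptance
tests; its study conditions are the generator defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from scintdose.geometry import GeometryCalibration
from scintdose.pipeline import (
    ReconstructionChain,
    build_dose_calibration,
    build_flatfield_map,
    calibrate_geometry_synthetic,
    default_camera,
    default_chain,
)
from scintdose.response import CorrectionMap, DoseCalibration

GRID_PIXELS = 256


@dataclass
class Bench:
    camera: object
    calibration: GeometryCalibration
    correction: CorrectionMap
    dose_cal: DoseCalibration
    calibration_points: list[tuple[float, float]]
    chain: ReconstructionChain


@pytest.fixture(scope="session")
def bench_camera():
    return default_camera()


@pytest.fixture(scope="session")
def geometry_calib(bench_camera):
    return calibrate_geometry_synthetic(bench_camera, grid_pixels=GRID_PIXELS)


@pytest.fixture(scope="session")
def bench(bench_camera, geometry_calib) -> Bench:
    cmap = build_flatfield_map(bench_camera, geometry_calib)
    dose_cal, points = build_dose_calibration(bench_camera, geometry_calib, cmap)
    chain = default_chain(geometry_calib, cmap, dose_cal)
    return Bench(bench_camera, geometry_calib, cmap, dose_cal, points, chain)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
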