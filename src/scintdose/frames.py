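"""Frame-stack handling: the time-resolved backbone of the dosimeter.

The raw measurement is a video of the scintillator recorded at a fixed frame
rate (24 fps for the reference hardware).  This module provides the in-memory
:class:`FrameStack`, grayscale conversion, detection of beam-on segments of a
step-and-shoot delivery, and per-segment accumulation of the scintillation
signal (the dose surrogate).

Conventions: frames are indexed from 0; pixel coordinate (x, y) is
(column, row) with the origin at the top-left pixel center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class FrameStack:
    """Time-ordered stack of intensity frames.

    ``frames`` is ``(T, H, W)`` for grayscale or ``(T, H, W, 3)`` for RGB;
    intensities are non-negative.  ``fps`` is the frame rate in Hz;
    timestamps are derived as ``t / fps``.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T,H,W) or (T,H,W,3)")
        if self.frames.ndim == 4 and self.frames.shape[-1] != 3:
            raise ValueError("color stacks must have 3 channels")
        if self.frames.shape[0] < 1:
            raise ValueError("a stack needs at least one frame")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.frames.size and float(self.frames.min()) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def mode(self) -> str:
        return "rgb" if self.frames.ndim == 4 else "gray"

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass(frozen=True)
class BeamSegment:
    """A maximal run of beam-on frames, inclusive on both ends."""

    start: int
    end: int
    fps: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must not exceed end")

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def to_grayscale(stack: FrameStack) -> FrameStack:
    """Mix RGB to gray with equal 1:1:1 channel weights (arithmetic mean).

    Equal weights conserve each color channel's contribution regardless of
    the scintillator's emission spectrum.  A gray stack passes through
    unchanged.
    """
    if stack.mode == "gray":
        return stack
    return FrameStack(stack.frames.mean(axis=-1), stack.fps)


def detect_segments(
    stack: FrameStack, rel_threshold: float = 0.05, min_frames: int = 3
) -> list[BeamSegment]:
    """Group frames carrying scintillation signal into beam-on segments.

    A frame is beam-on when its mean intensity is at least ``rel_threshold``
    times the maximum per-frame mean over the stack; maximal runs shorter
    than ``min_frames`` are discarded.  The relative threshold makes the
    rule invariant to uniform intensity scaling.
    """
    if stack.mode != "gray":
        raise ValueError("detect_segments expects a grayscale stack")
    means = stack.frames.reshape(stack.n_frames, -1).mean(axis=1)
    peak = float(means.max())
    if peak <= 0:
        return []
    active = means >= rel_threshold * peak
    segments: list[BeamSegment] = []
    padded = np.concatenate([[False], active, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_frames:
            segments.append(BeamSegment(int(s), int(e), stack.fps))
    return segments


def accumulate_segment(stack: FrameStack, seg: BeamSegment) -> np.ndarray:
    """Elementwise sum of the frames in ``[seg.start, seg.end]``."""
    if seg.start < 0 or seg.end >= stack.n_frames:
        raise ValueError(
            f"segment [{seg.start}, {seg.end}] outside stack of {stack.n_frames} frames"
        )
    return stack.frames[seg.start:seg.end + 1].sum(axis=0, dtype=np.float64)


# -- on-disk stacks: numbered TIFF frames + JSON manifest ----------------------


def write_stack(stack: FrameStack, directory: str | Path) -> Path:
    """Write a stack as numbered float32 TIFF frames plus ``manifest.json``."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    photometric = "rgb" if stack.mode == "rgb" else "minisblack"
    for i in range(stack.n_frames):
        name = f"frame_{i:06d}.tif"
        tifffile.imwrite(
            directory / name, stack.frames[i].astype(np.float32),
            photometric=photometric,
        )
        names.append(name)
    manifest = {
        "fps": stack.fps,
        "n_frames": stack.n_frames,
        "mode": stack.mode,
        "files": names,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def read_stack(directory: str | Path) -> FrameStack:
    """Read a stack written by :func:`write_stack`."""
    import tifffile

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    frames = np.stack(
        [tifffile.imread(directory / name) for name in manifest["files"]]
    )
    return FrameStack(frames, float(manifest["fps"]))
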