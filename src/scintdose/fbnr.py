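"""Frame-based noise reduction (FBNR): temporal removal of hot pixels.

Scattered photons striking the image sensor directly produce hot pixels —
instantaneous, high-intensity noise lasting a frame or two.  Spatial filters
(median, moving average) would blur the scintillation image; FBNR instead
exploits the transience of hot pixels: a pixel whose intensity persists over
several consecutive frames is scintillation and is kept, a pixel present
only briefly is a hot pixel and is zeroed.  Spatial resolution is untouched.

For frame ``n`` and pixel ``(x, y)`` that is active (intensity strictly above
the activity level), the filter counts the active frames in the window
``[n, n + k]``; if the count falls below the persistence threshold the pixel
is zeroed in frame ``n`` only.  Windows truncated by the end of the stack
scale the threshold by the ratio of actual to nominal window length, so no
frames are fabricated.  Defaults ``k = 5`` and ``threshold = 3``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import FrameStack


@dataclass(frozen=True)
class FbnrParams:
    """Persistence-filter parameters.

    k : window length beyond the current frame (window covers k+1 frames)
    threshold : minimum number of active frames for a pixel to be kept
    activity_level : intensity strictly above which a pixel counts as present
    """

    k: int = 5
    threshold: int = 3
    activity_level: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.threshold <= self.k + 1:
            raise ValueError("threshold must satisfy 1 <= threshold <= k + 1")
        if self.activity_level < 0:
            raise ValueError("activity_level must be >= 0")


def fbnr_filter(stack: FrameStack, params: FbnrParams = FbnrParams()) -> FrameStack:
    """Zero transient (hot) pixels; keep persistent scintillation untouched.

    The filter only ever zeroes values, never increases them, and a signal
    present in every frame passes through bit-identically.
    """
    if stack.mode != "gray":
        raise ValueError("fbnr_filter expects a grayscale stack")
    frames = stack.frames
    t = stack.n_frames
    active = frames > params.activity_level

    # Window count for frame n is cum[min(n+k+1, T)] - cum[n].
    cum = np.concatenate(
        [np.zeros((1,) + frames.shape[1:], dtype=np.int32),
         np.cumsum(active, axis=0, dtype=np.int32)]
    )
    n_idx = np.arange(t)
    hi = np.minimum(n_idx + params.k + 1, t)
    counts = cum[hi] - cum[n_idx]

    # Truncated windows at the stack end scale the threshold proportionally.
    win_len = (hi - n_idx).astype(float)
    eff_threshold = params.threshold * win_len / (params.k + 1)
    transient = active & (counts < eff_threshold[:, None, None])

    out = frames.copy()
    out[transient] = 0
    return FrameStack(out, stack.fps)
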