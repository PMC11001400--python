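"""Detector background and artefact reduction.

Pixel detectors at XFEL sources superimpose fixed-pattern noise, hot pixels
and diffuse scattering background on every frame.  Because most frames in a
serial-crystallography run are misses (no crystal in the beam), a running
estimate of background + artefacts can be built from them: a FIFO buffer of
the most recent non-hit frames is kept and its pixel-wise median is
subtracted from incoming frames before peak detection.  The median (rather
than the mean) is robust to the occasional stray Bragg spot or cosmic in a
buffered frame.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MissBuffer",
    "push_miss",
    "BackgroundEstimate",
    "compute_median_background",
    "subtract_background",
    "maybe_refresh",
]


class MissBuffer:
    """Fixed-capacity FIFO of recent non-hit frames.

    All stored frames must share one shape; the oldest frame is evicted when
    capacity is exceeded.  ``insertion_counter`` counts total pushes over the
    buffer's lifetime (it never decreases), which drives periodic refresh of
    the background estimate.
    """

    def __init__(self, capacity: int = 100):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._frames: deque[np.ndarray] = deque(maxlen=capacity)
        self.insertion_counter = 0

    def __len__(self) -> int:
        return len(self._frames)

    @property
    def frames(self) -> list[np.ndarray]:
        return list(self._frames)

    @property
    def shape(self) -> tuple[int, int] | None:
        return self._frames[0].shape if self._frames else None

    def push(self, frame: np.ndarray) -> "MissBuffer":
        frame = np.asarray(frame)
        if frame.ndim != 2:
            raise ValueError("frames must be 2-D")
        if self._frames and frame.shape != self.shape:
            raise ValueError(
                f"frame shape {frame.shape} does not match buffer "
                f"shape {self.shape}"
            )
        self._frames.append(frame)
        self.insertion_counter += 1
        return self


# module-level alias matching the verb used throughout the pipeline
def push_miss(buffer: MissBuffer, frame: np.ndarray) -> MissBuffer:
    """Append a non-hit frame, evicting the oldest if at capacity."""
    return buffer.push(frame)


@dataclass
class BackgroundEstimate:
    """Pixel-wise median over a miss buffer, with staleness bookkeeping."""

    median_frame: np.ndarray
    n_source_frames: int
    stale_counter: int = 0
    #: buffer insertion_counter at the time this estimate was computed
    refreshed_at: int = 0


def compute_median_background(buffer: MissBuffer) -> BackgroundEstimate:
    """Median of each pixel across all buffered frames.

    For an even number of frames the median is the arithmetic mean of the
    two central order statistics, matching a full per-pixel sort.
    """
    if len(buffer) == 0:
        raise ValueError("cannot estimate background from an empty buffer")
    stack = np.stack(buffer.frames)
    median = np.median(stack, axis=0)
    return BackgroundEstimate(
        median_frame=median,
        n_source_frames=len(buffer),
        stale_counter=0,
        refreshed_at=buffer.insertion_counter,
    )


def subtract_background(frame: np.ndarray, bg: BackgroundEstimate) -> np.ndarray:
    """Subtract the median background, clamping negatives to zero.

    Peak detection thresholds on positive photon counts, so negative
    residuals carry no information for this pipeline.
    """
    frame = np.asarray(frame)
    if frame.shape != bg.median_frame.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match background "
            f"shape {bg.median_frame.shape}"
        )
    return np.maximum(frame - bg.median_frame, 0.0)


def maybe_refresh(
    buffer: MissBuffer, bg: BackgroundEstimate, update_every: int = 10
) -> BackgroundEstimate:
    """Recompute the median once ``update_every`` insertions have accrued.

    Otherwise the existing estimate is returned with its stale counter
    bumped.  A fixed insertion period keeps the online pipeline
    deterministic.
    """
    if update_every < 1:
        raise ValueError("update_every must be >= 1")
    if buffer.insertion_counter - bg.refreshed_at >= update_every:
        return compute_median_background(buffer)
    bg.stale_counter += 1
    return bg
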