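"""Synthetic diffraction-frame generator.

Produces labelled hit/miss detector frames with ground-truth peak tables so
that every downstream stage of the hit-finding pipeline (background
subtraction, peak detection, descriptors, classification) can be exercised
without facility data.

A *miss* frame is Poisson counting noise on top of a static fixed-pattern
detector offset (smooth low-frequency gain structure plus hot pixels).  A
*hit* frame adds planted Bragg peaks: either single bright pixels or
discretized isotropic Gaussian blobs truncated at 3 sigma, apex-normalized
to the drawn amplitude.  This is a statistical stand-in, not a physical
diffraction simulation: there is no Ewald-sphere geometry, no unit cell and
no detector panel gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "PeakPlacementError",
    "make_fixed_pattern",
    "generate_miss_frame",
    "generate_hit_frame",
    "generate_dataset",
    "generate_five_class_dataset",
    "FIVE_CLASS_NAMES",
    "FIVE_CLASS_PEAK_COUNTS",
]

#: minimum frame edge: the radius-3 detection circle plus the refinement
#: margin must fit with room to spare
_MIN_EDGE = 16

#: planted apices stay this far from every frame border so that the
#: radius-3 circle and the 3x3 refinement window always fit around them
BORDER_MARGIN = 4

#: attempts per peak before giving up on the separation constraint
PLACEMENT_RETRY_CAP = 1000


class PeakPlacementError(RuntimeError):
    """Raised when the pairwise-separation constraint cannot be satisfied."""


@dataclass(frozen=True)
class SimulationParams:
    """Conditions of one simulated run.

    Parameters
    ----------
    frame_height, frame_width : int
        Detector dimensions in pixels; both must be >= 16.
    background_rate : float
        Mean diffuse-background counts per pixel (Poisson rate).
    hot_pixel_fraction : float
        Fraction of pixels stuck at ``hot_pixel_value`` in the fixed pattern.
    hot_pixel_value : float
        Counts recorded by a hot pixel.
    fixed_pattern_amplitude : float
        Scale of the smooth low-frequency static offset field, in counts.
    n_peaks_range : (int, int)
        Inclusive interval for the number of planted peaks per hit frame.
    peak_amplitude_range : (float, float)
        Inclusive interval for the apex amplitude of each planted peak.
    peak_sigma_range : (float, float)
        Interval for the Gaussian width in pixels.  The blob footprint is
        truncated at 3 sigma, so any sigma below 1/3 px renders as a
        single-pixel peak.  The default tops out at 1.0 px (FWHM ~2.4 px):
        Bragg peaks on photon-counting pixel detectors span one to a few
        pixels, and this keeps each peak's apex unambiguous at the pixel
        level.
    min_peak_separation : float
        Minimum pairwise Euclidean distance between planted apices, pixels.
    poisson_peaks : bool
        If True, resample the rendered peak profile through a Poisson draw.
        Off by default so that apex ground truth stays exact.
    seed : int
        Run seed; per-frame streams are derived from it.
    """

    frame_height: int = 256
    frame_width: int = 256
    background_rate: float = 1.0
    hot_pixel_fraction: float = 0.001
    hot_pixel_value: float = 500.0
    fixed_pattern_amplitude: float = 5.0
    n_peaks_range: Tuple[int, int] = (5, 20)
    peak_amplitude_range: Tuple[float, float] = (100.0, 300.0)
    peak_sigma_range: Tuple[float, float] = (0.0, 1.0)
    min_peak_separation: float = 8.0
    poisson_peaks: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_height < _MIN_EDGE or self.frame_width < _MIN_EDGE:
            raise ValueError(
                f"frame dimensions must be >= {_MIN_EDGE}, got "
                f"{self.frame_height}x{self.frame_width}"
            )
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not 0.0 <= self.hot_pixel_fraction <= 1.0:
            raise ValueError("hot_pixel_fraction must lie in [0, 1]")
        if self.min_peak_separation < 1:
            raise ValueError("min_peak_separation must be >= 1")
        lo, hi = self.n_peaks_range
        if lo < 0 or hi < lo:
            raise ValueError("n_peaks_range must be a nonneg. interval")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.frame_height, self.frame_width)


@dataclass(frozen=True)
class GroundTruth:
    """Planted-peak table and class label for one frame.

    ``peaks`` holds ``(row, col, amplitude)`` apex records; miss frames have
    an empty list.  ``label`` is ``"hit"`` or ``"miss"`` in the binary mode,
    or one of the five-class names.
    """

    peaks: Tuple[Tuple[int, int, float], ...] = field(default_factory=tuple)
    label: str = "miss"


def _frame_rng(seed: int, frame_index: int) -> np.random.Generator:
    # per-frame sub-stream: deterministic hash of (run seed, frame index)
    return np.random.default_rng(np.random.SeedSequence((seed, frame_index)))


def make_fixed_pattern(params: SimulationParams) -> np.ndarray:
    """Static per-pixel detector offset field, reused for a whole run.

    A smooth low-frequency component (coarse uniform grid upsampled with
    cubic interpolation, scaled by ``fixed_pattern_amplitude``) models gain
    structure; ``round(hot_pixel_fraction * H * W)`` pixels are then
    overwritten with ``hot_pixel_value``.  Deterministic for a given seed.
    """
    h, w = params.shape
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0xF1)))
    field_ = np.zeros((h, w), dtype=np.float32)
    if params.fixed_pattern_amplitude > 0:
        coarse_h = max(h // 32, 2) + 1
        coarse_w = max(w // 32, 2) + 1
        coarse = rng.uniform(0.0, 1.0, size=(coarse_h, coarse_w))
        smooth = ndimage.zoom(coarse, (h / coarse_h, w / coarse_w), order=3)
        smooth = np.clip(smooth[:h, :w], 0.0, 1.0)
        if smooth.shape != (h, w):  # zoom can undershoot by a row/col
            padded = np.zeros((h, w))
            padded[: smooth.shape[0], : smooth.shape[1]] = smooth
            padded[smooth.shape[0]:, :] = padded[smooth.shape[0] - 1, :]
            padded[:, smooth.shape[1]:] = padded[:, [smooth.shape[1] - 1]]
            smooth = padded
        field_ += (params.fixed_pattern_amplitude * smooth).astype(np.float32)
    n_hot = int(round(params.hot_pixel_fraction * h * w))
    if n_hot > 0:
        flat = rng.choice(h * w, size=n_hot, replace=False)
        field_.flat[flat] = params.hot_pixel_value
    return field_


def generate_miss_frame(
    params: SimulationParams,
    rng: np.random.Generator,
    fixed_pattern: np.ndarray | None = None,
) -> Tuple[np.ndarray, GroundTruth]:
    """Background-only frame: Poisson noise plus the fixed pattern."""
    if fixed_pattern is None:
        fixed_pattern = make_fixed_pattern(params)
    frame = rng.poisson(params.background_rate, size=params.shape)
    frame = frame.astype(np.float32) + fixed_pattern
    return frame, GroundTruth(peaks=(), label="miss")


def _place_apices(
    params: SimulationParams, rng: np.random.Generator, n_peaks: int
) -> List[Tuple[int, int]]:
    """Rejection-sample apex positions respecting min_peak_separation."""
    h, w = params.shape
    min_sep2 = params.min_peak_separation ** 2
    placed: List[Tuple[int, int]] = []
    for _ in range(n_peaks):
        for _attempt in range(PLACEMENT_RETRY_CAP):
            r = int(rng.integers(BORDER_MARGIN, h - BORDER_MARGIN))
            c = int(rng.integers(BORDER_MARGIN, w - BORDER_MARGIN))
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep2 for pr, pc in placed):
                placed.append((r, c))
                break
        else:
            raise PeakPlacementError(
                f"could not place peak {len(placed) + 1}/{n_peaks} with "
                f"separation {params.min_peak_separation} after "
                f"{PLACEMENT_RETRY_CAP} attempts"
            )
    return placed


def _render_peak(
    frame: np.ndarray, row: int, col: int, amplitude: float, sigma: float
) -> None:
    """Add one apex-normalized peak in place.

    Footprint radius is floor(3*sigma): sigma below 1/3 px gives a
    single-pixel peak; larger sigmas give a truncated Gaussian blob whose
    apex pixel carries exactly ``amplitude``.
    """
    radius = int(np.floor(3.0 * sigma))
    if radius == 0:
        frame[row, col] += amplitude
        return
    dr = np.arange(-radius, radius + 1)
    dd2 = dr[:, None] ** 2 + dr[None, :] ** 2
    blob = amplitude * np.exp(-dd2 / (2.0 * sigma ** 2))
    blob[dd2 > (3.0 * sigma) ** 2] = 0.0
    frame[row - radius: row + radius + 1, col - radius: col + radius + 1] += (
        blob.astype(np.float32)
    )


def generate_hit_frame(
    params: SimulationParams,
    rng: np.random.Generator,
    fixed_pattern: np.ndarray | None = None,
    n_peaks: int | None = None,
) -> Tuple[np.ndarray, GroundTruth]:
    """Hit frame: miss background plus K planted peaks with ground truth.

    K is drawn uniformly from ``n_peaks_range`` unless ``n_peaks`` is given.
    Apices are pairwise >= ``min_peak_separation`` apart and >= 4 px from
    every border.  Raises :class:`PeakPlacementError` if placement fails.
    """
    frame, _ = generate_miss_frame(params, rng, fixed_pattern)
    lo, hi = params.n_peaks_range
    if n_peaks is None:
        n_peaks = int(rng.integers(lo, hi + 1))
    apices = _place_apices(params, rng, n_peaks)
    peaks = []
    for r, c in apices:
        amp = float(rng.uniform(*params.peak_amplitude_range))
        sigma = float(rng.uniform(*params.peak_sigma_range))
        if params.poisson_peaks:
            before = frame.copy()
            _render_peak(frame, r, c, amp, sigma)
            profile = frame - before
            frame = before + rng.poisson(profile).astype(np.float32)
        else:
            _render_peak(frame, r, c, amp, sigma)
        peaks.append((r, c, amp))
    return frame, GroundTruth(peaks=tuple(peaks), label="hit")


def generate_dataset(
    params: SimulationParams, n_hit: int, n_miss: int
) -> Tuple[np.ndarray, List[GroundTruth]]:
    """Stack of ``n_hit`` hit frames followed by ``n_miss`` miss frames.

    Per-frame random streams are derived from ``params.seed`` and the frame
    index, so any single frame is reproducible in isolation and the whole
    stack is bit-identical across calls.
    """
    if n_hit < 0 or n_miss < 0:
        raise ValueError("frame counts must be >= 0")
    pattern = make_fixed_pattern(params)
    frames = np.empty((n_hit + n_miss, *params.shape), dtype=np.float32)
    truths: List[GroundTruth] = []
    for i in range(n_hit + n_miss):
        rng = _frame_rng(params.seed, i)
        if i < n_hit:
            frame, truth = generate_hit_frame(params, rng, pattern)
        else:
            frame, truth = generate_miss_frame(params, rng, pattern)
        frames[i] = frame
        truths.append(truth)
    return frames, truths


FIVE_CLASS_NAMES = ("blank", "no_crystal", "weak", "good", "strong")

#: planted-peak count bands per class; "blank" additionally suppresses the
#: diffuse background entirely (dark frame)
FIVE_CLASS_PEAK_COUNTS = {
    "blank": (0, 0),
    "no_crystal": (0, 0),
    "weak": (1, 5),
    "good": (6, 20),
    "strong": (21, 60),
}


def generate_five_class_dataset(
    params: SimulationParams, n_per_class: int
) -> Tuple[np.ndarray, List[GroundTruth]]:
    """Optional five-class corpus (blank / no-crystal / weak / good / strong).

    Classes map to planted-peak count bands; this emulates a graded label
    taxonomy without claiming fidelity to any external data set.
    """
    pattern = make_fixed_pattern(params)
    frames = []
    truths: List[GroundTruth] = []
    index = 0
    for name in FIVE_CLASS_NAMES:
        lo, hi = FIVE_CLASS_PEAK_COUNTS[name]
        for _ in range(n_per_class):
            rng = _frame_rng(params.seed, index)
            if name == "blank":
                frame = np.zeros(params.shape, dtype=np.float32)
                truth = GroundTruth(peaks=(), label=name)
            elif hi == 0:
                frame, _t = generate_miss_frame(params, rng, pattern)
                truth = GroundTruth(peaks=(), label=name)
            else:
                n_peaks = int(rng.integers(lo, hi + 1))
                frame, t = generate_hit_frame(params, rng, pattern, n_peaks)
                truth = GroundTruth(peaks=t.peaks, label=name)
            frames.append(frame)
            truths.append(truth)
            index += 1
    return np.stack(frames), truths
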