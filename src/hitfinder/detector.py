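"""MP-FAST Bragg-peak key-point detection.

The detector adapts the FAST corner test to find peak apices in a
(background-subtracted) diffraction frame.  For each interior pixel p:

1. *Threshold*: if I(p) <= tr (default 20 counts) the pixel is ignored —
   it cannot be a peak.
2. *Cardinal test*: I(p) is compared with the four compass-point pixels of
   the radius-3 FAST circle — pixels 1, 5, 9 and 13, i.e. offsets
   (-3,0), (0,+3), (+3,0), (0,-3).  p is a candidate if it is strictly
   greater than at least 3 of the 4.
3. *Apex refinement*: Bragg peaks can span several pixels, so the candidate
   is replaced by the maximum over its 3x3 neighbourhood; ties go to the
   candidate, then to the smallest (row, col).
4. *Dedup*: candidates refining to the same apex are merged.

Two realizations are provided.  ``order_independent`` (canonical) evaluates
every pixel independently and so gives the same answer regardless of scan
order or parallel decomposition; ``sequential_flags`` is the raster-scan
variant with a per-pixel checked-flag grid (a 3x3 block of flags is set
around each processed candidate), which can differ on adjacent-candidate
edge cases.  ``brute_force_oracle`` is a deliberately naive loop-based
restatement of the canonical semantics kept for testing only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

__all__ = [
    "DetectorParams",
    "KeyPoint",
    "cardinal_candidate_test",
    "refine_apex",
    "detect_keypoints",
    "brute_force_oracle",
    "chunked_detect",
]

logger = logging.getLogger(__name__)

#: radius of the FAST test circle; pixels 1/5/9/13 sit at this offset
CIRCLE_RADIUS = 3

#: cardinal offsets (pixel 1 = north, 5 = east, 9 = south, 13 = west)
CARDINAL_OFFSETS = ((-3, 0), (0, 3), (3, 0), (0, -3))

# 3x3 refinement window in tie-break order: candidate first, then the
# eight neighbours in row-major order (smallest row, then smallest col)
_REFINE_OFFSETS = (
    (0, 0),
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass(frozen=True)
class DetectorParams:
    """MP-FAST configuration.

    ``threshold`` is the minimum intensity tr in counts (default 20); a
    pixel at or below it is never a candidate.  ``min_cardinal_wins`` is the
    number of the four cardinal circle pixels the candidate must strictly
    exceed (default 3 of 4).  ``mode`` selects the canonical
    order-independent semantics or the sequential flagged raster scan.
    """

    threshold: float = 20.0
    circle_radius: int = CIRCLE_RADIUS
    min_cardinal_wins: int = 3
    dedup: bool = True
    mode: str = "order_independent"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.circle_radius != CIRCLE_RADIUS:
            raise ValueError("circle_radius is fixed at 3")
        if not 1 <= self.min_cardinal_wins <= 4:
            raise ValueError("min_cardinal_wins must be in 1..4")
        if self.mode not in ("order_independent", "sequential_flags"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True, order=True)
class KeyPoint:
    """Detected Bragg-peak apex: 0-based (row, col) and apex intensity."""

    row: int
    col: int
    intensity: float


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    h, w = frame.shape
    if h <= 2 * CIRCLE_RADIUS or w <= 2 * CIRCLE_RADIUS:
        raise ValueError(
            f"frame {h}x{w} too small: both dimensions must exceed "
            f"{2 * CIRCLE_RADIUS}"
        )
    return frame


def cardinal_candidate_test(
    frame: np.ndarray, row: int, col: int, params: DetectorParams
) -> bool:
    """High-speed candidate test at one pixel.

    True iff I(row, col) > tr and strictly greater than the intensity at
    >= ``min_cardinal_wins`` of the four cardinal circle pixels.  Pixels at
    or below tr short-circuit to False without touching neighbours.
    """
    frame = np.asarray(frame)
    h, w = frame.shape
    r0 = CIRCLE_RADIUS
    if not (r0 <= row < h - r0 and r0 <= col < w - r0):
        raise IndexError(
            f"({row}, {col}) is within {r0} px of a border of {h}x{w}"
        )
    center = frame[row, col]
    if center <= params.threshold:
        return False
    wins = sum(
        1 for dr, dc in CARDINAL_OFFSETS if center > frame[row + dr, col + dc]
    )
    return wins >= params.min_cardinal_wins


def refine_apex(frame: np.ndarray, row: int, col: int) -> KeyPoint:
    """Move a candidate to the 3x3 maximum (multi-pixel peak apex).

    Ties resolve to the candidate itself, then to the smallest row, then the
    smallest column, so the result is a deterministic total order.
    """
    frame = np.asarray(frame)
    h, w = frame.shape
    if not (1 <= row < h - 1 and 1 <= col < w - 1):
        raise IndexError(f"({row}, {col}) too close to the border of {h}x{w}")
    best_r, best_c = row, col
    best = frame[row, col]
    for dr, dc in _REFINE_OFFSETS[1:]:
        v = frame[row + dr, col + dc]
        if v > best:
            best = v
            best_r, best_c = row + dr, col + dc
    return KeyPoint(row=best_r, col=best_c, intensity=float(best))


def _candidate_mask(
    frame: np.ndarray, params: DetectorParams
) -> np.ndarray:
    """Boolean mask over the full frame; True only at interior candidates."""
    h, w = frame.shape
    r0 = CIRCLE_RADIUS
    interior = frame[r0: h - r0, r0: w - r0]
    wins = np.zeros(interior.shape, dtype=np.int8)
    for dr, dc in CARDINAL_OFFSETS:
        shifted = frame[r0 + dr: h - r0 + dr, r0 + dc: w - r0 + dc]
        wins += interior > shifted
    mask = np.zeros((h, w), dtype=bool)
    mask[r0: h - r0, r0: w - r0] = (interior > params.threshold) & (
        wins >= params.min_cardinal_wins
    )
    return mask


def _refine_many(
    frame: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized 3x3 argmax with the candidate-first tie rule."""
    vals = np.stack(
        [frame[rows + dr, cols + dc] for dr, dc in _REFINE_OFFSETS]
    )
    # argmax returns the first maximum, which realizes the tie-break order
    best = np.argmax(vals, axis=0)
    off = np.asarray(_REFINE_OFFSETS)
    return rows + off[best, 0], cols + off[best, 1]


def _finalize(
    frame: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    dedup: bool,
) -> List[KeyPoint]:
    """Apply the border rule, deduplicate and sort by (row, col)."""
    h, w = frame.shape
    r0 = CIRCLE_RADIUS
    keep = (
        (rows >= r0) & (rows < h - r0) & (cols >= r0) & (cols < w - r0)
    )
    rows, cols = rows[keep], cols[keep]
    pairs = np.stack([rows, cols], axis=1)
    if dedup:
        pairs = np.unique(pairs, axis=0) if len(pairs) else pairs
    else:
        order = np.lexsort((pairs[:, 1], pairs[:, 0])) if len(pairs) else []
        pairs = pairs[order] if len(pairs) else pairs
    return [
        KeyPoint(row=int(r), col=int(c), intensity=float(frame[r, c]))
        for r, c in pairs
    ]


def _detect_order_independent(
    frame: np.ndarray,
    params: DetectorParams,
    row_range: Tuple[int, int] | None = None,
) -> List[KeyPoint]:
    mask = _candidate_mask(frame, params)
    if row_range is not None:
        lo, hi = row_range
        mask[:lo, :] = False
        mask[hi:, :] = False
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return []
    rows, cols = _refine_many(frame, rows, cols)
    return _finalize(frame, rows, cols, params.dedup)


def _detect_sequential_flags(
    frame: np.ndarray, params: DetectorParams
) -> List[KeyPoint]:
    h, w = frame.shape
    r0 = CIRCLE_RADIUS
    flags = np.zeros((h, w), dtype=bool)
    rows: List[int] = []
    cols: List[int] = []
    # candidate mask is cheap to precompute; the flag grid then decides
    # which candidates the raster scan actually processes
    mask = _candidate_mask(frame, params)
    for r in range(r0, h - r0):
        for c in range(r0, w - r0):
            if flags[r, c] or not mask[r, c]:
                continue
            # flag the 3x3 block (candidate plus eight neighbours)
            flags[r - 1: r + 2, c - 1: c + 2] = True
            kp = refine_apex(frame, r, c)
            rows.append(kp.row)
            cols.append(kp.col)
    return _finalize(
        frame, np.asarray(rows, dtype=int), np.asarray(cols, dtype=int),
        params.dedup,
    )


def detect_keypoints(
    frame: np.ndarray, params: DetectorParams | None = None
) -> List[KeyPoint]:
    """Detect Bragg-peak key points in one frame.

    Returns key points sorted by (row, col); none lie within 3 px of an
    edge and all have intensity above the threshold.
    """
    params = params or DetectorParams()
    frame = _check_frame(frame)
    if params.mode == "sequential_flags":
        return _detect_sequential_flags(frame, params)
    return _detect_order_independent(frame, params)


def brute_force_oracle(
    frame: np.ndarray, params: DetectorParams | None = None
) -> List[KeyPoint]:
    """Naive loop-based reference detector (order-independent semantics).

    Re-states the threshold test, cardinal test, 3x3 refinement, border rule
    and dedup with explicit Python loops, independently of the vectorized
    path.  Intended for tests; orders of magnitude slower.
    """
    params = params or DetectorParams()
    frame = _check_frame(frame)
    h, w = frame.shape
    tr = params.threshold
    need = params.min_cardinal_wins
    apices = set()
    for r in range(3, h - 3):
        for c in range(3, w - 3):
            center = frame[r, c]
            if center <= tr:
                continue
            wins = 0
            if center > frame[r - 3, c]:
                wins += 1
            if center > frame[r, c + 3]:
                wins += 1
            if center > frame[r + 3, c]:
                wins += 1
            if center > frame[r, c - 3]:
                wins += 1
            if wins < need:
                continue
            # refinement: max over the 3x3 window, candidate wins ties,
            # then row-major order
            best_r, best_c, best = r, c, center
            for dr in (-1, 0, 1):
                for dc in (-1, 1) if dr == 0 else (-1, 0, 1):
                    v = frame[r + dr, c + dc]
                    if v > best:
                        best_r, best_c, best = r + dr, c + dc, v
            if 3 <= best_r < h - 3 and 3 <= best_c < w - 3:
                apices.add((best_r, best_c))
    return [
        KeyPoint(row=r, col=c, intensity=float(frame[r, c]))
        for r, c in sorted(apices)
    ]


def chunked_detect(
    frame: np.ndarray,
    params: DetectorParams | None = None,
    n_chunks: int = 1,
) -> List[KeyPoint]:
    """Detect by splitting the frame into horizontal bands and merging.

    Each band is processed independently with order-independent semantics
    (each band's refinement may read up to one row beyond its range — the
    halo).  The merged, deduplicated result is identical to whole-frame
    detection; this mirrors how the detector decomposes across parallel
    workers.
    """
    params = params or DetectorParams()
    frame = _check_frame(frame)
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    h = frame.shape[0]
    max_chunks = max(1, h // (2 * CIRCLE_RADIUS + 1))
    if n_chunks > max_chunks:
        logger.warning(
            "n_chunks=%d exceeds the feasible maximum for height %d; "
            "clamping to %d", n_chunks, h, max_chunks,
        )
        n_chunks = max_chunks
    bounds = [i * h // n_chunks for i in range(n_chunks + 1)]
    all_points: List[KeyPoint] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        all_points.extend(
            _detect_order_independent(frame, params, row_range=(lo, hi))
        )
    seen = {}
    for kp in all_points:
        seen[(kp.row, kp.col)] = kp
    return [seen[k] for k in sorted(seen)]


def keypoints_to_array(keypoints: List[KeyPoint]) -> np.ndarray:
    """(n, 3) float array of (row, col, intensity) for bulk storage."""
    if not keypoints:
        return np.empty((0, 3), dtype=np.float64)
    return np.asarray(
        [(kp.row, kp.col, kp.intensity) for kp in keypoints], dtype=np.float64
    )
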