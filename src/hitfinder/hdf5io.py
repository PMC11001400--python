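"""HDF5 interchange for frame stacks, peak lists, backgrounds and features.

Layout conventions (recorded as file attributes):

* ``/data``     — (N, H, W) float32 or int32 frame stack, axis order
  (frame, row, col), row 0 at the top, 0-based coordinates.
* ``/labels``   — (N,) integer label codes with attribute ``label_names``
  mapping code -> name.
* ``/truth/*``  — ragged planted-peak tables: ``peak_rows``, ``peak_cols``,
  ``peak_amplitudes`` flattened over frames, ``offsets`` of length N+1 so
  frame i owns slice ``offsets[i]:offsets[i+1]``.
* ``/peaks/*``  — detected key points in the same ragged layout with
  ``intensities`` instead of amplitudes.
* ``/background`` — (H, W) float32 median background.
* ``/features`` — (N, n) descriptor matrix.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .background import BackgroundEstimate
from .detector import KeyPoint
from .synthetic import GroundTruth

__all__ = [
    "save_frames",
    "load_frames",
    "save_background",
    "load_background",
    "save_peaks",
    "load_peaks",
    "peaks_to_csv",
    "save_features",
    "load_features",
]

_AXIS_NOTE = "axis order (frame, row, col); 0-based, row 0 at top"


def _encode_labels(labels: Sequence[str]) -> Tuple[np.ndarray, List[str]]:
    names = sorted(set(labels))
    code_of = {name: i for i, name in enumerate(names)}
    return np.array([code_of[l] for l in labels], dtype=np.int32), names


def save_frames(
    path,
    frames: np.ndarray,
    labels: Sequence[str] | None = None,
    truths: Sequence[GroundTruth] | None = None,
) -> None:
    """Write a frame stack with optional labels and ground-truth peaks."""
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be a 3-D (N, H, W) stack")
    if frames.dtype not in (np.float32, np.int32):
        frames = frames.astype(np.float32)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=frames)
        d.attrs["axis_order"] = _AXIS_NOTE
        if labels is not None:
            codes, names = _encode_labels(labels)
            ld = f.create_dataset("labels", data=codes)
            ld.attrs["label_names"] = names
        if truths is not None:
            rows, cols, amps, offsets = [], [], [], [0]
            for t in truths:
                for r, c, a in t.peaks:
                    rows.append(r)
                    cols.append(c)
                    amps.append(a)
                offsets.append(len(rows))
            g = f.create_group("truth")
            g.create_dataset("peak_rows", data=np.array(rows, dtype=np.int32))
            g.create_dataset("peak_cols", data=np.array(cols, dtype=np.int32))
            g.create_dataset(
                "peak_amplitudes", data=np.array(amps, dtype=np.float32)
            )
            g.create_dataset("offsets", data=np.array(offsets, dtype=np.int64))


def load_frames(path, with_truth: bool = False):
    """Read a frame stack; returns (frames, labels-or-None[, truths])."""
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise KeyError(f"{path}: missing required dataset /data")
        frames = f["data"][:]
        labels = None
        if "labels" in f:
            codes = f["labels"][:]
            names = list(f["labels"].attrs["label_names"])
            labels = [names[c] for c in codes]
        if not with_truth:
            return frames, labels
        truths = None
        if "truth" in f:
            g = f["truth"]
            rows = g["peak_rows"][:]
            cols = g["peak_cols"][:]
            amps = g["peak_amplitudes"][:]
            offsets = g["offsets"][:]
            truths = []
            for i in range(len(offsets) - 1):
                lo, hi = offsets[i], offsets[i + 1]
                peaks = tuple(
                    (int(rows[j]), int(cols[j]), float(amps[j]))
                    for j in range(lo, hi)
                )
                label = labels[i] if labels else ("hit" if peaks else "miss")
                truths.append(GroundTruth(peaks=peaks, label=label))
        return frames, labels, truths


def save_background(path, bg: BackgroundEstimate) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset(
            "background", data=bg.median_frame.astype(np.float32)
        )
        d.attrs["n_source_frames"] = bg.n_source_frames


def load_background(path) -> BackgroundEstimate:
    with h5py.File(path, "r") as f:
        if "background" not in f:
            raise KeyError(f"{path}: missing required dataset /background")
        d = f["background"]
        return BackgroundEstimate(
            median_frame=d[:],
            n_source_frames=int(d.attrs.get("n_source_frames", 1)),
        )


def save_peaks(path, keypoint_lists: Sequence[Sequence[KeyPoint]]) -> None:
    """Detected key points per frame, ragged layout mirroring /truth."""
    rows, cols, intens, offsets = [], [], [], [0]
    for kps in keypoint_lists:
        for kp in kps:
            rows.append(kp.row)
            cols.append(kp.col)
            intens.append(kp.intensity)
        offsets.append(len(rows))
    with h5py.File(path, "w") as f:
        g = f.create_group("peaks")
        g.attrs["coordinates"] = "0-based (row, col), row 0 at top"
        g.create_dataset("rows", data=np.array(rows, dtype=np.int32))
        g.create_dataset("cols", data=np.array(cols, dtype=np.int32))
        g.create_dataset(
            "intensities", data=np.array(intens, dtype=np.float32)
        )
        g.create_dataset("offsets", data=np.array(offsets, dtype=np.int64))


def load_peaks(path) -> List[List[KeyPoint]]:
    with h5py.File(path, "r") as f:
        if "peaks" not in f:
            raise KeyError(f"{path}: missing required group /peaks")
        g = f["peaks"]
        rows = g["rows"][:]
        cols = g["cols"][:]
        intens = g["intensities"][:]
        offsets = g["offsets"][:]
    out = []
    for i in range(len(offsets) - 1):
        lo, hi = offsets[i], offsets[i + 1]
        out.append(
            [
                KeyPoint(int(rows[j]), int(cols[j]), float(intens[j]))
                for j in range(lo, hi)
            ]
        )
    return out


def peaks_to_csv(path, keypoint_lists: Sequence[Sequence[KeyPoint]]) -> None:
    """CSV peak table: frame_index,row,col,intensity (0-based coords)."""
    records = [
        (i, kp.row, kp.col, kp.intensity)
        for i, kps in enumerate(keypoint_lists)
        for kp in kps
    ]
    pd.DataFrame(
        records, columns=["frame_index", "row", "col", "intensity"]
    ).to_csv(path, index=False)


def save_features(
    path, features: np.ndarray, labels: Sequence[str] | None = None
) -> None:
    features = np.asarray(features)
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=features.astype(np.int64))
        if labels is not None:
            codes, names = _encode_labels(labels)
            ld = f.create_dataset("labels", data=codes)
            ld.attrs["label_names"] = names


def load_features(path):
    with h5py.File(path, "r") as f:
        if "features" not in f:
            raise KeyError(f"{path}: missing required dataset /features")
        features = f["features"][:]
        labels = None
        if "labels" in f:
            codes = f["labels"][:]
            names = list(f["labels"].attrs["label_names"])
            labels = [names[c] for c in codes]
    return features, labels
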