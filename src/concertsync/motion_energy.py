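"""Motion Energy Analysis (MEA).

Body movement is quantified from top-view video as the number of pixels
whose gray level changes by more than a threshold between consecutive
frames, counted inside a per-participant region of interest (ROI).  At
15 frames/s this yields a 15 Hz movement time series per participant.
ROIs are axis-aligned, half-open pixel rectangles and must not overlap,
so each participant's count reflects only their own movement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .timeseries import Channel, UniformSeries

__all__ = [
    "ROI",
    "FrameStack",
    "frame_difference_count",
    "motion_energy_series",
    "load_rois",
    "load_frame_dir",
    "to_grayscale",
]

DEFAULT_THRESHOLD = 10  # gray levels; suppresses sensor noise


@dataclass(frozen=True)
class ROI:
    """Half-open pixel rectangle [x0, x1) × [y0, y1), 0-based."""

    participant_id: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("ROI must have positive width and height")

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def overlaps(self, other: "ROI") -> bool:
        return not (
            self.x1 <= other.x0 or other.x1 <= self.x0
            or self.y1 <= other.y0 or other.y1 <= self.y0
        )


@dataclass
class FrameStack:
    """Ordered grayscale frames (n, h, w), values in [0, 255]."""

    frames: np.ndarray
    fps: float = 15.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if len(self.frames) < 2:
            raise ValueError("need at least two frames")

    def __len__(self) -> int:
        return len(self.frames)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Rec. 601 luma for RGB input; grayscale passes through."""
    if img.ndim == 2:
        return img.astype(float)
    w = np.array([0.299, 0.587, 0.114])
    return img[..., :3].astype(float) @ w


def _check_roi_bounds(roi: ROI, shape: tuple[int, int]) -> None:
    h, w = shape
    if roi.x0 < 0 or roi.y0 < 0 or roi.x1 > w or roi.y1 > h:
        raise ValueError(f"ROI {roi.participant_id!r} out of image bounds {w}x{h}")


def frame_difference_count(
    a: np.ndarray, b: np.ndarray, roi: ROI, threshold: float = DEFAULT_THRESHOLD
) -> int:
    """Pixels p inside the ROI with |a(p) − b(p)| > threshold."""
    if a.shape != b.shape:
        raise ValueError("frames differ in shape")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    _check_roi_bounds(roi, a.shape)
    pa = a[roi.y0 : roi.y1, roi.x0 : roi.x1].astype(float)
    pb = b[roi.y0 : roi.y1, roi.x0 : roi.x1].astype(float)
    return int(np.count_nonzero(np.abs(pa - pb) > threshold))


def motion_energy_series(
    stack: FrameStack,
    rois: Sequence[ROI],
    threshold: float = DEFAULT_THRESHOLD,
    normalize: bool = False,
) -> list[UniformSeries]:
    """One MOVE series per ROI; sample k compares frames k and k+1."""
    rois = list(rois)
    if not rois:
        raise ValueError("empty ROI set")
    for i, r in enumerate(rois):
        _check_roi_bounds(r, stack.frames.shape[1:])
        for other in rois[i + 1 :]:
            if r.overlaps(other):
                raise ValueError(
                    f"ROIs {r.participant_id!r} and {other.participant_id!r} overlap"
                )
    frames = stack.frames.astype(float)
    diff = np.abs(frames[1:] - frames[:-1]) > threshold  # (n-1, h, w) bool
    out = []
    for r in rois:
        counts = diff[:, r.y0 : r.y1, r.x0 : r.x1].sum(axis=(1, 2)).astype(float)
        if normalize:
            counts = counts / r.area
        out.append(UniformSeries(r.participant_id, Channel.MOVE, stack.fps, counts))
    return out


def load_rois(path: str | Path) -> list[ROI]:
    """ROI config JSON: [{"participant_id", "x0", "y0", "x1", "y1"}, ...]."""
    import json

    items = json.loads(Path(path).read_text())
    return [
        ROI(it["participant_id"], int(it["x0"]), int(it["y0"]), int(it["x1"]), int(it["y1"]))
        for it in items
    ]


def load_frame_dir(path: str | Path, fps: float = 15.0) -> FrameStack:
    """PNG directory in lexicographic order, converted to grayscale."""
    import imageio.v3 as iio

    files = sorted(Path(path).glob("*.png"))
    if len(files) < 2:
        raise ValueError("need at least two PNG frames")
    frames = np.stack([to_grayscale(iio.imread(f)) for f in files])
    return FrameStack(frames=frames, fps=fps)
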