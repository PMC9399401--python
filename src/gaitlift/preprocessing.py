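"""Gap filling, smoothing, and pelvis-centred normalization.

The pipeline repairs detector dropouts by linear interpolation, smooths each
univariate coordinate with a unit-variance (sigma = 1 sample) Gaussian
filter, then moves every pose into a body-local system: the pelvis is
subtracted and all coordinates are divided by the per-frame Euclidean
distance between the right hip and the right shoulder, making the series
translation- and scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TypeVar

import numpy as np

from ._errors import ConfigError, DataError, DegenerateError, \
    UnrecoverableJointError
from .containers import KeypointSeries2D, MarkerSeries3D, Pose3DSeries

DEFAULT_MAX_GAP_FRAMES = 15   # 0.25 s at 60 Hz
DEFAULT_SIGMA_FRAMES = 1.0

SeriesT = TypeVar("SeriesT", KeypointSeries2D, MarkerSeries3D, Pose3DSeries)


@dataclass
class GapReport:
    """Gaps left unfilled because they exceeded the length limit."""

    unfilled: list[tuple[int, int, int]]  # (joint index, start, stop)

    @property
    def count(self) -> int:
        return len(self.unfilled)


def fill_gaps(series: SeriesT, max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES,
              ) -> tuple[SeriesT, GapReport]:
    """Fill missing samples by per-coordinate linear interpolation.

    Interior gaps of at most ``max_gap_frames`` frames are interpolated
    linearly between the flanking observations; leading/trailing gaps copy
    the nearest observed value.  Longer interior gaps are left missing and
    reported.  A joint observed in no frame at all raises
    :class:`UnrecoverableJointError`.
    """
    coords = series.coords.copy()
    missing = series.missing.copy()
    n_frames, n_joints = missing.shape
    unfilled: list[tuple[int, int, int]] = []
    t = np.arange(n_frames)
    names = getattr(series, "joints", getattr(series, "markers", None))

    for j in range(n_joints):
        gap = missing[:, j]
        if not gap.any():
            continue
        if gap.all():
            label = names[j] if names else str(j)
            raise UnrecoverableJointError(
                f"joint {label!r} missing in every frame")
        obs = ~gap
        for start, stop in _runs(gap):
            interior = start > 0 and stop < n_frames
            if interior and stop - start > max_gap_frames:
                unfilled.append((j, start, stop))
                continue
            for k in range(coords.shape[2]):
                coords[start:stop, j, k] = np.interp(
                    t[start:stop], t[obs], coords[obs, j, k])
            missing[start:stop, j] = False

    out = replace(series, coords=coords, missing=missing)
    return out, GapReport(unfilled)


def _runs(mask: np.ndarray):
    """Yield (start, stop) of each True run, stop exclusive."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    yield from zip(starts, stops)


def gaussian_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Discrete Gaussian kernel, truncated at ``truncate`` sigma, sum 1."""
    if sigma <= 0:
        raise ConfigError(f"sigma must be positive, got {sigma}")
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth(series: SeriesT, sigma_frames: float = DEFAULT_SIGMA_FRAMES,
           ) -> SeriesT:
    """Smooth each univariate coordinate with a Gaussian filter.

    The kernel has standard deviation ``sigma_frames`` samples (default 1),
    is truncated at 4 sigma and renormalized; boundaries are handled by
    reflection, which preserves the series mean on constant inputs.
    Requires a gap-free series.
    """
    if series.missing.any():
        raise DataError("smooth requires a gap-free series; run fill_gaps")
    kernel = gaussian_kernel(sigma_frames)
    radius = len(kernel) // 2
    coords = series.coords
    n = coords.shape[0]
    if n == 0:
        return replace(series, coords=coords.copy(),
                       missing=series.missing.copy())
    flat = coords.reshape(n, -1)
    # edge-repeating reflection: preserves the series sum for the symmetric,
    # normalized kernel
    ext = np.pad(flat, ((radius, radius), (0, 0)), mode="symmetric")
    sm = np.empty_like(flat)
    for c in range(flat.shape[1]):
        sm[:, c] = np.convolve(ext[:, c], kernel, mode="valid")
    return replace(series, coords=sm.reshape(coords.shape),
                   missing=series.missing.copy())


@dataclass
class NormalizedPoseSeries:
    """A pose series after pelvis centring and hip-shoulder scaling."""

    pose: Pose3DSeries
    pelvis_trajectory: np.ndarray   # frames x 3, the subtracted pelvis path
    scale: np.ndarray               # frames, right-hip-to-right-shoulder dist

    @property
    def coords(self) -> np.ndarray:
        return self.pose.coords

    @property
    def fps(self) -> float:
        return self.pose.fps

    @property
    def frames(self) -> int:
        return self.pose.frames

    @property
    def missing(self) -> np.ndarray:
        return self.pose.missing

    def joint(self, name: str) -> np.ndarray:
        return self.pose.joint(name)


def normalize_pose(series: Pose3DSeries) -> NormalizedPoseSeries:
    """Centre each frame on the pelvis and scale by hip-shoulder distance.

    The pelvis is the midpoint of the left and right hip joints; the scale
    is the per-frame Euclidean distance from the right hip to the right
    shoulder.  The output is invariant to rigid translation and uniform
    scaling of the input, and the transform is idempotent.
    """
    for name in ("right_hip", "left_hip", "right_shoulder"):
        idx = series.joints.index(name)
        if series.missing[:, idx].any():
            raise DataError(f"normalize_pose: joint {name!r} has gaps")
    pelvis = 0.5 * (series.joint("right_hip") + series.joint("left_hip"))
    scale = np.linalg.norm(
        series.joint("right_shoulder") - series.joint("right_hip"), axis=1)
    if np.any(scale <= 0) or not np.all(np.isfinite(scale)):
        raise DegenerateError(
            "normalize_pose: zero right-hip-to-right-shoulder distance")
    coords = (series.coords - pelvis[:, None, :]) / scale[:, None, None]
    coords[series.missing] = np.nan
    pose = replace(series, coords=coords, missing=series.missing.copy())
    return NormalizedPoseSeries(pose=pose, pelvis_trajectory=pelvis,
                                scale=scale)
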