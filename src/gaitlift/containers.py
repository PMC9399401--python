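"""Time-series containers shared across the pipeline.

Conventions: frame indices are 0-based; arrays are ``frames x joints x dim``
float64; a boolean ``missing`` mask marks samples with no observation.  A
missing sample's coordinates are NaN; everywhere else coordinates are finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._errors import DataError
from .skeleton import CANONICAL_JOINTS, MIDPOINT_SYNTHESIS, SkeletonMap


def _check_series(coords: np.ndarray, missing: np.ndarray, fps: float,
                  dim: int, what: str) -> None:
    if fps <= 0:
        raise DataError(f"{what}: fps must be positive, got {fps}")
    if coords.ndim != 3 or coords.shape[2] != dim:
        raise DataError(f"{what}: coords must be frames x joints x {dim}, "
                        f"got shape {coords.shape}")
    if missing.shape != coords.shape[:2]:
        raise DataError(f"{what}: missing mask shape {missing.shape} does not "
                        f"match coords {coords.shape[:2]}")
    observed = ~missing
    if not np.all(np.isfinite(coords[observed])):
        raise DataError(f"{what}: non-finite coordinates outside the missing "
                        "mask")


@dataclass
class KeypointSeries2D:
    """Per-frame 2D keypoints with confidences and gaps (pixel units)."""

    fps: float
    joints: tuple[str, ...]
    coords: np.ndarray          # frames x joints x 2
    confidence: np.ndarray      # frames x joints, in [0, 1]
    missing: np.ndarray         # frames x joints, bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        _check_series(self.coords, self.missing, self.fps, 2, "KeypointSeries2D")
        if self.confidence.shape != self.missing.shape:
            raise DataError("KeypointSeries2D: confidence shape mismatch")
        obs_conf = self.confidence[~self.missing]
        if obs_conf.size and (obs_conf.min() < 0 or obs_conf.max() > 1):
            raise DataError("KeypointSeries2D: confidence outside [0, 1]")
        if len(self.joints) != self.coords.shape[1]:
            raise DataError("KeypointSeries2D: joint list length mismatch")

    @property
    def frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class MarkerSeries3D:
    """Per-frame 3D marker trajectories in mm, with gaps."""

    fps: float
    markers: tuple[str, ...]
    coords: np.ndarray          # frames x markers x 3
    missing: np.ndarray         # frames x markers, bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        _check_series(self.coords, self.missing, self.fps, 3, "MarkerSeries3D")
        if len(self.markers) != self.coords.shape[1]:
            raise DataError("MarkerSeries3D: marker list length mismatch")

    @property
    def frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class Pose3DSeries:
    """Per-frame 3D positions on the canonical 17-joint skeleton."""

    fps: float
    coords: np.ndarray          # frames x 17 x 3
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]
    root_relative: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.coords.shape[:2], dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        _check_series(self.coords, self.missing, self.fps, 3, "Pose3DSeries")
        if self.coords.shape[1] != len(CANONICAL_JOINTS):
            raise DataError(
                f"Pose3DSeries: expected {len(CANONICAL_JOINTS)} canonical "
                f"joints, got {self.coords.shape[1]}")

    @property
    def frames(self) -> int:
        return self.coords.shape[0]

    @property
    def joints(self) -> tuple[str, ...]:
        return CANONICAL_JOINTS

    def joint(self, name: str) -> np.ndarray:
        """Trajectory of one canonical joint, frames x 3."""
        return self.coords[:, CANONICAL_JOINTS.index(name), :]

    def copy(self) -> "Pose3DSeries":
        return replace(self, coords=self.coords.copy(),
                       missing=self.missing.copy())


def to_canonical_3d(series: MarkerSeries3D, skel_map: SkeletonMap
                    ) -> Pose3DSeries:
    """Place mapped markers on the canonical skeleton.

    Unmapped canonical joints are synthesized as midpoints where the
    registered synthesis rule applies (pelvis from the hips, spine from
    pelvis/thorax, ...); otherwise they stay missing.
    """
    n_frames = series.frames
    n_canon = len(CANONICAL_JOINTS)
    coords = np.full((n_frames, n_canon, 3), np.nan)
    missing = np.ones((n_frames, n_canon), dtype=bool)
    for src, dst in skel_map.index_map.items():
        coords[:, dst, :] = series.coords[:, src, :]
        missing[:, dst] = series.missing[:, src]
    _synthesize_midpoints(coords, missing)
    return Pose3DSeries(fps=series.fps, coords=coords, missing=missing)


def canonical_2d(series: KeypointSeries2D, skel_map: SkeletonMap
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Map a 2D keypoint series onto the canonical joint order.

    Returns (coords frames x 17 x 2, missing frames x 17); synthesizes
    midpoint joints like :func:`to_canonical_3d`.
    """
    n_frames = series.frames
    n_canon = len(CANONICAL_JOINTS)
    coords = np.full((n_frames, n_canon, 2), np.nan)
    missing = np.ones((n_frames, n_canon), dtype=bool)
    for src, dst in skel_map.index_map.items():
        coords[:, dst, :] = series.coords[:, src, :]
        missing[:, dst] = series.missing[:, src]
    _synthesize_midpoints(coords, missing)
    return coords, missing


def _synthesize_midpoints(coords: np.ndarray, missing: np.ndarray) -> None:
    index = {j: i for i, j in enumerate(CANONICAL_JOINTS)}
    for joint, (a, b) in MIDPOINT_SYNTHESIS.items():
        j, ia, ib = index[joint], index[a], index[b]
        need = missing[:, j] & ~missing[:, ia] & ~missing[:, ib]
        coords[need, j, :] = 0.5 * (coords[need, ia, :] + coords[need, ib, :])
        missing[need, j] = False
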