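"""Human-centred frame, joint angles, heel strikes, and cycle resampling.

Coordinate frame
----------------
Per frame t the body-local system {O} has origin o(t), the midpoint of the
right and left pelvis landmarks PR, PL.  Two unit vectors define it:
V1 = unit(PR - PL) (hip-to-hip) and V2 = unit(o(t) - o(t-1)) (progression).
The axes are xh = V1, yh = unit(V1 x V2), zh = unit(xh x yh), an orthonormal
right-handed triad.

Note the axis *names* follow the original convention of this analysis family
(angles are reported as R?X, R?Y, R?Z for the xh, yh, zh normals) even
though xh is the hip-to-hip (lateral) axis rather than the anterior one; the
labels are kept for comparability and the geometry is implemented literally.

Angles
------
Three link segments are formed: upper trunk U = u - o (u = shoulder
midpoint), right thigh T = alpha - delta and right shank S = alpha - beta,
with delta/alpha/beta the right hip/knee/ankle.  The knee angle is
RTS = arccos(T.S / (|T| |S|)); the other nine angles are the arccos of each
unit segment against each axis of {O}.  All angles live in [0, pi] and are
invariant to global rigid motion and uniform scaling.

Cycles
------
Right heel strikes are the positive peaks of the anterior-posterior right
ankle trajectory; a gait cycle is the half-open interval between consecutive
strikes.  Within each cycle every angle is resampled at K evenly spaced
phase points over [0%, 100%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from ._errors import DataError, DegenerateError, NoCycleError
from .containers import Pose3DSeries
from .preprocessing import NormalizedPoseSeries

__all__ = [
    "ANGLE_NAMES", "HumanFrame", "SegmentVectors", "GaitCycleIndex",
    "AngleCurves", "human_frame", "knee_angle", "plane_angles",
    "segment_vectors", "compute_angle_curves", "detect_heel_strikes",
    "resample_cycle", "resample_curves", "estimate_progression_axis",
]

#: The ten reported angles: knee angle plus segment-vs-plane-normal angles.
ANGLE_NAMES: tuple[str, ...] = (
    "RTS",
    "RUX", "RTX", "RSX",
    "RUY", "RTY", "RSY",
    "RUZ", "RTZ", "RSZ",
)

_SEGMENTS = ("U", "T", "S")
_AXES = ("X", "Y", "Z")

_EPS = 1e-12


@dataclass
class HumanFrame:
    """Per-frame origin and orthonormal axes of the body-local system."""

    origin: np.ndarray   # F x 3
    xh: np.ndarray       # F x 3 unit
    yh: np.ndarray
    zh: np.ndarray
    v1: np.ndarray
    v2: np.ndarray

    @property
    def frames(self) -> int:
        return self.origin.shape[0]

    def axis(self, name: str) -> np.ndarray:
        return {"X": self.xh, "Y": self.yh, "Z": self.zh}[name]


@dataclass
class SegmentVectors:
    """Per-frame upper-trunk, thigh, and shank link vectors."""

    U: np.ndarray   # shoulder midpoint - origin
    T: np.ndarray   # knee - hip
    S: np.ndarray   # knee - ankle

    def vector(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class GaitCycleIndex:
    """Heel-strike frames and the half-open cycles they delimit."""

    strikes: np.ndarray              # strictly increasing frame indices
    fps: float

    def __post_init__(self) -> None:
        self.strikes = np.asarray(self.strikes, dtype=int)
        if len(self.strikes) < 2:
            raise NoCycleError("need >= 2 heel strikes to form a cycle")
        if np.any(np.diff(self.strikes) <= 0):
            raise DataError("heel strikes must be strictly increasing")

    @property
    def cycles(self) -> list[tuple[int, int]]:
        return list(zip(self.strikes[:-1], self.strikes[1:]))

    @property
    def n_cycles(self) -> int:
        return len(self.strikes) - 1


@dataclass
class AngleCurves:
    """The ten per-frame angle series, optionally with per-cycle matrices."""

    fps: float
    angles: dict[str, np.ndarray]             # name -> (F,) radians
    phi: dict[str, np.ndarray] | None = None  # name -> (n_cycles x K)
    cycle_index: GaitCycleIndex | None = None
    K: int | None = None

    @property
    def frames(self) -> int:
        return len(next(iter(self.angles.values())))


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norm <= _EPS):
        raise DegenerateError(f"{what}: zero-length vector")
    return v / norm


def _vector_angle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle between unit vectors in [0, pi].

    Uses atan2(|a x b|, a.b), which equals arccos(a.b) but stays accurate
    for nearly parallel or antiparallel vectors where arccos loses half the
    significant digits; the dot product is still clamped to absorb rounding.
    """
    dot = np.clip(np.sum(a * b, axis=-1), -1.0, 1.0)
    cross = np.linalg.norm(np.cross(a, b), axis=-1)
    return np.arctan2(cross, dot)


def human_frame(PR: np.ndarray, PL: np.ndarray,
                v2_override: np.ndarray | None = None) -> HumanFrame:
    """Build the body-local frame from the pelvis landmark trajectories.

    ``PR``/``PL`` are F x 3 right/left pelvis landmark positions (F >= 2).
    V2 comes from the frame-to-frame displacement of the origin; the first
    frame copies the second frame's V2.  For root-relative data whose origin
    never moves, pass ``v2_override`` (a single 3-vector or F x 3 array,
    e.g. from :func:`estimate_progression_axis`).

    Raises :class:`DegenerateError` for coincident hips, a stationary origin
    (without override), or V1 parallel to V2.
    """
    PR = np.asarray(PR, dtype=float)
    PL = np.asarray(PL, dtype=float)
    if PR.ndim != 2 or PR.shape != PL.shape or PR.shape[1] != 3:
        raise DataError("human_frame: PR and PL must be matching F x 3 arrays")
    if PR.shape[0] < 2 and v2_override is None:
        raise DataError("human_frame: need >= 2 frames to form V2")
    origin = 0.5 * (PR + PL)
    v1 = _unit(PR - PL, "V1 (coincident hips)")
    if v2_override is not None:
        v2 = np.broadcast_to(np.asarray(v2_override, dtype=float),
                             origin.shape).copy()
        v2 = _unit(v2, "V2 override")
    else:
        disp = np.diff(origin, axis=0)
        v2 = np.empty_like(origin)
        v2[1:] = _unit(disp, "V2 (stationary origin)")
        v2[0] = v2[1]
    xh = v1
    yh = _unit(np.cross(v1, v2), "V1 x V2 (V1 parallel to V2)")
    zh = _unit(np.cross(xh, yh), "xh x yh")
    return HumanFrame(origin=origin, xh=xh, yh=yh, zh=zh, v1=v1, v2=v2)


def knee_angle(T_vec: np.ndarray, S_vec: np.ndarray) -> np.ndarray:
    """Angle between thigh and shank vectors, radians in [0, pi].

    Accepts single 3-vectors or F x 3 arrays.  The normalized dot product is
    clamped to [-1, 1] before arccos to absorb rounding.
    """
    T_vec = np.asarray(T_vec, dtype=float)
    S_vec = np.asarray(S_vec, dtype=float)
    tu = _unit(T_vec, "thigh segment")
    su = _unit(S_vec, "shank segment")
    return _vector_angle(tu, su)


def segment_vectors(pose: Pose3DSeries | NormalizedPoseSeries
                    ) -> SegmentVectors:
    """Extract U, T, S link vectors from a canonical pose series."""
    o = 0.5 * (pose.joint("right_hip") + pose.joint("left_hip"))
    u = 0.5 * (pose.joint("right_shoulder") + pose.joint("left_shoulder"))
    return SegmentVectors(
        U=u - o,
        T=pose.joint("right_knee") - pose.joint("right_hip"),
        S=pose.joint("right_knee") - pose.joint("right_ankle"),
    )


def plane_angles(segments: SegmentVectors, frame: HumanFrame
                 ) -> dict[str, np.ndarray]:
    """The nine segment-vs-axis angles R{U,T,S}{X,Y,Z}, radians."""
    out: dict[str, np.ndarray] = {}
    for seg in _SEGMENTS:
        v = _unit(segments.vector(seg), f"segment {seg}")
        for ax in _AXES:
            out[f"R{seg}{ax}"] = _vector_angle(v, frame.axis(ax))
    return out


def compute_angle_curves(pose: Pose3DSeries | NormalizedPoseSeries,
                         frame: HumanFrame) -> AngleCurves:
    """All ten per-frame angle series for a pose series and its frame."""
    segs = segment_vectors(pose)
    angles = {"RTS": knee_angle(segs.T, segs.S)}
    angles.update(plane_angles(segs, frame))
    return AngleCurves(fps=pose.fps, angles=angles)


def detect_heel_strikes(ankle_anterior: np.ndarray, fps: float,
                        min_separation: int | None = None,
                        prominence: float | None = None) -> GaitCycleIndex:
    """Detect right heel strikes as peaks of the anterior ankle series.

    Heel strikes are the positive local maxima of the anterior-posterior
    ankle trajectory.  Defaults: ``min_separation`` = 0.5 s worth of frames,
    ``prominence`` = 20% of the series range.  Fewer than two detected
    strikes raises :class:`NoCycleError`.
    """
    x = np.asarray(ankle_anterior, dtype=float)
    if x.ndim != 1:
        raise DataError("detect_heel_strikes: series must be 1-D")
    if not np.all(np.isfinite(x)):
        raise DataError("detect_heel_strikes: series has gaps/NaNs")
    if min_separation is None:
        min_separation = max(1, int(round(0.5 * fps)))
    rng = float(x.max() - x.min())
    if prominence is None:
        prominence = 0.2 * rng
    if rng <= 0:
        raise NoCycleError("constant series: no peaks")
    peaks, _ = find_peaks(x, distance=min_separation, prominence=prominence)
    if len(peaks) < 2:
        raise NoCycleError(f"only {len(peaks)} heel strikes detected")
    return GaitCycleIndex(strikes=peaks, fps=fps)


def resample_cycle(series: np.ndarray, cycle: tuple[int, int], K: int
                   ) -> np.ndarray:
    """Resample one cycle at K evenly spaced phases over [0%, 100%).

    Phase k maps to frame start + (end - start) * k / K; values come from
    linear interpolation of the per-frame series.
    """
    start, end = cycle
    series = np.asarray(series, dtype=float)
    if K < 2:
        raise DataError("resample_cycle: K must be >= 2")
    if not 0 <= start < end <= len(series) - 1:
        raise DataError(f"resample_cycle: cycle {cycle} outside series")
    phases = start + (end - start) * np.arange(K) / K
    return np.interp(phases, np.arange(len(series)), series)


def resample_curves(curves: AngleCurves, index: GaitCycleIndex, K: int = 50
                    ) -> AngleCurves:
    """Attach per-cycle K-point matrices (n_cycles x K) to angle curves."""
    phi = {
        name: np.vstack([resample_cycle(series, cyc, K)
                         for cyc in index.cycles])
        for name, series in curves.angles.items()
    }
    return AngleCurves(fps=curves.fps, angles=curves.angles, phi=phi,
                       cycle_index=index, K=K)


def estimate_progression_axis(ankle_rel: np.ndarray,
                              knee_angle_series: np.ndarray | None = None
                              ) -> np.ndarray:
    """Estimate the walking direction from a root-relative ankle trajectory.

    For data whose pelvis never moves (root-relative lifted poses, treadmill
    walking) the origin displacement cannot define V2.  The swing of the
    ankle relative to the pelvis is dominated by the progression axis, so
    the first principal component of the detrended ankle trajectory is
    used.  The sign is oriented with the knee angle when available: at the
    anterior extreme (heel strike) the leg is extended (angle near pi)
    while at the posterior extreme the knee is flexed, a large and robust
    asymmetry.  Without a knee-angle series the larger excursion is taken
    as anterior.
    """
    x = np.asarray(ankle_rel, dtype=float)
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    axis = vt[0]
    proj = x @ axis
    if knee_angle_series is not None:
        rts = np.asarray(knee_angle_series, dtype=float)
        if rts[int(np.argmax(proj))] < rts[int(np.argmin(proj))]:
            axis = -axis
    elif abs(proj.min()) > abs(proj.max()):
        axis = -axis
    return axis
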