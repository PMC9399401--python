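"""Synthetic walking data with analytic ground truth.

The generator poses a kinematic chain (pelvis -> hips -> knees -> ankles,
pelvis -> trunk -> shoulders/arms/head) with sinusoidal hip and knee
flexion at a constant cadence, then renders it two ways:

* a 3D marker series in a world frame (mm), standing in for an optical
  capture export, and
* a 2D keypoint series through a pinhole camera with additive Gaussian
  pixel noise and randomly placed gaps, standing in for a single-camera
  detector output.

The joint-angle model is the simplest family with realistic periodicity:
right-leg phase p(t) = 2*pi*(t - t0)/P with stride period P = 120/cadence
seconds; hip flexion phi = A_hip*cos(p); knee flexion
theta = A_knee*(1 - cos(p))/2; the left leg runs half a stride out of
phase.  This puts the anterior peak of the ankle trajectory (the heel
strike) exactly at p = 0 modulo 2*pi, so strike times and the knee angle
curve RTS = pi - theta are known in closed form and every downstream stage
can be checked against them.

Treadmill walking is emulated by a slow constant pelvis drift (plus an
optional forward oscillation) so the progression direction stays
well-defined without the subject leaving the camera view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._errors import ConfigError, DataError
from .containers import KeypointSeries2D, MarkerSeries3D, Pose3DSeries
from .pose_lifting import PoseBatch, normalize_2d_frames
from .skeleton import BODY25_JOINTS, CANONICAL_JOINTS

__all__ = ["GaitSimConfig", "CameraModel", "GroundTruthBundle", "generate",
           "project", "make_training_set"]

_DEG = math.pi / 180.0

_J = {name: i for i, name in enumerate(CANONICAL_JOINTS)}


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: intrinsics in pixels, pose as position + target."""

    focal_px: float = 1000.0
    principal: tuple[float, float] = (960.0, 540.0)   # 1920 x 1080 sensor
    position: tuple[float, float, float] = (3000.0, 100.0, 900.0)
    target: tuple[float, float, float] = (0.0, 100.0, 900.0)
    up: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def rotation(self) -> np.ndarray:
        """World-to-camera rotation; rows are right, down, forward axes."""
        pos = np.asarray(self.position, float)
        fwd = np.asarray(self.target, float) - pos
        fwd = fwd / np.linalg.norm(fwd)
        right = np.cross(fwd, np.asarray(self.up, float))
        nr = np.linalg.norm(right)
        if nr < 1e-9:
            raise ConfigError("camera forward parallel to up vector")
        right /= nr
        down = np.cross(fwd, right)
        return np.vstack([right, down, fwd])

    def project_points(self, pts: np.ndarray) -> np.ndarray:
        """Project ... x 3 world points to ... x 2 pixels (all depths > 0)."""
        rel = pts - np.asarray(self.position, float)
        cam = rel @ self.rotation().T
        depth = cam[..., 2]
        if np.any(depth <= 0):
            raise DataError("point behind camera")
        cx, cy = self.principal
        u = self.focal_px * cam[..., 0] / depth + cx
        v = self.focal_px * cam[..., 1] / depth + cy
        return np.stack([u, v], axis=-1)


@dataclass(frozen=True)
class GaitSimConfig:
    """Study conditions for one synthetic walking bout."""

    duration_s: float = 10.0
    fps: float = 60.0
    cadence_spm: float = 100.0        # steps/min, both feet
    trunk_mm: float = 500.0
    thigh_mm: float = 420.0
    shank_mm: float = 400.0
    pelvis_width_mm: float = 240.0
    shoulder_width_mm: float = 380.0
    upper_arm_mm: float = 280.0
    forearm_mm: float = 250.0
    head_mm: float = 220.0
    hip_amp_deg: float = 20.0         # hip flexion amplitude
    knee_amp_deg: float = 60.0        # peak knee flexion (0 at strike)
    ankle_amp_deg: float = 15.0       # reserve range for random poses
    trunk_pitch_deg: float = 3.0      # anterior-posterior trunk sway
    pelvis_speed_mm_s: float = 20.0   # slow treadmill drift
    pelvis_osc_mm: float = 0.0        # optional forward oscillation
    strike_phase: float = 0.25        # first strike at strike_phase * P
    noise_px: float = 0.0             # keypoint noise sigma
    gap_rate: float = 0.0             # per-sample gap probability
    camera: CameraModel = field(default_factory=CameraModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration_s", "fps", "cadence_spm", "trunk_mm",
                     "thigh_mm", "shank_mm", "pelvis_width_mm",
                     "shoulder_width_mm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.fps < 2.0 * self.cadence_spm / 60.0:
            raise ConfigError("fps must be at least twice the step frequency")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ConfigError("gap_rate must be in [0, 1)")

    @property
    def stride_period_s(self) -> float:
        """Seconds per full (same-side) gait cycle: two steps."""
        return 120.0 / self.cadence_spm

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class GroundTruthBundle:
    """One simulated bout with everything later stages can be checked on."""

    config: GaitSimConfig
    pose3d: Pose3DSeries                 # world mm, canonical joints
    markers: MarkerSeries3D              # same data, marker-table container
    keypoints: KeypointSeries2D          # projected + noise + gaps, Body25
    analytic_knee_angle: np.ndarray      # RTS per frame, radians
    analytic_strike_times: np.ndarray    # seconds
    analytic_strike_frames: np.ndarray   # nearest frame indices


def _leg_joints(config: GaitSimConfig, phi: np.ndarray, theta: np.ndarray,
                hip: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Knee and ankle world positions for hip flexion phi, knee flexion theta.

    Flexion rotates about the lateral (+x) axis; phi > 0 swings the limb
    anterior, theta bends the shank back relative to the thigh.
    """
    thigh_dir = np.stack([np.zeros_like(phi), np.sin(phi), -np.cos(phi)],
                         axis=-1)
    shank_ang = phi - theta
    shank_dir = np.stack([np.zeros_like(phi), np.sin(shank_ang),
                          -np.cos(shank_ang)], axis=-1)
    knee = hip + config.thigh_mm * thigh_dir
    ankle = knee + config.shank_mm * shank_dir
    return knee, ankle


def _skeleton_frames(config: GaitSimConfig, pelvis: np.ndarray,
                     phi_r: np.ndarray, theta_r: np.ndarray,
                     phi_l: np.ndarray, theta_l: np.ndarray,
                     psi: np.ndarray | None = None) -> np.ndarray:
    """World positions, F x 17 x 3, for given pelvis path and leg angles.

    ``psi`` is the anterior-posterior trunk pitch per frame (radians).
    """
    F = pelvis.shape[0]
    if psi is None:
        psi = np.zeros(F)
    pts = np.zeros((F, len(CANONICAL_JOINTS), 3))
    half_pw = np.array([config.pelvis_width_mm / 2.0, 0.0, 0.0])
    half_sw = np.array([config.shoulder_width_mm / 2.0, 0.0, 0.0])
    trunk_dir = np.stack([np.zeros_like(psi), np.sin(psi), np.cos(psi)],
                         axis=-1)
    up_trunk = config.trunk_mm * trunk_dir
    pts[:, _J["pelvis"]] = pelvis
    pts[:, _J["right_hip"]] = pelvis + half_pw
    pts[:, _J["left_hip"]] = pelvis - half_pw
    thorax = pelvis + up_trunk
    pts[:, _J["thorax"]] = thorax
    pts[:, _J["spine"]] = 0.5 * (pelvis + thorax)
    head = thorax + config.head_mm * trunk_dir
    pts[:, _J["head"]] = head
    pts[:, _J["neck"]] = 0.5 * (thorax + head)
    pts[:, _J["right_shoulder"]] = thorax + half_sw
    pts[:, _J["left_shoulder"]] = thorax - half_sw
    drop_upper = np.array([0.0, 0.0, -config.upper_arm_mm])
    drop_fore = np.array([0.0, 0.0, -config.forearm_mm])
    for side in ("right", "left"):
        sho = pts[:, _J[f"{side}_shoulder"]]
        pts[:, _J[f"{side}_elbow"]] = sho + drop_upper
        pts[:, _J[f"{side}_wrist"]] = sho + drop_upper + drop_fore
    knee_r, ankle_r = _leg_joints(config, phi_r, theta_r,
                                  pts[:, _J["right_hip"]])
    knee_l, ankle_l = _leg_joints(config, phi_l, theta_l,
                                  pts[:, _J["left_hip"]])
    pts[:, _J["right_knee"]] = knee_r
    pts[:, _J["right_ankle"]] = ankle_r
    pts[:, _J["left_knee"]] = knee_l
    pts[:, _J["left_ankle"]] = ankle_l
    return pts


def generate(config: GaitSimConfig) -> GroundTruthBundle:
    """Simulate one walking bout; deterministic given ``config.seed``."""
    F = config.n_frames
    t = np.arange(F) / config.fps
    P = config.stride_period_s
    p = 2.0 * math.pi * (t - config.strike_phase * P) / P
    a_hip = config.hip_amp_deg * _DEG
    a_knee = config.knee_amp_deg * _DEG
    phi_r = a_hip * np.cos(p)
    theta_r = a_knee * (1.0 - np.cos(p)) / 2.0
    phi_l = a_hip * np.cos(p + math.pi)
    theta_l = a_knee * (1.0 - np.cos(p + math.pi)) / 2.0
    # trunk pitches twice per stride (once per step)
    psi = config.trunk_pitch_deg * _DEG * np.sin(2.0 * p)

    hip_height = config.thigh_mm + config.shank_mm
    pelvis = np.zeros((F, 3))
    pelvis[:, 1] = (config.pelvis_speed_mm_s * t
                    + config.pelvis_osc_mm * np.sin(p))
    pelvis[:, 2] = hip_height

    coords = _skeleton_frames(config, pelvis, phi_r, theta_r, phi_l, theta_l,
                              psi)
    pose = Pose3DSeries(fps=config.fps, coords=coords)
    markers = MarkerSeries3D(
        fps=config.fps, markers=CANONICAL_JOINTS, coords=coords.copy(),
        missing=np.zeros((F, len(CANONICAL_JOINTS)), dtype=bool))

    analytic_rts = math.pi - theta_r
    # strikes where the right-leg phase crosses 0 mod 2*pi
    k_max = int(math.floor((t[-1] / P) - config.strike_phase))
    ks = np.arange(0, k_max + 1)
    strike_times = (config.strike_phase + ks) * P
    strike_frames = np.round(strike_times * config.fps).astype(int)

    rng = np.random.default_rng(config.seed)
    keypoints = project(pose, config.camera, noise_px=config.noise_px,
                        gap_rate=config.gap_rate, rng=rng)
    return GroundTruthBundle(
        config=config, pose3d=pose, markers=markers, keypoints=keypoints,
        analytic_knee_angle=analytic_rts,
        analytic_strike_times=strike_times,
        analytic_strike_frames=strike_frames)


# canonical joint backing each Body25 keypoint (extremity/face keypoints
# borrow the nearest canonical joint; the pipeline never consumes them)
_BODY25_SOURCE = {
    "Nose": "head", "Neck": "thorax",
    "RShoulder": "right_shoulder", "RElbow": "right_elbow",
    "RWrist": "right_wrist", "LShoulder": "left_shoulder",
    "LElbow": "left_elbow", "LWrist": "left_wrist",
    "MidHip": "pelvis", "RHip": "right_hip", "RKnee": "right_knee",
    "RAnkle": "right_ankle", "LHip": "left_hip", "LKnee": "left_knee",
    "LAnkle": "left_ankle", "REye": "head", "LEye": "head",
    "REar": "head", "LEar": "head", "LBigToe": "left_ankle",
    "LSmallToe": "left_ankle", "LHeel": "left_ankle",
    "RBigToe": "right_ankle", "RSmallToe": "right_ankle",
    "RHeel": "right_ankle",
}


def project(pose3d: Pose3DSeries, camera: CameraModel, *,
            noise_px: float = 0.0, gap_rate: float = 0.0,
            rng: np.random.Generator | None = None) -> KeypointSeries2D:
    """Render a 3D pose series as a Body25 keypoint series.

    Pinhole projection, then i.i.d. Gaussian pixel noise of standard
    deviation ``noise_px`` and Bernoulli gaps at ``gap_rate``.  Confidence
    is 1 minus a jitter proportional to the realized noise magnitude, so
    noisier samples score lower but stay above the default gate.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    clean = camera.project_points(pose3d.coords)   # F x 17 x 2
    F = clean.shape[0]
    n25 = len(BODY25_JOINTS)
    coords = np.empty((F, n25, 2))
    for b, name in enumerate(BODY25_JOINTS):
        coords[:, b, :] = clean[:, _J[_BODY25_SOURCE[name]], :]
    if noise_px > 0:
        eps = rng.normal(0.0, noise_px, size=coords.shape)
        coords = coords + eps
        jitter = np.linalg.norm(eps, axis=2) / (3.0 * noise_px)
        confidence = np.clip(1.0 - 0.5 * np.minimum(jitter, 1.0), 0.5, 1.0)
    else:
        confidence = np.ones((F, n25))
    missing = np.zeros((F, n25), dtype=bool)
    if gap_rate > 0:
        missing = rng.random((F, n25)) < gap_rate
        # keep at least one observation per joint so gaps stay recoverable
        for j in range(n25):
            if missing[:, j].all():
                missing[rng.integers(F), j] = False
    coords = coords.copy()
    coords[missing] = np.nan
    confidence = confidence.copy()
    confidence[missing] = 0.0
    return KeypointSeries2D(fps=pose3d.fps, joints=BODY25_JOINTS,
                            coords=coords, confidence=confidence,
                            missing=missing)


def make_training_set(config: GaitSimConfig, n_poses: int,
                      seed: int | None = None,
                      noise_px: float | None = None) -> PoseBatch:
    """Random static poses paired as (normalized 2D, normalized 3D) samples.

    Poses are drawn uniformly from the generator's joint-angle ranges (each
    leg independently), placed at a random point of the walkway, and
    projected through the configured camera.  Gaussian pixel noise of
    standard deviation ``noise_px`` (default: the config's keypoint noise)
    is added to the 2D inputs so the network trains under the same
    observation noise it will see; targets stay noise-free.  Targets are
    root-relative 3D coordinates divided by the right-hip-to-right-shoulder
    distance, matching the network's input normalization.
    """
    if n_poses < 1:
        raise ConfigError("n_poses must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    a_hip = config.hip_amp_deg * _DEG
    a_knee = config.knee_amp_deg * _DEG
    phi_r = rng.uniform(-a_hip, a_hip, n_poses)
    phi_l = rng.uniform(-a_hip, a_hip, n_poses)
    theta_r = rng.uniform(0.0, a_knee, n_poses)
    theta_l = rng.uniform(0.0, a_knee, n_poses)
    a_pitch = config.trunk_pitch_deg * _DEG
    psi = rng.uniform(-a_pitch, a_pitch, n_poses)
    travel = max(1.0, config.pelvis_speed_mm_s * config.duration_s
                 + abs(config.pelvis_osc_mm))
    pelvis = np.zeros((n_poses, 3))
    pelvis[:, 1] = rng.uniform(0.0, travel, n_poses)
    pelvis[:, 2] = config.thigh_mm + config.shank_mm

    coords = _skeleton_frames(config, pelvis, phi_r, theta_r, phi_l, theta_l,
                              psi)
    px = config.camera.project_points(coords)
    if noise_px is None:
        noise_px = config.noise_px
    if noise_px > 0:
        px = px + rng.normal(0.0, noise_px, size=px.shape)
    inputs = normalize_2d_frames(px)

    root_rel = coords - coords[:, :1, :]
    scale = np.linalg.norm(coords[:, _J["right_shoulder"]]
                           - coords[:, _J["right_hip"]], axis=1)
    targets = (root_rel / scale[:, None, None]).reshape(n_poses, -1)
    return PoseBatch(inputs=inputs, targets=targets)
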