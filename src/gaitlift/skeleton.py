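"""Canonical skeleton and schema maps.

All geometry runs on a canonical 17-joint skeleton (the Human3.6M joint set,
root first).  Source schemas — the OpenPose Body25 keypoint model and a
Plug-In-Gait-style marker set — are mapped onto it with a
:class:`SkeletonMap`.  Two canonical joints (``spine`` and ``neck``) have no
Body25 source and are synthesized as segment midpoints during conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._errors import SchemaError

#: Canonical joint order (root first, Human3.6M convention).
CANONICAL_JOINTS: tuple[str, ...] = (
    "pelvis",
    "right_hip",
    "right_knee",
    "right_ankle",
    "left_hip",
    "left_knee",
    "left_ankle",
    "spine",
    "thorax",
    "neck",
    "head",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
)

N_CANONICAL = len(CANONICAL_JOINTS)

#: Joints the angle pipeline cannot do without.
REQUIRED_FOR_GEOMETRY: tuple[str, ...] = (
    "right_hip",
    "left_hip",
    "right_shoulder",
    "left_shoulder",
    "right_knee",
    "right_ankle",
)

#: OpenPose Body25 joint names, index order of the JSON triples.
BODY25_JOINTS: tuple[str, ...] = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)

_BODY25_TO_CANONICAL = {
    "MidHip": "pelvis",
    "RHip": "right_hip",
    "RKnee": "right_knee",
    "RAnkle": "right_ankle",
    "LHip": "left_hip",
    "LKnee": "left_knee",
    "LAnkle": "left_ankle",
    "Neck": "thorax",
    "Nose": "head",
    "LShoulder": "left_shoulder",
    "LElbow": "left_elbow",
    "LWrist": "left_wrist",
    "RShoulder": "right_shoulder",
    "RElbow": "right_elbow",
    "RWrist": "right_wrist",
}

# Plug-In-Gait-style marker labels for the joints the pipeline uses.  RASI and
# LASI play the roles of the right/left pelvis landmarks in the human frame.
_PIG_TO_CANONICAL = {
    "RASI": "right_hip",
    "LASI": "left_hip",
    "RKNE": "right_knee",
    "RANK": "right_ankle",
    "LKNE": "left_knee",
    "LANK": "left_ankle",
    "RSHO": "right_shoulder",
    "LSHO": "left_shoulder",
    "RELB": "right_elbow",
    "RWRA": "right_wrist",
    "LELB": "left_elbow",
    "LWRA": "left_wrist",
    "C7": "thorax",
    "RFHD": "head",
}

#: Canonical joints synthesized as midpoints when their schema has no source.
MIDPOINT_SYNTHESIS: dict[str, tuple[str, str]] = {
    "pelvis": ("right_hip", "left_hip"),
    "spine": ("pelvis", "thorax"),
    "neck": ("thorax", "head"),
    "thorax": ("right_shoulder", "left_shoulder"),
    "head": ("right_shoulder", "left_shoulder"),
}


@dataclass(frozen=True)
class SkeletonMap:
    """Mapping from a source joint/marker schema to the canonical skeleton.

    ``index_map`` maps source index -> canonical index and must be injective
    on the canonical joints the geometry needs.
    """

    source_schema: str
    source_joints: tuple[str, ...]
    index_map: dict[int, int] = field(repr=False)

    def __post_init__(self) -> None:
        targets = list(self.index_map.values())
        if len(targets) != len(set(targets)):
            raise SchemaError(
                f"{self.source_schema}: index map is not injective")
        covered = {CANONICAL_JOINTS[c] for c in targets}
        covered |= _synthesizable(covered)
        missing = [j for j in REQUIRED_FOR_GEOMETRY if j not in covered]
        if missing:
            raise SchemaError(
                f"{self.source_schema}: required canonical joints not "
                f"covered: {missing}")

    @property
    def n_source(self) -> int:
        return len(self.source_joints)


def _synthesizable(covered: set[str]) -> set[str]:
    out: set[str] = set()
    for joint, (a, b) in MIDPOINT_SYNTHESIS.items():
        if joint not in covered and a in covered and b in covered:
            out.add(joint)
    return out


def _build_map(schema: str, source_joints: tuple[str, ...],
               name_map: dict[str, str]) -> SkeletonMap:
    canon_index = {j: i for i, j in enumerate(CANONICAL_JOINTS)}
    index_map = {
        source_joints.index(src): canon_index[dst]
        for src, dst in name_map.items() if src in source_joints
    }
    return SkeletonMap(schema, source_joints, index_map)


def get_skeleton_map(schema: str,
                     source_joints: tuple[str, ...] | None = None
                     ) -> SkeletonMap:
    """Return the registered map for ``schema``.

    ``schema`` is one of ``"Body25"``, ``"PlugInGait39"`` or ``"H36M17"``.
    For marker tables (``PlugInGait39``) pass the actual header labels so the
    map is built against the file's own column order.
    """
    if schema == "Body25":
        return _build_map(schema, BODY25_JOINTS, _BODY25_TO_CANONICAL)
    if schema == "PlugInGait39":
        joints = source_joints if source_joints is not None else tuple(
            _PIG_TO_CANONICAL)
        return _build_map(schema, tuple(joints), _PIG_TO_CANONICAL)
    if schema == "H36M17":
        joints = source_joints if source_joints is not None else CANONICAL_JOINTS
        return _build_map(schema, tuple(joints),
                          {j: j for j in CANONICAL_JOINTS})
    raise SchemaError(f"unknown schema {schema!r}")
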