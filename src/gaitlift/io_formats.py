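"""Readers and writers for the pipeline's file formats.

Three formats are handled: the OpenPose Body25 per-frame JSON dialect for 2D
keypoints, delimited marker tables with ``<label>X/Y/Z`` column triples for
3D trajectories, and the agreement report (JSON with a CSV rendering).
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from ._errors import FormatError, SchemaError
from .containers import KeypointSeries2D, MarkerSeries3D
from .skeleton import BODY25_JOINTS, get_skeleton_map

if TYPE_CHECKING:
    from .agreement_stats import AgreementReport

__all__ = [
    "read_keypoints", "read_markers", "write_report", "read_report",
    "write_keypoints", "KeypointSeries2D", "MarkerSeries3D",
]

DEFAULT_CONFIDENCE_THRESHOLD = 0.3


# ---------------------------------------------------------------------------
# 2D keypoints (OpenPose JSON dialect)

def read_keypoints(path: str | Path, schema: str = "Body25", *,
                   fps: float = 60.0,
                   confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
                   ) -> KeypointSeries2D:
    """Read 2D keypoints from OpenPose-style JSON.

    ``path`` is either a directory of one-file-per-frame JSONs (sorted by
    name, the OpenPose output layout) or a single JSON file holding a list of
    frame objects.  Each frame object carries ``people``, a list of
    detections with flat ``pose_keypoints_2d`` = [x, y, c] * 25.

    Frames with no detected person become all-missing.  When several people
    are present the one with the highest mean confidence is kept (a single
    treadmill walker is assumed; extra detections are noise).  Keypoints with
    confidence below ``confidence_threshold`` are marked missing so the
    gap-filling stage can repair them.
    """
    if schema != "Body25":
        raise SchemaError(f"read_keypoints supports Body25, got {schema!r}")
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix == ".json")
        if not files:
            raise FormatError(f"no .json files in {path}")
        frames = []
        for f in files:
            frames.append(_load_frame_json(f))
    else:
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}: malformed JSON: {exc}") from exc
        if isinstance(doc, dict):
            doc = [doc]
        frames = [(path, obj) for obj in doc]

    n_joints = len(BODY25_JOINTS)
    coords = np.full((len(frames), n_joints, 2), np.nan)
    confidence = np.zeros((len(frames), n_joints))
    missing = np.ones((len(frames), n_joints), dtype=bool)

    for t, (src, obj) in enumerate(frames):
        people = obj.get("people", [])
        if not people:
            continue
        best = max(people, key=lambda p: _mean_confidence(p, src, t))
        triples = _triples(best, src, t)
        conf = triples[:, 2]
        keep = conf >= confidence_threshold
        coords[t, keep, :] = triples[keep, :2]
        confidence[t] = np.clip(conf, 0.0, 1.0)
        missing[t] = ~keep

    return KeypointSeries2D(fps=fps, joints=BODY25_JOINTS, coords=coords,
                            confidence=confidence, missing=missing)


def _load_frame_json(path: Path):
    with open(path) as fh:
        try:
            return path, json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: malformed JSON: {exc}") from exc


def _triples(person: dict, src, frame: int) -> np.ndarray:
    flat = person.get("pose_keypoints_2d")
    if flat is None:
        raise FormatError(f"{src} frame {frame}: no pose_keypoints_2d")
    arr = np.asarray(flat, dtype=float)
    if arr.size != 3 * len(BODY25_JOINTS):
        raise SchemaError(
            f"{src} frame {frame}: expected {3 * len(BODY25_JOINTS)} values "
            f"({len(BODY25_JOINTS)} joints), got {arr.size}")
    return arr.reshape(-1, 3)


def _mean_confidence(person: dict, src, frame: int) -> float:
    return float(_triples(person, src, frame)[:, 2].mean())


def write_keypoints(series: KeypointSeries2D, path: str | Path) -> None:
    """Write a keypoint series as a single JSON array of frame objects."""
    doc = []
    for t in range(series.frames):
        triples = np.zeros((len(series.joints), 3))
        obs = ~series.missing[t]
        triples[obs, :2] = series.coords[t, obs]
        triples[:, 2] = series.confidence[t]
        triples[~obs, 2] = 0.0
        doc.append({"people": [
            {"pose_keypoints_2d": [round(v, 10) for v in triples.ravel()]}]})
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# 3D marker tables

_SUFFIX_RE = re.compile(r"^(?P<label>.+?)[._ ]?(?P<axis>[XYZxyz])$")


def read_markers(path: str | Path, schema: str = "PlugInGait39", *,
                 fps: float = 60.0, sep: str | None = None) -> MarkerSeries3D:
    """Read 3D marker trajectories from a delimited table.

    The header row names each column ``<label>X``/``<label>_X`` (same for Y
    and Z); every label must come as a complete X/Y/Z triple.  Blank or NaN
    cells become missing-mask entries.  A leading ``frame`` column is
    accepted and ignored for coordinates.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    cols = [c for c in df.columns if c.lower() not in ("frame", "time")]
    groups: dict[str, dict[str, str]] = {}
    for col in cols:
        m = _SUFFIX_RE.match(col.strip())
        if not m:
            raise SchemaError(f"{path}: column {col!r} has no X/Y/Z suffix")
        groups.setdefault(m["label"], {})[m["axis"].upper()] = col
    markers = []
    for label, axes in groups.items():
        if set(axes) != {"X", "Y", "Z"}:
            raise SchemaError(
                f"{path}: marker {label!r} has columns {sorted(axes)}, "
                "expected a complete X/Y/Z triple")
        markers.append(label)
    coords = np.stack(
        [df[[groups[m]["X"], groups[m]["Y"], groups[m]["Z"]]].to_numpy(float)
         for m in markers], axis=1)
    missing = np.isnan(coords).any(axis=2)
    coords[missing] = np.nan
    if schema:
        # validates that the required canonical joints are coverable
        get_skeleton_map(schema, tuple(markers))
    return MarkerSeries3D(fps=fps, markers=tuple(markers), coords=coords,
                          missing=missing)


def write_markers(series: MarkerSeries3D, path: str | Path) -> None:
    """Write a marker series as CSV with <label>X/Y/Z columns."""
    data = {"frame": np.arange(series.frames)}
    for i, label in enumerate(series.markers):
        for k, axis in enumerate("XYZ"):
            col = series.coords[:, i, k].copy()
            col[series.missing[:, i]] = np.nan
            data[f"{label}{axis}"] = col
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Agreement reports

def write_report(report: "AgreementReport", path: str | Path) -> None:
    """Write an agreement report as JSON, plus a CSV table next to it.

    ``path`` names the JSON file; a sibling with suffix ``.csv`` is written
    for spreadsheet use.  The JSON rendering round-trips losslessly through
    :func:`read_report`.
    """
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
    report.to_frame().to_csv(path.with_suffix(".csv"), index=False)


def read_report(path: str | Path) -> "AgreementReport":
    from .agreement_stats import AgreementReport
    with open(path) as fh:
        return AgreementReport.from_dict(json.load(fh))
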