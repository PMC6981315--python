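"""Read, calibrate, validate and write instrument-tip trajectories.

The input boundary of the package is the output of a video tracking tool:
an ordered sequence of (frame, x, y) samples for one instrument tip.  Two
dialects are supported, a generic trajectory CSV and a Kinovea-style XML
track export.  Raw coordinates are in pixels; a :class:`Calibration`
(pixels per cm, frame rate) converts them into the centimetre coordinates
that every kinematic index downstream expects.  The 1.0 cm extreme-step
threshold makes a correct pixel scale essential, so calibration is always
an explicit input — never guessed from the file.

Coordinate convention: image coordinates (origin top-left, y down), as
tracking tools export.  All indices use only inter-sample distances, so
the convention matters only for plotting.

Gaps in frame indices (dropped frames) are retained, not interpolated;
kinematics treats each consecutive sample pair as one frame step.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TrajectoryFormatError

__all__ = [
    "Calibration",
    "Trajectory",
    "read_trajectory_csv",
    "read_trajectory_kinovea_xml",
    "write_trajectory_csv",
]


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-centimetre scale and video frame rate.

    Parameters
    ----------
    pixels_per_cm
        Number of image pixels per physical centimetre in the tracking
        plane.  Must be measured against a known reference (e.g. the
        instrument shaft diameter); an incorrect scale silently corrupts
        the extreme-movement count.
    frame_rate_hz
        Video frame rate.  Carried as metadata: the indices are defined
        per frame, not per second.
    """

    pixels_per_cm: float
    frame_rate_hz: float

    def __post_init__(self) -> None:
        for name in ("pixels_per_cm", "frame_rate_hz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class Trajectory:
    """A calibrated 2-D instrument-tip track.

    ``frames`` are strictly increasing integer frame indices; ``xy_cm`` is
    an (n, 2) float array of tip positions in centimetres.
    """

    frames: np.ndarray
    xy_cm: np.ndarray
    frame_rate_hz: float
    label: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        xy = np.asarray(self.xy_cm, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError(f"xy_cm must have shape (n, 2), got {xy.shape}")
        if frames.shape[0] != xy.shape[0]:
            raise ValueError("frames and xy_cm lengths differ")
        if frames.size > 1 and not np.all(np.diff(frames) > 0):
            raise ValueError("frame indices must be strictly increasing")
        if not np.all(np.isfinite(xy)):
            raise ValueError("coordinates must be finite")
        if not (np.isfinite(self.frame_rate_hz) and self.frame_rate_hz > 0):
            raise ValueError("frame_rate_hz must be finite and > 0")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "xy_cm", xy)

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_steps(self) -> int:
        """Number of consecutive sample pairs."""
        return max(len(self) - 1, 0)


def _columns(df: pd.DataFrame, frame_col: str, x_col: str, y_col: str,
             path: Path) -> tuple[str, str, str, bool]:
    """Resolve column names; returns (frame, x, y, already_calibrated)."""
    cols = set(df.columns)
    if {frame_col, x_col, y_col} <= cols:
        return frame_col, x_col, y_col, False
    # calibrated dialect written by write_trajectory_csv
    if {frame_col, f"{x_col}_cm", f"{y_col}_cm"} <= cols:
        return frame_col, f"{x_col}_cm", f"{y_col}_cm", False
    raise TrajectoryFormatError(
        f"{path}: expected columns ({frame_col}, {x_col}, {y_col}) or "
        f"({frame_col}, {x_col}_cm, {y_col}_cm); found {sorted(cols)}"
    )


def read_trajectory_csv(
    path: str | Path,
    calibration: Calibration,
    *,
    frame_col: str = "frame",
    x_col: str = "x",
    y_col: str = "y",
    label: str | None = None,
) -> Trajectory:
    """Read a trajectory from a generic tracking CSV.

    The file must contain a header with a frame column and an x/y pair —
    either raw pixel columns (``x``, ``y``) or pre-calibrated ones
    (``x_cm``, ``y_cm``; pass ``pixels_per_cm=1`` in that case).  Rows are
    sorted by frame index; duplicate frame indices are rejected.  Missing
    or non-numeric cells raise :class:`TrajectoryFormatError` naming the
    offending row (1-based, excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    fc, xc, yc, _ = _columns(df, frame_col, x_col, y_col, path)

    numeric = df[[fc, xc, yc]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise TrajectoryFormatError(
            f"{path}: missing or non-numeric cell in data row {row}"
        )
    numeric = numeric.sort_values(fc, kind="stable")
    frames = numeric[fc].to_numpy()
    if np.any(frames != np.round(frames)):
        raise TrajectoryFormatError(f"{path}: frame indices must be integers")
    frames = frames.astype(np.int64)
    if frames.size > 1 and np.any(np.diff(frames) == 0):
        dup = int(frames[np.argmin(np.diff(frames))])
        raise TrajectoryFormatError(f"{path}: duplicate frame index {dup}")
    xy_px = numeric[[xc, yc]].to_numpy(dtype=float)
    return Trajectory(
        frames=frames,
        xy_cm=xy_px / calibration.pixels_per_cm,
        frame_rate_hz=calibration.frame_rate_hz,
        label=path.stem if label is None else label,
    )


def read_trajectory_kinovea_xml(
    path: str | Path,
    calibration: Calibration,
    *,
    decimal_comma: bool = False,
    label: str | None = None,
) -> Trajectory:
    """Read a Kinovea-style XML track export.

    Accepted dialect (see the bundled sample in the README): the document
    contains one or more ``TrackPointList`` elements whose ``TrackPoint``
    children carry per-sample ``X``/``Y`` pixel attributes and a ``T``
    frame attribute.  The first list found is read.  Some locales export
    decimal commas; pass ``decimal_comma=True`` to accept them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise TrajectoryFormatError(f"{path}: malformed XML: {exc}") from exc

    point_list = root.find(".//TrackPointList")
    if root.tag == "TrackPointList":
        point_list = root
    if point_list is None:
        raise TrajectoryFormatError(f"{path}: no TrackPointList element found")

    def _num(raw: str | None, what: str, i: int) -> float:
        if raw is None:
            raise TrajectoryFormatError(
                f"{path}: TrackPoint {i} missing attribute {what}"
            )
        if decimal_comma:
            raw = raw.replace(",", ".")
        try:
            return float(raw)
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"{path}: TrackPoint {i} has non-numeric {what}={raw!r}"
            ) from exc

    rows = []
    for i, pt in enumerate(point_list.findall("TrackPoint")):
        rows.append((
            _num(pt.get("T"), "T", i),
            _num(pt.get("X"), "X", i),
            _num(pt.get("Y"), "Y", i),
        ))
    if not rows:
        raise TrajectoryFormatError(f"{path}: TrackPointList contains no points")
    arr = np.array(sorted(rows, key=lambda r: r[0]), dtype=float)
    frames = arr[:, 0]
    if np.any(frames != np.round(frames)):
        raise TrajectoryFormatError(f"{path}: T attributes must be integer frames")
    frames = frames.astype(np.int64)
    if frames.size > 1 and np.any(np.diff(frames) == 0):
        raise TrajectoryFormatError(f"{path}: duplicate frame index in track")
    if label is None:
        track = root.find(".//Track")
        label = (track.get("name") if track is not None else None) or path.stem
    return Trajectory(
        frames=frames,
        xy_cm=arr[:, 1:] / calibration.pixels_per_cm,
        frame_rate_hz=calibration.frame_rate_hz,
        label=label,
    )


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    """Write a calibrated trajectory as ``frame,x_cm,y_cm`` CSV.

    Full float precision (``repr``) is used, so reading the file back with
    ``pixels_per_cm=1`` reproduces the points exactly.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("frame,x_cm,y_cm\n")
        for f, (x, y) in zip(traj.frames, traj.xy_cm):
            fh.write(f"{int(f)},{float(x)!r},{float(y)!r}\n")
    return path
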