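"""The three kinematic indices of psychomotor economy: L, A and J.

Given a calibrated instrument-tip trajectory, this module computes

* **path length** ``L`` — total distance travelled by the tip, the
  discrete Euclidean arc length over consecutive samples, in cm;
* **average movement** ``A`` — mean tip displacement per frame step,
  ``L / n_steps``, in cm/frame;
* **extreme movements** ``J`` (the "jerk index") — the number of frame
  steps longer than a threshold, 1.0 cm by default.  Note this is a
  *count* of large excursions, not the third derivative of position.

A step is a consecutive sample pair.  Dropped frames are allowed by
default (each surviving pair still counts as one step); set
``strict_frames=True`` to reject gapped input instead.  The threshold
comparison is strict: a step of exactly 1.0 cm is not extreme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .trajectory_io import Trajectory

__all__ = [
    "KinematicsConfig",
    "KinematicIndices",
    "step_lengths",
    "path_length",
    "average_movement",
    "extreme_movements",
    "compute_indices",
]

DEFAULT_EXTREME_STEP_CM = 1.0


@dataclass(frozen=True)
class KinematicsConfig:
    """Options for index computation.

    extreme_step_cm
        Step length above which (strictly) a movement counts as extreme.
    strict_frames
        Reject trajectories whose frame indices are not contiguous.
    smooth_window
        Width of an optional centred moving-average pre-filter on the
        coordinates; 1 (default) disables smoothing.  The indices are
        defined on the raw track; the filter exists for exploratory use
        with very noisy tracking only.
    """

    extreme_step_cm: float = DEFAULT_EXTREME_STEP_CM
    strict_frames: bool = False
    smooth_window: int = 1

    def __post_init__(self) -> None:
        if not (np.isfinite(self.extreme_step_cm) and self.extreme_step_cm > 0):
            raise ValueError("extreme_step_cm must be finite and > 0")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")


@dataclass(frozen=True)
class KinematicIndices:
    """The (L, A, J) triple for one performance."""

    path_length_cm: float
    avg_move_cm_per_frame: float
    extreme_moves: int
    n_steps: int

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0 <= self.extreme_moves <= self.n_steps:
            raise ValueError("extreme_moves must lie in [0, n_steps]")
        if abs(self.avg_move_cm_per_frame * self.n_steps - self.path_length_cm) > 1e-9 * max(1.0, self.path_length_cm):
            raise ValueError("A must equal L / n_steps")

    def as_dict(self) -> dict:
        return {
            "L": self.path_length_cm,
            "A": self.avg_move_cm_per_frame,
            "J": self.extreme_moves,
            "n_steps": self.n_steps,
        }


def _prepared_xy(traj: Trajectory, config: KinematicsConfig) -> np.ndarray:
    if len(traj) < 2:
        raise InsufficientDataError(
            f"trajectory {traj.label!r} has {len(traj)} point(s); need >= 2"
        )
    if config.strict_frames and np.any(np.diff(traj.frames) != 1):
        raise ValueError(
            f"trajectory {traj.label!r} has frame gaps and strict_frames is set"
        )
    xy = traj.xy_cm
    if config.smooth_window > 1:
        w = config.smooth_window
        kernel = np.ones(w) / w
        pad = np.pad(xy, ((w // 2, w - 1 - w // 2), (0, 0)), mode="edge")
        xy = np.column_stack([
            np.convolve(pad[:, 0], kernel, mode="valid"),
            np.convolve(pad[:, 1], kernel, mode="valid"),
        ])
    return xy


def step_lengths(traj: Trajectory, config: KinematicsConfig | None = None) -> np.ndarray:
    """Euclidean length of every consecutive-sample step, in cm."""
    config = config or KinematicsConfig()
    xy = _prepared_xy(traj, config)
    d = np.diff(xy, axis=0)
    return np.hypot(d[:, 0], d[:, 1])


def path_length(traj: Trajectory, config: KinematicsConfig | None = None) -> float:
    """Total tip path length L in cm: the sum of all step lengths."""
    return float(np.sum(step_lengths(traj, config)))


def average_movement(traj: Trajectory, config: KinematicsConfig | None = None) -> float:
    """Average movement A in cm/frame: L divided by the number of steps."""
    steps = step_lengths(traj, config)
    return float(np.mean(steps))


def extreme_movements(traj: Trajectory, config: KinematicsConfig | None = None) -> int:
    """Extreme-movement count J: steps strictly longer than the threshold."""
    config = config or KinematicsConfig()
    steps = step_lengths(traj, config)
    return int(np.sum(steps > config.extreme_step_cm))


def compute_indices(traj: Trajectory, config: KinematicsConfig | None = None) -> KinematicIndices:
    """Compute the full (L, A, J) triple in one pass."""
    config = config or KinematicsConfig()
    steps = step_lengths(traj, config)
    total = float(np.sum(steps))
    return KinematicIndices(
        path_length_cm=total,
        avg_move_cm_per_frame=total / steps.size,
        extreme_moves=int(np.sum(steps > config.extreme_step_cm)),
        n_steps=int(steps.size),
    )
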