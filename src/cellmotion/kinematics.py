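"""Kinematic summaries of a track: intensity of response, directionality ratio, speed.

* IR (intensity of response): the modulus of the net displacement vector,
  |r(N) − r(1)|, in mm — how far the cell ended up from where it started.
* DR (directionality ratio): net displacement / total path length, in [0, 1];
  1 for a perfectly straight track, 0 for a closed loop.
* AS (average speed): total path length / duration, in mm/s, computed on the
  raw sampled polyline (no smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import InsufficientDataError, Trajectory


@dataclass(frozen=True)
class KinematicRecord:
    ir: float                # mm
    dr: float                # dimensionless, NaN when path length is 0
    as_speed: float          # mm/s
    path_length: float       # mm
    net_displacement: float  # mm
    duration: float          # s


def path_length(traj: Trajectory) -> float:
    """Sum of frame-to-frame step lengths, mm."""
    return float(np.sum(np.hypot(np.diff(traj.x), np.diff(traj.y))))


def intensity_of_response(traj: Trajectory, project_on_axis: bool = False) -> float:
    """|net displacement| in mm (or, optionally, its projection on the stimulus x-axis)."""
    if len(traj) < 2:
        raise InsufficientDataError("need >= 2 frames")
    dx = traj.x[-1] - traj.x[0]
    dy = traj.y[-1] - traj.y[0]
    return abs(float(dx)) if project_on_axis else float(np.hypot(dx, dy))


def directionality_ratio(traj: Trajectory) -> float:
    """Net displacement over path length; NaN for a track that never moved."""
    pl = path_length(traj)
    if pl == 0.0:
        return float("nan")
    return intensity_of_response(traj) / pl


def average_speed(traj: Trajectory) -> float:
    """Path length divided by duration, mm/s."""
    if traj.duration <= 0:
        raise ValueError("track duration must be positive")
    return path_length(traj) / traj.duration


def kinematic_record(traj: Trajectory, project_ir_on_axis: bool = False) -> KinematicRecord:
    pl = path_length(traj)
    nd = intensity_of_response(traj)
    return KinematicRecord(
        ir=intensity_of_response(traj, project_on_axis=project_ir_on_axis),
        dr=(nd / pl) if pl > 0 else float("nan"),
        as_speed=pl / traj.duration,
        path_length=pl,
        net_displacement=nd,
        duration=traj.duration,
    )
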