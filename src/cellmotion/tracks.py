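"""Trajectory containers, track table I/O, validation and resampling.

A trajectory is a time-ordered sequence of 2-D cell-centroid positions
``r(t) = (x(t), y(t))`` sampled at a fixed interval ``dt``.  Positions are in
millimetres and time in seconds throughout the package; every downstream
statistic (displacement cosines, scaling exponents, entropy, kinematics) is
documented in these units.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Relative tolerance on the uniformity of the sampling grid.
DT_RTOL = 1e-6

#: Recognized scenario labels: no stimulus, electric field (galvanotaxis),
#: peptide gradient (chemotaxis), both stimuli at once, and generated tracks.
SCENARIOS = ("Sc1", "Sc2", "Sc3", "Sc4", "synthetic")

REQUIRED_COLUMNS = ("cell_id", "t", "x", "y")
ALL_COLUMNS = ("cell_id", "species", "scenario", "t", "x", "y")


class TrackFormatError(ValueError):
    """A track table is structurally unreadable (e.g. a required column is missing)."""


class TrackValidationError(ValueError):
    """A parsed track violates an invariant (non-monotone time, non-finite coordinates...)."""


class InsufficientDataError(ValueError):
    """A track is too short for the requested operation."""


@dataclass(frozen=True)
class Trajectory:
    """One cell's track: strictly increasing, uniformly spaced times with x/y in mm.

    Parameters
    ----------
    cell_id : str
        Identifier of the cell (unique within a :class:`TrajectorySet`).
    species : str
        Species label (free-form; "synthetic" for generated walkers).
    scenario : str
        One of ``Sc1``–``Sc4`` or ``synthetic``.
    t, x, y : ndarray
        Equal-length arrays, ``N >= 3`` after validation; ``t`` in s, ``x``/``y`` in mm.
    """

    cell_id: str
    species: str
    scenario: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "x", "y"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise TrackValidationError(
                f"cell {self.cell_id!r}: t, x, y must be equal-length 1-D arrays"
            )
        if len(self.t) < 3:
            raise InsufficientDataError(
                f"cell {self.cell_id!r}: need at least 3 frames, got {len(self.t)}"
            )
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise TrackValidationError(f"cell {self.cell_id!r}: non-finite coordinates or times")
        dts = np.diff(self.t)
        if np.any(dts <= 0):
            raise TrackValidationError(f"cell {self.cell_id!r}: time not strictly increasing")
        if self.scenario not in SCENARIOS:
            raise TrackValidationError(
                f"cell {self.cell_id!r}: unknown scenario {self.scenario!r}"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        """Sampling interval in seconds (median frame spacing)."""
        return float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        """Track duration ``t[-1] - t[0]`` in seconds."""
        return float(self.t[-1] - self.t[0])

    def is_uniform(self, rtol: float = DT_RTOL) -> bool:
        dts = np.diff(self.t)
        return bool(np.all(np.abs(dts - self.dt) <= rtol * self.dt))

    def positions(self) -> np.ndarray:
        """(N, 2) array of positions in mm."""
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class StepSeries:
    """Frame-to-frame move steps of a trajectory.

    ``dx``/``dy`` are first differences (length ``N-1``); ``turning_angle`` is
    the signed angle between consecutive step vectors (length ``N-2``), in
    (−π, π], with entries adjacent to zero-length steps undefined (NaN) and
    flagged in ``angle_defined``.
    """

    dx: np.ndarray
    dy: np.ndarray
    step_length: np.ndarray
    turning_angle: np.ndarray
    angle_defined: np.ndarray


@dataclass
class TrajectorySet:
    """A bag of trajectories sharing one sampling interval."""

    trajectories: list[Trajectory]
    dt: float
    provenance: str = ""
    n_rejected_rows: int = 0

    def __post_init__(self) -> None:
        for tr in self.trajectories:
            if not np.isclose(tr.dt, self.dt, rtol=1e-6):
                raise TrackValidationError(
                    f"cell {tr.cell_id!r}: dt {tr.dt} differs from set dt {self.dt}"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per frame (the on-disk layout)."""
        parts = []
        for tr in self.trajectories:
            parts.append(
                pd.DataFrame(
                    {
                        "cell_id": tr.cell_id,
                        "species": tr.species,
                        "scenario": tr.scenario,
                        "t": tr.t,
                        "x": tr.x,
                        "y": tr.y,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# I/O


def read_trajectories(
    path,
    delimiter: str = ",",
    default_species: str = "unknown",
    default_scenario: str = "synthetic",
) -> TrajectorySet:
    """Read a delimiter-separated track table into a :class:`TrajectorySet`.

    The header must name ``cell_id``, ``t``, ``x`` and ``y`` (``species`` and
    ``scenario`` are optional).  Rows whose numeric fields fail to parse are
    dropped and counted in ``n_rejected_rows``.  Frames are sorted by time
    within each cell; a cell with duplicate or otherwise non-monotone times
    after sorting raises :class:`TrackValidationError` naming the cell.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"track table missing required column(s): {missing}")
    if "species" not in df.columns:
        df["species"] = default_species
    if "scenario" not in df.columns:
        df["scenario"] = default_scenario

    n_before = len(df)
    for col in ("t", "x", "y"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["t", "x", "y"])
    n_rejected = n_before - len(df)

    trajectories = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("t", kind="stable")
        t = grp["t"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise TrackValidationError(
                f"cell {cell_id!r}: duplicate or non-monotone time values"
            )
        trajectories.append(
            Trajectory(
                cell_id=str(cell_id),
                species=str(grp["species"].iloc[0]),
                scenario=str(grp["scenario"].iloc[0]),
                t=t,
                x=grp["x"].to_numpy(float),
                y=grp["y"].to_numpy(float),
            )
        )
    if not trajectories:
        raise TrackFormatError("track table contains no valid rows")
    dt = trajectories[0].dt
    source = path if isinstance(path, str) else getattr(path, "name", "<stream>")
    return TrajectorySet(trajectories, dt=dt, provenance=f"read from {source}",
                         n_rejected_rows=n_rejected)


def write_trajectories(tset: TrajectorySet, path, delimiter: str = ",") -> None:
    """Write the set in the same long tabular format ``read_trajectories`` accepts."""
    tset.to_frame().to_csv(path, sep=delimiter, index=False,
                           float_format="%.12g")


# ---------------------------------------------------------------------------
# Derived series


def to_steps(traj: Trajectory) -> StepSeries:
    """First-difference move steps and signed turning angles of a track.

    Turning angle i is the angle from step vector i to step vector i+1,
    in (−π, π]; where either step has zero length the angle is undefined
    (NaN, ``angle_defined`` False) rather than assigned an arbitrary direction.
    """
    if len(traj) < 2:
        raise InsufficientDataError(f"cell {traj.cell_id!r}: need >= 2 frames for steps")
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    step_length = np.hypot(dx, dy)

    # cross/dot of consecutive step vectors -> signed angle
    cross = dx[:-1] * dy[1:] - dy[:-1] * dx[1:]
    dot = dx[:-1] * dx[1:] + dy[:-1] * dy[1:]
    angle = np.arctan2(cross, dot)
    # arctan2(0, -q) returns +pi, already in (-pi, pi]
    defined = (step_length[:-1] > 0) & (step_length[1:] > 0)
    angle = np.where(defined, angle, np.nan)
    return StepSeries(dx=dx, dy=dy, step_length=step_length,
                      turning_angle=angle, angle_defined=defined)


def resample_uniform(traj: Trajectory, dt: float) -> Trajectory:
    """Linearly interpolate a track onto a uniform grid with spacing ``dt``.

    Endpoints are preserved; a track that is already uniform at ``dt`` is
    returned with identical coordinates.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if traj.duration < 2 * dt:
        raise InsufficientDataError(
            f"cell {traj.cell_id!r}: duration {traj.duration} s < 2*dt = {2 * dt} s"
        )
    n = int(round(traj.duration / dt))
    grid = traj.t[0] + dt * np.arange(n + 1)
    grid[-1] = traj.t[-1]  # guard against rounding past the last sample
    x = np.interp(grid, traj.t, traj.x)
    y = np.interp(grid, traj.t, traj.y)
    return replace(traj, t=grid, x=x, y=y)


def validate_uniform(traj: Trajectory, rtol: float = DT_RTOL) -> Trajectory:
    """Return a track guaranteed uniform: unchanged if already so, else resampled at its median dt."""
    if traj.is_uniform(rtol):
        return traj
    return resample_uniform(traj, traj.dt)
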