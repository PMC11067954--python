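"""Displacement-cosine directionality analysis and polar-histogram summaries.

The stimulus axis of the migration chamber runs along x, with the cathode on
the +x side and the chemoattractant peptide on the −x side.  A cell's
directionality is summarized by the cosine of the angle between its net
displacement vector and the +x axis: +1 means straight toward the cathode,
−1 straight toward the peptide, 0 orthogonal to the cue axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import Trajectory, TrajectorySet

N_SECTORS = 8


class ZeroDisplacementError(ValueError):
    """Net displacement is zero: the direction (and cosine) is undefined."""


@dataclass(frozen=True)
class DirectionalitySummary:
    """Per-cell cosines plus the 8-sector polar histogram of net-displacement angles."""

    cosines: np.ndarray          # one value per cell with nonzero net displacement
    median: float
    iqr: float
    sector_percent: np.ndarray   # 8 sector percentages, summing to 100
    n_excluded: int              # cells dropped for zero net displacement


def net_displacement(traj: Trajectory) -> np.ndarray:
    return np.array([traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]])


def displacement_cosine(traj: Trajectory, flip_axis: bool = False) -> float:
    """Cosine of the angle between the net displacement and the stimulus (+x) axis.

    ``flip_axis`` reverses the sign convention (cathode at −x).  Raises
    :class:`ZeroDisplacementError` when start and end coincide.
    """
    d = net_displacement(traj)
    norm = float(np.hypot(*d))
    if norm == 0.0:
        raise ZeroDisplacementError(f"cell {traj.cell_id!r}: zero net displacement")
    c = float(d[0] / norm)
    return -c if flip_axis else c


def displacement_angle(traj: Trajectory) -> float:
    """Net-displacement angle in (−π, π], measured from the +x axis."""
    d = net_displacement(traj)
    if d[0] == 0.0 and d[1] == 0.0:
        raise ZeroDisplacementError(f"cell {traj.cell_id!r}: zero net displacement")
    return float(np.arctan2(d[1], d[0]))


def polar_histogram(trajs: TrajectorySet | list[Trajectory]) -> np.ndarray:
    """Percentage of cells whose net-displacement angle falls in each of 8 sectors.

    Sectors are half-open intervals of width π/4 centred on the +x axis: the
    first is [−π/8, π/8), the next proceeds counter-clockwise, and so on.
    Cells with zero net displacement are excluded; if none remain, raises
    :class:`ZeroDisplacementError`.
    """
    angles = []
    for tr in trajs:
        try:
            angles.append(displacement_angle(tr))
        except ZeroDisplacementError:
            continue
    if not angles:
        raise ZeroDisplacementError("no cell has a nonzero net displacement")
    angles = np.asarray(angles)
    # rotate by +pi/8 so sector boundaries land on multiples of pi/4
    sector = np.floor((angles + np.pi / 8) / (np.pi / 4)).astype(int) % N_SECTORS
    counts = np.bincount(sector, minlength=N_SECTORS)
    return 100.0 * counts / counts.sum()


def summarize_directionality(trajs: TrajectorySet | list[Trajectory],
                             flip_axis: bool = False) -> DirectionalitySummary:
    """Cosines, their median/IQR and the polar histogram for a set of tracks."""
    cosines = []
    n_excluded = 0
    for tr in trajs:
        try:
            cosines.append(displacement_cosine(tr, flip_axis=flip_axis))
        except ZeroDisplacementError:
            n_excluded += 1
    if not cosines:
        raise ZeroDisplacementError("no cell has a nonzero net displacement")
    cosines = np.asarray(cosines)
    q1, med, q3 = np.percentile(cosines, [25, 50, 75])
    return DirectionalitySummary(
        cosines=cosines,
        median=float(med),
        iqr=float(q3 - q1),
        sector_percent=polar_histogram(trajs),
        n_excluded=n_excluded,
    )
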