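"""Approximate entropy (ApEn) of move-step series, on full tracks and growing windows.

ApEn(m, r, N) quantifies the (ir)regularity of a time series as a finite-N
proxy for the Kolmogorov–Sinai entropy rate: the negative average log
conditional probability that sequences matching for m samples (within a
Chebyshev tolerance r) still match at sample m+1.  Ordered, predictable
series score near 0; uncorrelated noise scores near 2 for the standard
parameters m = 2, r = 0.2 SD.

Self-matches are included (the original convention), which keeps ApEn >= 0.

The profile variant recomputes ApEn on windows anchored at t = 0 whose
endpoint grows by a fixed increment (default 25 s, 72 windows spanning a
30-min track), mirroring the heatmap layout used to compare recorded and
shuffled trajectories.  The series analysed is the frame-to-frame increment
series of one coordinate — increments are quasi-stationary, which ApEn
assumes, while raw positions of a migrating cell are not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import InsufficientDataError, Trajectory

DEFAULT_M = 2
DEFAULT_R_FRAC = 0.2
DEFAULT_WINDOW_STEP = 25.0  # s
DEFAULT_N_WINDOWS = 72

_CHUNK = 256  # template rows per block in the pairwise-distance pass


@dataclass(frozen=True)
class ApEnProfile:
    """ApEn over growing windows, plus the parameters that produced it.

    ``apen`` holds one value per window; windows too short to embed are NaN.
    ``summary`` is the median of the defined entries (the per-cell scalar used
    in feature vectors).
    """

    window_endpoints: np.ndarray  # s
    apen: np.ndarray
    m: int
    r_frac: float

    @property
    def summary(self) -> float:
        defined = self.apen[np.isfinite(self.apen)]
        return float(np.median(defined)) if len(defined) else float("nan")


def _phi(series: np.ndarray, m: int, r: float) -> float:
    """Pincus Φ_m(r) = mean_i log C_i^m(r), self-matches included."""
    n = len(series)
    n_templates = n - m + 1
    tmpl = np.lib.stride_tricks.sliding_window_view(series, m)
    counts = np.zeros(n_templates, dtype=np.int64)
    for start in range(0, n_templates, _CHUNK):
        block = tmpl[start:start + _CHUNK]  # (b, m)
        # Chebyshev distance block vs all templates
        d = np.abs(block[:, None, 0] - tmpl[None, :, 0])
        for k in range(1, m):
            np.maximum(d, np.abs(block[:, None, k] - tmpl[None, :, k]), out=d)
        counts[start:start + _CHUNK] = np.count_nonzero(d <= r, axis=1)
    return float(np.mean(np.log(counts / n_templates)))


def apen(series: np.ndarray, m: int = DEFAULT_M, r: float | None = None,
         r_frac: float = DEFAULT_R_FRAC) -> float:
    """Approximate entropy ApEn(m, r) = Φ_m(r) − Φ_{m+1}(r) of a 1-D series.

    ``r`` is the match tolerance in series units; if omitted it is resolved
    as ``r_frac`` times the series SD.  A constant series returns exactly 0.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < m + 2:
        raise InsufficientDataError(f"apen needs N >= m+2 = {m + 2}, got {n}")
    sd = float(series.std())
    if sd == 0.0:
        return 0.0  # fully regular signal, regardless of tolerance
    if r is None:
        r = r_frac * sd
    if r <= 0:
        raise ValueError(f"tolerance r must be positive, got {r}")
    return _phi(series, m, r) - _phi(series, m + 1, r)


def apen_profile(traj_or_series, m: int = DEFAULT_M, r_frac: float = DEFAULT_R_FRAC,
                 window_step: float = DEFAULT_WINDOW_STEP,
                 n_windows: int = DEFAULT_N_WINDOWS,
                 dt: float | None = None, coordinate: str = "x") -> ApEnProfile:
    """ApEn over cumulative windows [0, k * window_step], k = 1..n_windows.

    Accepts a :class:`Trajectory` (its ``coordinate`` increment series is
    analysed) or a pre-computed 1-D increment series with explicit ``dt``.
    The tolerance is resolved per window as ``r_frac`` times that window's SD.
    Windows extending beyond the track are NaN (the profile is truncated).
    """
    if isinstance(traj_or_series, Trajectory):
        coord = getattr(traj_or_series, coordinate)
        series = np.diff(coord)
        dt = traj_or_series.dt
    else:
        series = np.asarray(traj_or_series, dtype=float)
        if dt is None:
            raise ValueError("dt is required when passing a raw series")
    endpoints = window_step * np.arange(1, n_windows + 1)
    values = np.full(n_windows, np.nan)
    for k, t_end in enumerate(endpoints):
        n_frames = int(round(t_end / dt))  # increments in [0, t_end]
        if n_frames > len(series):
            break  # track shorter than requested span: truncate
        if n_frames < m + 2:
            continue  # too short to embed; flagged undefined
        values[k] = apen(series[:n_frames], m=m, r_frac=r_frac)
    return ApEnProfile(window_endpoints=endpoints, apen=values, m=m, r_frac=r_frac)
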