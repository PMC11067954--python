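"""Fluctuation-scaling estimators: rmsf, MSD and DFA, with shared log–log fitting.

All three estimators summarize how a fluctuation measure F grows with scale
and reduce to a single scaling exponent from an ordinary least-squares fit in
log–log coordinates:

* **rmsf** (root mean square fluctuation): F(l) = SD over t of the l-lag
  displacements ``s(t+l) − s(t)`` of one position coordinate.  F(l) ~ l^α with
  α ≈ 0.5 for uncorrelated increments, α > 0.5 for positive long-range
  correlation (for fractional Brownian motion, α = H).
* **MSD** (time-averaged mean square displacement): F(τ) = mean over t of
  ``|r(t+τ) − r(t)|²`` using both coordinates.  MSD ~ τ^β with β = 1 normal
  diffusion, 1 < β < 2 superdiffusion, β = 2 ballistic.
* **DFA** (detrended fluctuation analysis): rms residual of the integrated,
  per-window polynomial-detrended series versus window size ℓ, F(ℓ) ~ ℓ^γ;
  γ ≈ 0.5 for uncorrelated series, 1.5 < γ < 2 for persistent
  trend-reinforcing paths (for fBm position input, γ = H + 1).

The temporal-order null (shuffle surrogate) collapses all three: α → 0.5,
γ → 0.5, β → 0.  See :func:`cellmotion.pipeline.shuffled_exponents` for the
per-estimator shuffle targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import InsufficientDataError, Trajectory

#: log-spaced lag grids: points per decade and maximum lag as a fraction of N.
POINTS_PER_DECADE = 25
MAX_LAG_FRACTION = 0.25

#: Tolerance (log10 units) for delimiting the correlation regime around the fit line.
CROSSOVER_TOL = 0.05

MIN_N_RMSF = 64
MIN_N_MSD = 64
MIN_N_DFA = 256
MIN_FIT_POINTS = 5


class FitError(ValueError):
    """A power-law fit could not be performed (degenerate or insufficient curve)."""


@dataclass(frozen=True)
class ScalingCurve:
    """(lag, fluctuation) pairs on which a log–log fit is made."""

    lags: np.ndarray
    fluctuation: np.ndarray
    method: str  # rmsf | msd | dfa

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags", np.asarray(self.lags, dtype=float))
        object.__setattr__(self, "fluctuation", np.asarray(self.fluctuation, dtype=float))
        if len(self.lags) != len(self.fluctuation) or len(self.lags) < MIN_FIT_POINTS:
            raise ValueError("curve needs >= 5 matching (lag, F) pairs")
        if np.any(np.diff(self.lags) <= 0) or self.lags[0] < 1:
            raise ValueError("lags must be strictly increasing and >= 1")
        if np.any(self.fluctuation < 0):
            raise ValueError("fluctuation values must be nonnegative")


@dataclass(frozen=True)
class ScalingFit:
    """Result of an OLS power-law fit ``log10 F = exponent * log10 lag + intercept``."""

    exponent: float
    intercept: float
    fit_range: tuple[float, float]
    r_squared: float
    n_points: int
    crossover_lag: float | None = None


def log_lag_grid(n: int, min_lag: int = 1, max_fraction: float = MAX_LAG_FRACTION,
                 points_per_decade: int = POINTS_PER_DECADE) -> np.ndarray:
    """Unique integer lags, log-spaced from ``min_lag`` to ``max_fraction * n``."""
    max_lag = int(n * max_fraction)
    if max_lag <= min_lag:
        raise InsufficientDataError(f"series too short for lag grid (N={n})")
    n_pts = max(MIN_FIT_POINTS + 1,
                int(np.ceil(points_per_decade * np.log10(max_lag / min_lag))))
    grid = np.logspace(np.log10(min_lag), np.log10(max_lag), n_pts)
    return np.unique(np.round(grid).astype(int))


# ---------------------------------------------------------------------------
# estimators


def rmsf_curve(series: np.ndarray, lags: np.ndarray | None = None) -> ScalingCurve:
    """Root-mean-square fluctuation of a 1-D position series.

    For each lag l, all overlapping l-lag displacements Δ_l(t) = s(t+l) − s(t)
    are formed and F(l) is their standard deviation (centred, so a pure linear
    drift contributes nothing).
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < MIN_N_RMSF:
        raise InsufficientDataError(f"rmsf needs N >= {MIN_N_RMSF}, got {n}")
    if lags is None:
        lags = log_lag_grid(n)
    fluct = np.empty(len(lags))
    for i, l in enumerate(lags):
        d = series[l:] - series[:-l]
        fluct[i] = d.std()
    return ScalingCurve(lags=lags, fluctuation=fluct, method="rmsf")


def msd_curve(traj: Trajectory | np.ndarray, lags: np.ndarray | None = None) -> ScalingCurve:
    """Time-averaged mean square displacement of a 2-D track.

    MSD(τ) = mean over t of |r(t+τ) − r(t)|², overlapping time origins, both
    coordinates.  Accepts a :class:`Trajectory` or an (N, 2) position array.
    """
    pos = traj.positions() if isinstance(traj, Trajectory) else np.asarray(traj, dtype=float)
    n = len(pos)
    if n < MIN_N_MSD:
        raise InsufficientDataError(f"msd needs N >= {MIN_N_MSD}, got {n}")
    if lags is None:
        lags = log_lag_grid(n)
    fluct = np.empty(len(lags))
    for i, l in enumerate(lags):
        d = pos[l:] - pos[:-l]
        fluct[i] = np.mean(np.sum(d * d, axis=1))
    return ScalingCurve(lags=lags, fluctuation=fluct, method="msd")


def dfa_curve(series: np.ndarray, detrend_order: int = 1,
              window_sizes: np.ndarray | None = None) -> ScalingCurve:
    """Detrended fluctuation analysis of a 1-D series.

    The profile is the cumulative sum of the mean-centred series.  For each
    window size ℓ the profile is cut into non-overlapping windows (scanned
    forward and backward so trailing samples are not discarded), each window
    is detrended by an order-``detrend_order`` least-squares polynomial, and
    F(ℓ) is the rms of all residuals.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < MIN_N_DFA:
        raise InsufficientDataError(f"dfa needs N >= {MIN_N_DFA}, got {n}")
    if detrend_order < 0:
        raise ValueError("detrend_order must be >= 0")
    if np.ptp(series) == 0.0:
        # constant input: the profile is identically zero; avoid reporting
        # rounding residue as fluctuation
        profile = np.zeros(n)
    else:
        profile = np.cumsum(series - series.mean())
    if window_sizes is None:
        window_sizes = log_lag_grid(n, min_lag=max(4, detrend_order + 2))
    fluct = np.empty(len(window_sizes))
    for i, ell in enumerate(window_sizes):
        fluct[i] = _dfa_fluctuation(profile, int(ell), detrend_order)
    return ScalingCurve(lags=window_sizes, fluctuation=fluct, method="dfa")


def _dfa_fluctuation(profile: np.ndarray, ell: int, order: int) -> float:
    """Mean-square residual over forward and reversed windowing, root-taken."""
    n = len(profile)
    k = n // ell
    # shared design matrix for all windows of this size
    tloc = np.arange(ell, dtype=float)
    vand = np.vander(tloc, order + 1, increasing=True)
    proj = vand @ np.linalg.pinv(vand)  # hat matrix, ell x ell
    ms = 0.0
    for seg in (profile[: k * ell], profile[-k * ell:][::-1]):
        w = seg.reshape(k, ell)
        resid = w - w @ proj.T
        ms += np.mean(resid * resid)
    return float(np.sqrt(ms / 2.0))


# ---------------------------------------------------------------------------
# fitting


def fit_powerlaw(curve: ScalingCurve,
                 fit_range: tuple[float, float] | None = None) -> ScalingFit:
    """OLS fit of log10 F against log10 lag; zero-F points are excluded.

    Raises :class:`FitError` when fewer than 5 positive points remain in the
    range (e.g. the degenerate flat-zero curve of a constant series).
    """
    lags = curve.lags
    fluct = curve.fluctuation
    if fit_range is not None:
        lo, hi = fit_range
        keep = (lags >= lo) & (lags <= hi)
        lags, fluct = lags[keep], fluct[keep]
    pos = fluct > 0
    lags, fluct = lags[pos], fluct[pos]
    if len(lags) < MIN_FIT_POINTS:
        raise FitError(
            f"power-law fit needs >= {MIN_FIT_POINTS} positive points, got {len(lags)}"
        )
    lx = np.log10(lags)
    ly = np.log10(fluct)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return ScalingFit(
        exponent=float(slope),
        intercept=float(intercept),
        fit_range=(float(lags[0]), float(lags[-1])),
        r_squared=r2,
        n_points=len(lags),
    )


def correlation_regime(curve: ScalingCurve, fit: ScalingFit, dt: float,
                       tol: float = CROSSOVER_TOL) -> tuple[int, float]:
    """Extent of the scaling (correlation) regime along a fitted curve.

    Returns ``(l_max, duration_minutes)`` where ``l_max`` is the largest lag
    such that every positive-F curve point up to it lies within ``tol`` log10
    units of the fitted line.  A curve whose first point already deviates
    yields a zero-length regime ``(0, 0.0)``.
    """
    keep = curve.fluctuation > 0
    lags = curve.lags[keep]
    dev = np.abs(
        np.log10(curve.fluctuation[keep])
        - (fit.exponent * np.log10(lags) + fit.intercept)
    )
    inside = dev <= tol
    if not inside[0]:
        return 0, 0.0
    bad = np.nonzero(~inside)[0]
    last = (bad[0] - 1) if len(bad) else (len(lags) - 1)
    l_max = int(lags[last])
    return l_max, l_max * dt / 60.0


def fit_scaling(series_or_traj, method: str, dt: float | None = None,
                detrend_order: int = 1) -> tuple[ScalingCurve, ScalingFit]:
    """Convenience: build the curve for ``method`` and fit it over the full range."""
    if method == "rmsf":
        curve = rmsf_curve(series_or_traj)
    elif method == "msd":
        curve = msd_curve(series_or_traj)
    elif method == "dfa":
        curve = dfa_curve(series_or_traj, detrend_order=detrend_order)
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    return curve, fit_powerlaw(curve)
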