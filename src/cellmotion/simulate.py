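"""Synthetic 2-D walkers emulating the four experimental migration scenarios.

The experimental setup records amoebae for 30 min at ~2 frames/s (3,600 frames
at dt = 0.5 s) in four scenarios: no stimulus, an electric field (cells steer
toward the cathode, placed at +x), a chemoattractant peptide gradient (peptide
at −x), and both stimuli at once.  The generator reproduces the *statistical*
structure those analyses assume — it makes no mechanistic claim about amoeboid
motility:

* ``brownian`` — iid Gaussian increments per axis (uncorrelated walker).
* ``fbm`` — fractional-Brownian-motion positions, i.e. fractional-Gaussian-noise
  increments with Hurst exponent H per axis; H > 0.5 gives the persistent,
  superdiffusive regime observed in real tracks (rmsf α ≈ H, DFA γ ≈ H+1,
  MSD β ≈ 2H).
* ``ballistic`` — constant velocity (MSD β = 2, directionality ratio 1).
* ``biased`` — Brownian noise plus a constant drift along a cue axis, standing
  in for galvanotactic/chemotactic steering.

fGn is generated by the exact stationary Davies–Harte circulant-embedding
method, with a jittered Cholesky fallback for the rare lengths at which the
circulant spectrum is not nonnegative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .tracks import Trajectory, TrajectorySet

#: Default sampling interval (s) and track length: 30-min tracks at 2 frames/s.
DEFAULT_DT = 0.5
DEFAULT_N_FRAMES = 3600

#: Default Hurst exponent of the persistent (fbm) walker, matching the
#: persistent regime recovered from real tracks (rmsf exponent ~0.7).
DEFAULT_HURST = 0.72

#: Drift magnitude of biased walkers, as a multiple of the per-axis step SD.
#: 2x makes directionality near-deterministic, as under a strong field.
DEFAULT_DRIFT_GAIN = 2.0

#: Cathode-ward/peptide-ward split observed under simultaneous opposing cues.
SC4_WEIGHTS = (0.42, 0.58)


class FGnFallbackWarning(UserWarning):
    """Circulant embedding was not positive semi-definite; Cholesky used instead."""


@dataclass(frozen=True)
class WalkerSpec:
    """Parameters of one synthetic walker.

    ``step_sd`` is the per-axis increment SD in mm/frame (diffusive kinds);
    ``speed`` is in mm/s (ballistic); ``drift_angle`` (rad, 0 = +x) and
    ``drift_gain`` (drift per frame = drift_gain * step_sd) apply to ``biased``.
    """

    kind: str  # ballistic | brownian | fbm | biased
    n_frames: int = DEFAULT_N_FRAMES
    dt: float = DEFAULT_DT
    step_sd: float = 0.002
    speed: float = 0.004
    hurst: float = DEFAULT_HURST
    drift_angle: float = 0.0
    drift_gain: float = DEFAULT_DRIFT_GAIN
    heading: float | None = None  # ballistic direction; None -> random
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ballistic", "brownian", "fbm", "biased"):
            raise ValueError(f"unknown walker kind {self.kind!r}")
        if self.n_frames < 16:
            raise ValueError("n_frames must be >= 16")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kind == "ballistic":
            if self.speed <= 0:
                raise ValueError("ballistic walker needs speed > 0")
        elif self.step_sd <= 0:
            raise ValueError("diffusive walker needs step_sd > 0")
        if self.kind == "fbm" and not (0.0 < self.hurst < 1.0):
            raise ValueError(f"hurst must lie in (0, 1), got {self.hurst}")


@dataclass(frozen=True)
class ScenarioSpec:
    """A mixture of walker kinds emulating one experimental scenario.

    ``weights`` are mixture proportions over ``components`` and must sum to 1.
    The cue axis convention is +x = cathode side, −x = peptide side.
    """

    scenario: str
    n_cells: int
    components: tuple[WalkerSpec, ...]
    weights: tuple[float, ...]
    species: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.components) != len(self.weights) or not self.components:
            raise ValueError("components and weights must be equal-length and nonempty")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {sum(self.weights)}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


# ---------------------------------------------------------------------------
# fractional Gaussian noise


def fgn_autocovariance(lags: np.ndarray, hurst: float) -> np.ndarray:
    """Autocovariance of unit-variance fGn: rho(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k ** h2 + np.abs(k - 1) ** h2)


def generate_fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact sample of unit-variance fractional Gaussian noise of length ``n``.

    Uses Davies–Harte circulant embedding; if the circulant eigenvalues are
    not all nonnegative at this ``n`` (possible for H near 1), falls back to a
    Cholesky factorization of the fGn covariance with diagonal jitter and
    warns.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    acov = fgn_autocovariance(np.arange(n), hurst)
    # circulant first row: c_0..c_{n-1}, c_n (=acov at lag n), c_{n-1}..c_1
    acov_n = fgn_autocovariance(np.array([n]), hurst)[0]
    row = np.concatenate([acov, [acov_n], acov[1:][::-1]])
    eig = np.fft.rfft(row).real
    if np.min(eig) < -1e-10 * np.max(eig):
        return _fgn_cholesky(n, hurst, rng)
    eig = np.clip(eig, 0.0, None)
    m = 2 * n
    # rfft of a real 2n-vector has n+1 bins; synthesize a Hermitian spectrum
    z = np.empty(n + 1, dtype=complex)
    z[0] = rng.standard_normal() * np.sqrt(m * eig[0])
    z[n] = rng.standard_normal() * np.sqrt(m * eig[n])
    re = rng.standard_normal(n - 1)
    im = rng.standard_normal(n - 1)
    z[1:n] = (re + 1j * im) * np.sqrt(m * eig[1:n] / 2.0)
    sample = np.fft.irfft(z, n=m)[:n]
    return sample


def _fgn_cholesky(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    warnings.warn(
        f"circulant embedding not PSD at n={n}, H={hurst}; using jittered Cholesky",
        FGnFallbackWarning,
        stacklevel=3,
    )
    idx = np.arange(n)
    cov = fgn_autocovariance(np.abs(idx[:, None] - idx[None, :]), hurst)
    jitter = 1e-12
    while True:
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter *= 10
            if jitter > 1e-3:
                raise
    return chol @ rng.standard_normal(n)


# ---------------------------------------------------------------------------
# walkers and scenarios


def generate_walker(spec: WalkerSpec, cell_id: str = "walker",
                    species: str = "synthetic", scenario: str = "synthetic") -> Trajectory:
    """Generate one trajectory from a :class:`WalkerSpec` (deterministic given seed)."""
    rng = np.random.default_rng(spec.seed)
    n_steps = spec.n_frames - 1
    if spec.kind == "ballistic":
        heading = rng.uniform(-np.pi, np.pi) if spec.heading is None else spec.heading
        step = spec.speed * spec.dt
        dx = np.full(n_steps, step * np.cos(heading))
        dy = np.full(n_steps, step * np.sin(heading))
    elif spec.kind == "brownian":
        dx = spec.step_sd * rng.standard_normal(n_steps)
        dy = spec.step_sd * rng.standard_normal(n_steps)
    elif spec.kind == "fbm":
        dx = spec.step_sd * generate_fgn(n_steps, spec.hurst, rng)
        dy = spec.step_sd * generate_fgn(n_steps, spec.hurst, rng)
    else:  # biased
        drift = spec.drift_gain * spec.step_sd
        dx = spec.step_sd * rng.standard_normal(n_steps) + drift * np.cos(spec.drift_angle)
        dy = spec.step_sd * rng.standard_normal(n_steps) + drift * np.sin(spec.drift_angle)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    t = spec.dt * np.arange(spec.n_frames)
    return Trajectory(cell_id=cell_id, species=species, scenario=scenario, t=t, x=x, y=y)


def scenario_spec(
    scenario: str,
    n_cells: int,
    n_frames: int = DEFAULT_N_FRAMES,
    dt: float = DEFAULT_DT,
    step_sd: float = 0.002,
    hurst: float = DEFAULT_HURST,
    drift_gain: float = DEFAULT_DRIFT_GAIN,
    species: str = "synthetic",
) -> ScenarioSpec:
    """Default mixture for one of the four experimental scenarios.

    Sc1: persistent (fbm) walkers, no drift — undirected migration.
    Sc2: drift toward the cathode (+x) — galvanotaxis.
    Sc3: drift toward the peptide (−x) — chemotaxis.
    Sc4: 42% cathode-ward / 58% peptide-ward mixture — opposing simultaneous cues.
    """
    base = dict(n_frames=n_frames, dt=dt, step_sd=step_sd, drift_gain=drift_gain)
    if scenario == "Sc1":
        comps = (WalkerSpec(kind="fbm", hurst=hurst, **base),)
        weights = (1.0,)
    elif scenario == "Sc2":
        comps = (WalkerSpec(kind="biased", drift_angle=0.0, **base),)
        weights = (1.0,)
    elif scenario == "Sc3":
        comps = (WalkerSpec(kind="biased", drift_angle=np.pi, **base),)
        weights = (1.0,)
    elif scenario == "Sc4":
        comps = (
            WalkerSpec(kind="biased", drift_angle=0.0, **base),
            WalkerSpec(kind="biased", drift_angle=np.pi, **base),
        )
        weights = SC4_WEIGHTS
    else:
        raise ValueError(f"unknown scenario {scenario!r} (expected Sc1..Sc4)")
    return ScenarioSpec(scenario=scenario, n_cells=n_cells, components=comps,
                        weights=weights, species=species)


def generate_scenario(spec: ScenarioSpec, seed: int = 0) -> TrajectorySet:
    """Draw ``n_cells`` walkers from the scenario mixture (deterministic given seed)."""
    rng = np.random.default_rng(seed)
    kinds = rng.choice(len(spec.components), size=spec.n_cells, p=np.asarray(spec.weights))
    child_seeds = rng.integers(0, 2**31 - 1, size=spec.n_cells)
    trajectories = []
    for i in range(spec.n_cells):
        comp = spec.components[kinds[i]]
        wspec = replace(comp, seed=int(child_seeds[i]))
        trajectories.append(
            generate_walker(
                wspec,
                cell_id=f"{spec.scenario}_cell{i:04d}",
                species=spec.species,
                scenario=spec.scenario,
            )
        )
    dt = spec.components[0].dt
    return TrajectorySet(
        trajectories,
        dt=dt,
        provenance=f"generated scenario {spec.scenario}, n={spec.n_cells}, seed={seed}",
    )


def shuffle_surrogate(series: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniform random permutation of a 1-D series (the temporal-order null).

    The multiset of values is preserved exactly; all temporal structure —
    autocorrelation, trends, persistence — is destroyed.
    """
    series = np.asarray(series)
    if series.ndim != 1 or len(series) < 2:
        raise ValueError("series must be 1-D with length >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return series[rng.permutation(len(series))]
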