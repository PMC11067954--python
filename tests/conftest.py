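import numpy as np
import pytest

from cellmotion import Trajectory
from cellmotion.simulate import WalkerSpec, generate_walker


def make_track(x, y, dt=0.5, cell_id="c1", species="test", scenario="synthetic"):
    x = np.asarray(x, dtype=float)
    t = dt * np.arange(len(x))
    return Trajectory(cell_id=cell_id, species=species, scenario=scenario,
                      t=t, x=x, y=np.asarray(y, dtype=float))


@pytest.fixture
def straight_track():
    """10 frames moving +0.1 mm/frame along +x."""
    n = 10
    return make_track(0.1 * np.arange(n), np.zeros(n))


@pytest.fixture
def brownian_track():
    return generate_walker(WalkerSpec(kind="brownian", n_frames=3600, seed=42))


@pytest.fixture
def fbm_track():
    return generate_walker(WalkerSpec(kind="fbm", hurst=0.75, n_frames=3600, seed=7))


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive implementations)


def dfa_bruteforce(series, window_sizes, order=1):
    """Explicit per-window polyfit DFA, forward+reversed windowing, no vectorization."""
    series = np.asarray(series, dtype=float)
    profile = np.cumsum(series - series.mean())
    out = []
    for ell in window_sizes:
        ell = int(ell)
        k = len(profile) // ell
        sq = []
        for seg in (profile[: k * ell], profile[-k * ell:][::-1]):
            for j in range(k):
                w = seg[j * ell: (j + 1) * ell]
                tloc = np.arange(ell, dtype=float)
                coef = np.polyfit(tloc, w, order)
                resid = w - np.polyval(coef, tloc)
                sq.append(np.mean(resid**2))
        fwd = np.mean(sq[:k])
        rev = np.mean(sq[k:])
        out.append(np.sqrt((fwd + rev) / 2.0))
    return np.array(out)


def apen_bruteforce(series, m, r):
    """Pincus ApEn by per-template counting: loop over templates, self-matches included."""
    series = np.asarray(series, dtype=float)
    n = len(series)

    def phi(mm):
        n_t = n - mm + 1
        logs = []
        for i in range(n_t):
            d = np.zeros(n_t)
            for k in range(mm):
                d = np.maximum(d, np.abs(series[i + k] - series[k: k + n_t]))
            logs.append(np.log(np.count_nonzero(d <= r) / n_t))
        return np.mean(logs)

    return phi(m) - phi(m + 1)


def silhouette_bruteforce(points, assignments):
    """O(n^2) per-point silhouette from the definition; singletons contribute 0."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    scores = np.zeros(n)
    labels = np.unique(assignments)
    for i in range(n):
        same = (assignments == assignments[i])
        n_same = same.sum()
        if n_same == 1:
            scores[i] = 0.0
            continue
        a = dist[i, same].sum() / (n_same - 1)
        b = min(dist[i, assignments == lab].mean() for lab in labels
                if lab != assignments[i])
        scores[i] = (b - a) / max(a, b)
    return scores.mean()
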