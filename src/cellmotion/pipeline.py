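"""End-to-end analysis: per-cell metrics with shuffle twins, group statistics,
clustering, and a machine-readable run report.

Shuffle-null policy
-------------------
The temporal-order null permutes a series uniformly and re-runs the estimator.
Which series is permuted depends on what the estimator consumes, so that every
null lands in its theoretical uncorrelated regime:

* rmsf — the *increment* series is permuted and re-integrated into a path;
  the resulting walk has iid increments, so α → 0.5.
* ApEn — the increment series is permuted directly (ApEn of iid noise ≈ 2
  at m = 2, r = 0.2 SD).
* MSD and DFA — the *position* series is permuted; permuted positions have a
  lag-independent displacement variance (β → 0) and an iid-valued profile
  increment (γ → 0.5).

Permuting positions for rmsf would drive α to 0 (not 0.5), and permuting
increments for MSD/DFA would leave β ≈ 1 and γ ≈ 1.5; only the assignment
above collapses all four statistics to their uncorrelated references
simultaneously.

Seed scheme: every stochastic stage consumes a child of one root
``numpy.random.SeedSequence``; cell i's shuffle generator is
``default_rng([root_seed, cell_index])``.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as cl
from . import stats as st
from .directionality import ZeroDisplacementError, displacement_cosine
from .entropy import apen, apen_profile
from .kinematics import kinematic_record
from .scaling import (FitError, correlation_regime, dfa_curve, fit_powerlaw,
                      msd_curve, rmsf_curve)
from .simulate import generate_scenario, scenario_spec, shuffle_surrogate
from .tracks import (InsufficientDataError, TrajectorySet, read_trajectories,
                     validate_uniform, write_trajectories)

#: Published full-scale reference medians for the 700-cell amoeba dataset
#: (deposit: https://doi.org/10.5281/zenodo.10974258), used only by
#: :func:`replicate_study` for side-by-side comparison tables.
REFERENCE_MEDIANS = {
    "alpha": 0.72,
    "beta": 1.87,
    "gamma": 1.78,
    "gamma_shuffled": 0.48,
    "apen_shuffled": 1.97,
    "cosine_sc2": 0.99,
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; all randomness flows from ``seed``."""

    input_path: str | None = None        # track table; None -> simulate scenarios
    scenarios: tuple[str, ...] = ("Sc1", "Sc2", "Sc3", "Sc4")
    n_cells_per_scenario: int = 50
    n_frames: int = 3600
    dt: float = 0.5
    hurst: float = 0.72
    step_sd: float = 0.002
    coordinates: tuple[str, ...] = ("x", "y")   # averaged per cell; ("x",) for x-only
    n_shuffles: int = 20
    apen_m: int = 2
    apen_r_frac: float = 0.2
    apen_window_step: float = 25.0
    apen_n_windows: int = 72
    apen_profile_enabled: bool = True
    cluster_ks: tuple[int, ...] = (3, 4)
    kmeans_n_init: int = 50
    seed: int = 0
    out_dir: str = "cellmotion_out"


# ---------------------------------------------------------------------------
# per-cell metrics


def _mean_over_coords(values: list[float]) -> float:
    finite = [v for v in values if np.isfinite(v)]
    return float(np.mean(finite)) if finite else float("nan")


def scaling_exponents(traj, coordinates=("x", "y")) -> dict:
    """rmsf α (with correlation regime), MSD β and DFA γ for one track.

    α and γ are computed per coordinate and averaged; β uses both coordinates
    at once.  The correlation-regime line is fitted over the initial half of
    the curve's log-lag range, then extended until the curve departs from it.
    """
    out: dict = {}
    alphas, gammas, r2a, r2g, corr_steps, corr_minutes = [], [], [], [], [], []
    for coord in coordinates:
        series = getattr(traj, coord)
        curve = rmsf_curve(series)
        try:
            fit = fit_powerlaw(curve)
            alphas.append(fit.exponent)
            r2a.append(fit.r_squared)
            lag_mid = float(np.sqrt(curve.lags[0] * curve.lags[-1]))
            initial = fit_powerlaw(curve, fit_range=(curve.lags[0], lag_mid))
            l_max, minutes = correlation_regime(curve, initial, traj.dt)
            corr_steps.append(l_max)
            corr_minutes.append(minutes)
        except FitError:
            pass
        dcurve = dfa_curve(series)
        try:
            gfit = fit_powerlaw(dcurve)
            gammas.append(gfit.exponent)
            r2g.append(gfit.r_squared)
        except FitError:
            pass
    out["alpha"] = _mean_over_coords(alphas)
    out["alpha_r2"] = _mean_over_coords(r2a)
    out["corr_steps"] = _mean_over_coords(corr_steps)
    out["corr_minutes"] = _mean_over_coords(corr_minutes)
    out["gamma"] = _mean_over_coords(gammas)
    out["gamma_r2"] = _mean_over_coords(r2g)
    mcurve = msd_curve(traj)
    try:
        mfit = fit_powerlaw(mcurve)
        out["beta"] = mfit.exponent
        out["beta_r2"] = mfit.r_squared
    except FitError:
        out["beta"] = float("nan")
        out["beta_r2"] = float("nan")
    return out


def shuffled_exponents(traj, rng: np.random.Generator, n_shuffles: int = 20,
                       coordinates=("x", "y"), apen_m: int = 2,
                       apen_r_frac: float = 0.2) -> dict:
    """Median-over-permutations shuffle twins of α, β, γ and ApEn for one track."""
    coords = {c: getattr(traj, c) for c in coordinates}
    incs = {c: np.diff(v) for c, v in coords.items()}
    alpha_s, beta_s, gamma_s, apen_s = [], [], [], []
    for _ in range(n_shuffles):
        a_per_coord, g_per_coord, e_per_coord = [], [], []
        pos_shuffled = {}
        for c in coordinates:
            inc_perm = shuffle_surrogate(incs[c], rng)
            path = np.concatenate([[coords[c][0]], coords[c][0] + np.cumsum(inc_perm)])
            try:
                a_per_coord.append(fit_powerlaw(rmsf_curve(path)).exponent)
            except FitError:
                pass
            pos_perm = shuffle_surrogate(coords[c], rng)
            pos_shuffled[c] = pos_perm
            try:
                g_per_coord.append(fit_powerlaw(dfa_curve(pos_perm)).exponent)
            except FitError:
                pass
            e_per_coord.append(apen(inc_perm, m=apen_m, r_frac=apen_r_frac))
        alpha_s.append(_mean_over_coords(a_per_coord))
        gamma_s.append(_mean_over_coords(g_per_coord))
        apen_s.append(_mean_over_coords(e_per_coord))
        pos2d = np.column_stack([pos_shuffled[c] for c in coordinates]) \
            if len(coordinates) == 2 else \
            np.column_stack([pos_shuffled[coordinates[0]], traj.y])
        try:
            beta_s.append(fit_powerlaw(msd_curve(pos2d)).exponent)
        except FitError:
            pass
    return {
        "alpha_shuffled": float(np.median(alpha_s)) if alpha_s else float("nan"),
        "beta_shuffled": float(np.median(beta_s)) if beta_s else float("nan"),
        "gamma_shuffled": float(np.median(gamma_s)) if gamma_s else float("nan"),
        "apen_shuffled": float(np.median(apen_s)) if apen_s else float("nan"),
    }


def compute_cell_metrics(traj, config: RunConfig, cell_index: int) -> tuple[dict, np.ndarray | None]:
    """All per-cell metrics (and the ApEn window profile, if enabled) for one track."""
    row: dict = {
        "cell_id": traj.cell_id,
        "species": traj.species,
        "scenario": traj.scenario,
        "n_frames": len(traj),
        "qc": "",
    }
    flags = []
    try:
        row["cosine"] = displacement_cosine(traj)
    except ZeroDisplacementError:
        row["cosine"] = float("nan")
        flags.append("zero_net_displacement")
    try:
        row.update(scaling_exponents(traj, config.coordinates))
    except InsufficientDataError:
        for k in ("alpha", "alpha_r2", "corr_steps", "corr_minutes",
                  "gamma", "gamma_r2", "beta", "beta_r2"):
            row[k] = float("nan")
        flags.append("too_short_for_scaling")

    profile_values = None
    if config.apen_profile_enabled:
        prof = apen_profile(traj, m=config.apen_m, r_frac=config.apen_r_frac,
                            window_step=config.apen_window_step,
                            n_windows=config.apen_n_windows)
        row["apen"] = prof.summary
        profile_values = prof.apen
    else:
        row["apen"] = apen(np.diff(traj.x), m=config.apen_m, r_frac=config.apen_r_frac)

    kin = kinematic_record(traj)
    row["ir"] = kin.ir
    row["dr"] = kin.dr
    row["as_speed"] = kin.as_speed
    if not np.isfinite(kin.dr):
        flags.append("zero_path_length")

    rng = np.random.default_rng([config.seed, cell_index])
    row.update(shuffled_exponents(traj, rng, n_shuffles=config.n_shuffles,
                                  coordinates=config.coordinates,
                                  apen_m=config.apen_m,
                                  apen_r_frac=config.apen_r_frac))
    row["qc"] = ";".join(flags)
    return row, profile_values


# ---------------------------------------------------------------------------
# full runs


def load_or_simulate(config: RunConfig) -> TrajectorySet:
    if config.input_path is not None:
        tset = read_trajectories(config.input_path)
        tset.trajectories = [validate_uniform(tr) for tr in tset]
        return tset
    rng = np.random.default_rng([config.seed, 0xC0FFEE])
    all_tracks = []
    for sc in config.scenarios:
        spec = scenario_spec(sc, config.n_cells_per_scenario,
                             n_frames=config.n_frames, dt=config.dt,
                             step_sd=config.step_sd, hurst=config.hurst)
        all_tracks.extend(generate_scenario(spec, seed=int(rng.integers(2**31 - 1))))
    return TrajectorySet(all_tracks, dt=config.dt,
                         provenance=f"simulated scenarios {config.scenarios}, seed={config.seed}")


def metrics_table(tset: TrajectorySet, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell metrics table and the cells x windows ApEn matrix."""
    rows, profiles, ids = [], [], []
    for i, traj in enumerate(tset):
        row, prof = compute_cell_metrics(traj, config, i)
        rows.append(row)
        if prof is not None:
            profiles.append(prof)
            ids.append(traj.cell_id)
    metrics = pd.DataFrame(rows)
    if profiles:
        apen_matrix = pd.DataFrame(
            np.vstack(profiles), index=pd.Index(ids, name="cell_id"),
            columns=[f"w{k + 1}" for k in range(len(profiles[0]))],
        )
    else:
        apen_matrix = pd.DataFrame()
    return metrics, apen_matrix


def group_tests(metrics: pd.DataFrame) -> pd.DataFrame:
    """Experimental-vs-shuffled rank-sum tests and between-group Kruskal–Wallis tests."""
    rows = []
    for metric in ("alpha", "beta", "gamma", "apen"):
        twin = f"{metric}_shuffled"
        if twin not in metrics.columns:
            continue
        a = metrics[metric].dropna()
        b = metrics[twin].dropna()
        if len(a) and len(b):
            res = st.rank_sum(a, b)
            rows.append({"comparison": f"{metric} experimental vs shuffled",
                         "test": res.method, "statistic": res.statistic,
                         "p_value": res.p_value, "n": res.group_sizes})
    for metric in ("cosine", "ir", "dr", "as_speed", "alpha", "beta", "gamma"):
        groups = [g[metric].dropna().to_numpy()
                  for _, g in metrics.groupby("scenario") if g[metric].notna().sum() > 0]
        if len(groups) >= 2 and sum(len(g) for g in groups) >= 5:
            res = st.kruskal_wallis(groups)
            rows.append({"comparison": f"{metric} across scenarios",
                         "test": res.method, "statistic": res.statistic,
                         "p_value": res.p_value, "n": res.group_sizes})
    return pd.DataFrame(rows)


def cluster_analyses(metrics: pd.DataFrame, config: RunConfig) -> dict:
    """k-means + hierarchical solutions on the kinematic (3-D) and dynamic
    (5-D, PCA-reduced to 3) feature sets, for each configured k."""
    results: dict = {}
    for fs in ("kinematic", "dynamic"):
        try:
            fm = cl.build_features(metrics, fs)
        except ValueError as exc:
            results[fs] = {"error": str(exc)}
            continue
        if fs == "dynamic":
            points, var_ratio = cl.pca_reduce(fm, n_components=min(3, fm.values.shape[1]))
            pca_info = {"variance_explained": var_ratio.tolist(),
                        "cumulative": float(var_ratio.sum())}
        else:
            points, pca_info = fm.values, None
        entry: dict = {"n_cells": len(points), "n_dropped": fm.n_dropped, "pca": pca_info,
                       "solutions": {}}
        for k in config.cluster_ks:
            if len(points) <= k:
                continue
            km = cl.kmeans_cluster(points, k, labels=fm.labels,
                                   n_init=config.kmeans_n_init, seed=config.seed)
            hc = cl.hierarchical_cluster(points, k, labels=fm.labels)
            entry["solutions"][k] = {"kmeans": km, "hierarchical": hc}
        results[fs] = entry
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write metrics.csv, apen_matrix.csv, tests.csv,
    clusters/ and report.json under ``config.out_dir``.  Deterministic given
    ``config.seed``."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tset = load_or_simulate(config)
    write_trajectories(tset, out / "tracks.csv")

    metrics, apen_matrix = metrics_table(tset, config)
    metrics.to_csv(out / "metrics.csv", index=False, float_format="%.8g")
    if not apen_matrix.empty:
        apen_matrix.to_csv(out / "apen_matrix.csv", float_format="%.6g")

    tests = group_tests(metrics)
    tests.to_csv(out / "tests.csv", index=False)

    clusters = cluster_analyses(metrics, config)
    cdir = out / "clusters"
    cdir.mkdir(exist_ok=True)
    cluster_report: dict = {}
    for fs, entry in clusters.items():
        if "error" in entry:
            cluster_report[fs] = entry
            continue
        cluster_report[fs] = {"n_cells": entry["n_cells"], "n_dropped": entry["n_dropped"],
                              "pca": entry["pca"], "solutions": {}}
        for k, sols in entry["solutions"].items():
            for name, sol in sols.items():
                stem = f"{fs}_k{k}_{name}"
                pd.DataFrame({"cell": range(1, len(sol.assignments) + 1),
                              "cluster": sol.assignments}).to_csv(
                    cdir / f"{stem}_assignments.csv", index=False)
                sol.composition.to_csv(cdir / f"{stem}_composition.csv")
                cluster_report[fs]["solutions"][f"{name}_k{k}"] = {
                    "silhouette": sol.silhouette,
                    "inertia": sol.inertia,
                }

    summaries = {}
    for metric in ("cosine", "alpha", "corr_minutes", "beta", "gamma", "apen",
                   "ir", "dr", "as_speed", "alpha_shuffled", "beta_shuffled",
                   "gamma_shuffled", "apen_shuffled"):
        vals = metrics[metric].dropna()
        if len(vals):
            summaries[metric] = st.summarize(vals)
            summaries[metric]["median_iqr"] = st.median_iqr_string(vals)

    report = {
        "config": asdict(config),
        "provenance": tset.provenance,
        "n_cells_in": len(tset),
        "n_metric_rows": len(metrics),
        "n_qc_flagged": int((metrics["qc"] != "").sum()),
        "summaries": summaries,
        "tests": tests.to_dict(orient="records"),
        "clusters": cluster_report,
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def replicate_study(deposit_dir: str, config: RunConfig | None = None) -> pd.DataFrame:
    """Recompute headline medians from a local copy of the deposited track data
    and print them next to the published full-scale values.

    ``deposit_dir`` must contain one or more track tables in the package's
    tabular format (columns cell_id, [species], [scenario], t, x, y).  The
    deposit is never downloaded; an unrecognized layout raises ``ValueError``
    with inspection hints.
    """
    config = config or RunConfig()
    root = Path(deposit_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"deposit directory not found: {deposit_dir}")
    tables = sorted(root.glob("**/*.csv")) + sorted(root.glob("**/*.tsv"))
    if not tables:
        raise ValueError(
            f"no .csv/.tsv track tables under {deposit_dir}; expected tables with "
            "columns cell_id, t, x, y (plus optional species, scenario)"
        )
    tracks = []
    for tab in tables:
        tset = read_trajectories(tab, delimiter="\t" if tab.suffix == ".tsv" else ",")
        tracks.extend(validate_uniform(tr) for tr in tset)
    allset = TrajectorySet(tracks, dt=tracks[0].dt, provenance=f"deposit {deposit_dir}")
    metrics, _ = metrics_table(allset, config)

    recomputed = {
        "alpha": metrics["alpha"].median(),
        "beta": metrics["beta"].median(),
        "gamma": metrics["gamma"].median(),
        "gamma_shuffled": metrics["gamma_shuffled"].median(),
        "apen_shuffled": metrics["apen_shuffled"].median(),
    }
    sc2 = metrics.loc[metrics["scenario"] == "Sc2", "cosine"]
    recomputed["cosine_sc2"] = sc2.median() if len(sc2) else float("nan")

    rows = []
    for key, ref in REFERENCE_MEDIANS.items():
        rec = float(recomputed.get(key, float("nan")))
        rows.append({"metric": key, "recomputed": rec, "published": ref,
                     "abs_difference": abs(rec - ref)})
    return pd.DataFrame(rows)
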