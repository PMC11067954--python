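# cellmotion

Quantitative analysis of 2-D cell-migration trajectories, built for studies of
directed locomotion in free-moving cells (amoebae under galvanotactic and/or
chemotactic stimulation) but applicable to any tabulated single-cell track
data sampled at a fixed frame interval.

Given tracks `r(t) = (x(t), y(t))` (mm, sampled every `dt` seconds), the
package computes, per cell:

* **Directionality** — the displacement cosine
  `cos θ = (x_N − x_1) / |r_N − r_1|` of the net displacement against the
  stimulus axis (+x = cathode side, −x = peptide side), and 8-sector polar
  histograms of net-displacement angles.
* **Long-range correlation (rmsf)** — the root-mean-square fluctuation of a
  position coordinate, `F(l) = SD_t[s(t+l) − s(t)] ~ l^α`; α ≈ 0.5 for
  uncorrelated steps, α > 0.5 for persistent long-range interdependence,
  plus the duration of the correlation regime in move steps and minutes.
* **Anomalous diffusion (MSD)** — time-averaged mean square displacement
  `⟨|r(t+τ) − r(t)|²⟩_t ~ τ^β`; β = 1 normal diffusion, 1 < β < 2
  superdiffusion, β = 2 ballistic.
* **Persistence (DFA)** — detrended fluctuation analysis of a position
  coordinate, `F(ℓ) ~ ℓ^γ`; γ ≈ 0.5 no memory, 1.5 < γ < 2 trend-reinforcing
  persistence.
* **Complexity (ApEn)** — approximate entropy of the move-step increments,
  `ApEn(m, r) = Φ_m(r) − Φ_{m+1}(r)`, over 72 growing 25-s windows; ordered
  motion scores near 0, shuffled steps near 2.
* **Kinematics** — intensity of response (|net displacement|, mm),
  directionality ratio (net displacement / path length ∈ [0, 1]), and average
  speed (path length / duration, mm/s).

Every statistic has a **shuffle-surrogate twin** (random permutation of the
series feeding the estimator), giving per-cell nulls that collapse to
α ≈ 0.5, γ ≈ 0.5, β ≈ 0 and ApEn ≈ 2. Group comparisons use Wilcoxon
rank-sum (with Z) and Kruskal–Wallis tests; motility phenotypes are explored
with z-scored feature matrices, PCA, k-means and hierarchical clustering with
silhouette scoring.

A synthetic-walker generator (Brownian, fractional-Brownian with tunable
Hurst exponent via exact Davies–Harte circulant embedding, ballistic, and
drift-biased walkers, plus four scenario mixtures emulating no-stimulus,
galvanotaxis, chemotaxis and opposed simultaneous cues) makes the whole
pipeline runnable with no data download.

## Worked example

```python
from cellmotion import (RunConfig, run_pipeline)

report = run_pipeline(RunConfig(
    scenarios=("Sc1",), n_cells_per_scenario=12, n_frames=1200,
    n_shuffles=5, apen_n_windows=10, cluster_ks=(2,), seed=11,
    out_dir="demo_out"))
for name in ("alpha", "gamma", "beta", "gamma_shuffled"):
    print(name, report["summaries"][name]["median_iqr"])
print(report["tests"][2]["comparison"], "p =", report["tests"][2]["p_value"])
```

prints (seed 11):

```
alpha 0.63/0.05
gamma 1.71/0.03
beta 1.43/0.09
gamma_shuffled 0.51/0.02
gamma experimental vs shuffled p = 3.6584553538971e-05
```

The 12 simulated no-stimulus cells are persistent walkers (Hurst H = 0.72):
their rmsf exponent α ≈ 0.63 and DFA exponent γ ≈ 1.71 sit in the
long-range-correlated, trend-reinforcing regime (γ ≈ α + 1), the MSD
exponent β ≈ 1.44 ≈ 2H indicates superdiffusion, and shuffling the tracks
collapses γ to ≈ 0.5 — the separation is already highly significant at 12
cells. `demo_out/` contains `metrics.csv` (one row per cell with all metrics
and shuffle twins), `apen_matrix.csv` (cells × windows), `tests.csv`,
`clusters/` and `report.json`.

The same pipeline runs from a shell:

```bash
cellmotion simulate --scenario Sc4 --n-cells 200 --hurst 0.75 --seed 7 --out tracks.csv
cellmotion analyze --input tracks.csv --out-dir out --seed 7
cellmotion report --report-json out/report.json
```

For replication against the deposited experimental dataset
(https://doi.org/10.5281/zenodo.10974258, downloaded manually), point
`cellmotion replicate --deposit-dir <dir>` at track tables in the package's
tabular format to get recomputed-vs-published medians side by side.

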