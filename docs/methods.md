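# Methods

## Data model and units

A trajectory is a time-ordered `(t, x, y)` track for one cell, coordinates in
mm and time in s, with uniform frame spacing `dt`. The default sampling is
`dt = 0.5 s` with 3,600 frames per track (30 min at 2 frames/s), consistent
with correlation regimes reported in move steps and minutes jointly
(≈1,125 steps ≈ 9.4 min implies ≈2 steps/s). Tracks read from tables are
validated (finite coordinates, strictly increasing time) and, if their
spacing is non-uniform beyond a relative tolerance of 1e-6, linearly
resampled onto a uniform grid with endpoints preserved. Zero-length move
steps are kept in the step-length series with value 0, but the turning angle
at those indices is marked undefined rather than assigned an arbitrary
direction, and such entries are excluded from angle statistics.

## Synthetic walkers

The generator emulates the statistical structure the estimators assume; it
is a test substrate, not a mechanistic model of amoeboid motility (no
cytoskeletal or run-and-tumble dynamics, no cell–cell interaction, no
measurement noise or digitization error of real centroid tracking).

* `brownian`: iid Gaussian increments per axis (`step_sd`, default 0.002
  mm/frame, giving average speeds of ~0.005 mm/s, the order observed in
  migrating amoebae).
* `fbm`: fractional-Gaussian-noise increments per axis with Hurst exponent
  H, generated by Davies–Harte circulant embedding. The method is exact and
  O(N log N); if the circulant spectrum is not nonnegative at the requested
  length (possible for H near 1), the generator falls back to a jittered
  Cholesky factorization of the fGn covariance and warns. Default H = 0.72,
  matching the persistent regime recovered from real tracks (rmsf α ≈ 0.72).
* `ballistic`: constant velocity (default 0.004 mm/s), random heading unless
  fixed.
* `biased`: Brownian plus constant drift along a cue angle; the drift per
  frame defaults to 2 × `step_sd`, which makes directionality
  near-deterministic, as under a strong electric field.

Scenario mixtures: Sc1 = persistent walkers without drift (no stimulus);
Sc2 = drift toward +x (cathode, galvanotaxis); Sc3 = drift toward −x
(peptide, chemotaxis); Sc4 = 42% +x / 58% −x mixture (opposed simultaneous
cues, the split observed experimentally). All randomness is explicit: walker
specs carry seeds, scenario generation spawns per-cell seeds from one
generator, and the pipeline derives each cell's shuffle generator as
`default_rng([root_seed, cell_index])`.

## Estimators

**rmsf.** For one position coordinate, `F(l)` is the standard deviation over
all overlapping time origins of the l-lag displacement. Centring removes
pure drift exactly (a linear ramp gives F ≡ 0). The overlapping, centred
form is used; lags are log-spaced, ~25 points per decade, from 1 to N/4
(capping at N/4 bounds estimator variance at large lags). For fBm input
α = H; for iid-increment walks α ≈ 0.5. Note a small finite-size bias: the
centring at lags near N/4 absorbs part of the variance, so the full-range
fitted null sits at ≈0.47 rather than 0.50 at N = 3,600 — the same value the
full-scale shuffled data reproduce.

**MSD.** Time-averaged over overlapping origins, both coordinates, same lag
grid. Ballistic tracks give β = 2 to machine precision; Brownian walks
β ≈ 1; fBm β ≈ 2H.

**DFA.** The profile is the cumulative sum of the mean-centred series.
Windows are non-overlapping, scanned forward and reversed (so trailing
samples are used), detrended per window by a least-squares polynomial
(order 1 by default), and F(ℓ) is the rms residual over both scans; window
sizes are log-spaced from max(4, order+2) to N/4. With position input DFA of
fBm yields γ = H + 1; iid series yield γ ≈ 0.5. A constant series produces
an identically zero profile and the fit is rejected rather than reported as
exponent 0 (rounding residue from centring is clamped to zero).

**Power-law fits.** Ordinary least squares of log10 F on log10 lag over the
full grid by default; points with F = 0 are excluded; fewer than 5 positive
points is a fit error. Slopes are base-invariant; R² is reported.

**Correlation regime.** The regime line is fitted over the initial half of
the curve's log-lag range (lags up to the geometric midpoint); the regime
extends to the largest lag such that every curve point up to it stays within
0.05 log10 units of that line. The duration in minutes is `l_max · dt / 60`.
The 0.05 tolerance is a package choice — no standard rule exists for
delimiting a scaling regime — and is configurable.

**Per-cell exponents.** α and γ are computed on each of x and y and
averaged (an x-only mode is available); β uses both coordinates at once.
This assignment is the only one that lands all three shuffle nulls in their
theoretical regimes simultaneously (see below).

**ApEn.** Pincus approximate entropy with self-matches included (hence
ApEn ≥ 0), embedding m = 2 and tolerance r = 0.2 × SD — the field-standard
defaults. The analysed series is the increment (move-step) series of one
coordinate: increments are quasi-stationary, which ApEn assumes, while raw
positions of a migrating cell are not. The growing-window profile uses 72
cumulative windows anchored at t = 0 whose endpoint grows by 25 s, with r
resolved per window from that window's SD; windows too short to embed are
flagged undefined, and the per-cell scalar is the median of defined entries.
The implementation counts Chebyshev-ball matches in vectorized blocks and is
checked against a naive per-template counting oracle to 1e-12.

## Shuffle nulls

The surrogate is a uniform random permutation — the value distribution is
kept, all temporal order destroyed. Which series is permuted depends on the
estimator, so that each null lands in its theoretical uncorrelated regime:

| estimator | permuted series | null regime |
|---|---|---|
| rmsf | increments, re-integrated into a path | α → 0.5 |
| ApEn | increments | ApEn → ≈2 |
| MSD | positions | β → 0 |
| DFA | positions | γ → 0.5 |

Permuting positions for rmsf would give a lag-independent displacement
variance (α → 0, not 0.5), and permuting increments for MSD/DFA would leave
an iid-increment walk (β ≈ 1, γ ≈ 1.5); only the assignment above collapses
all four statistics at once. Twenty permutations per cell (median reported)
is the pipeline default; scaled-down runs in the examples and test suite use
2–5 permutations, which is sufficient because the experimental/null
separation on persistent walkers is complete, not marginal.

## Statistics

Rank-sum: midranks for ties, tie-corrected variance, continuity correction
(on by default, switchable), two-sided p, and Z signed positive when the
first sample tends larger. For pooled n ≤ 12 without ties the p-value is
computed by full enumeration of rank assignments. Kruskal–Wallis uses the
tie-corrected H with a χ² reference (k−1 df); all-identical data return the
degenerate H = 0, p = 1 rather than an error. Quantiles use linear
interpolation (type 7), so IQRs recomputed from published tables may differ
in the second decimal. No multiple-testing correction is applied.

## Clustering

Features are z-scored before any distance computation because the metric
sets mix units (mm, mm/s, dimensionless exponents); rows with undefined
metrics are dropped with a logged count, and constant columns are an error.
The kinematic set is (IR, DR, AS); the dynamic set is (α, correlation time
in minutes, γ, β, ApEn summary), reduced to its first three principal
components before clustering (per-component and cumulative explained
variance reported). k-means is Lloyd's algorithm with k-means++ seeding,
best of 50 restarts, deterministic given the seed; hierarchical clustering
is agglomerative with ward (default), average or complete linkage. Default
k ∈ {3, 4} (a species-count and a scenario-count question); silhouette is
the mean of (b−a)/max(a,b) with singletons contributing 0 (all-singleton
partitions score 0 by the same convention). Clustering operates on per-cell
vectors; aggregate first if replication-level analysis is wanted.

## Problem sizes and numerical choices

Simulation-backed checks use medians over 20–100 walkers of 3,600 frames,
which keeps every estimator's sampling error well inside the asserted
tolerances (e.g. the rmsf/DFA/MSD null medians are stable to ±0.01 over 100
walks). The acceptance summary regenerates its inputs at that same scale.
Exact oracles (DFA brute-force windowing, ApEn template counting,
silhouette pairwise distances, rank-sum enumeration) are compared at
1e-10–1e-12. fGn exactness is verified against the closed-form lag-1
autocovariance ρ(1) = 2^(2H−1) − 1 using the uncentered estimator (the
process mean is 0 by construction; centring would bias a long-memory
autocovariance estimate low).

## Known limitations

* The walkers are statistical stand-ins; passing tests show the estimators
  recover planted structure, not that real cells are fBm.
* rmsf/DFA exponents carry the usual finite-size biases of scaling
  estimators; no per-cell confidence intervals are provided.
* ApEn values depend on (m, r, N); comparisons are meaningful only at fixed
  parameters, which the profile and metrics tables record.
* Multifractal DFA, maximum-likelihood Hurst estimation, sample/permutation
  entropy and gap statistics are out of scope.
* 3-D trajectories, video processing and track linking are out of scope;
  input is digitized 2-D tracks.
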