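# Methods

## The model

`phaseflow` treats the gut (or any quasi-batch, flow-through ecosystem) as a
collection of bacterial populations each growing on its own internal logistic
curve, with stool sampling reading each population at some point along — or
past — that curve.  The deterministic logistic growth equation (LGE)

    dx/dt = r x (1 − x/K),      x(0) = x0,

has the closed-form solution x(t) = x0 K e^{rt} / ((K − x0) + x0 e^{rt}),
which the package evaluates as K / (1 + ((K − x0)/x0) e^{−rt}) so that no
growing exponential is ever formed (no overflow at large rt).  The first
derivative r x (1 − x/K) is the effective growth rate; the second
derivative, the growth acceleration, is

    d²x/dt² = r² x (1 − x/K)(1 − 2x/K).

The acceleration curve has one positive peak (at abundance K(3 − √3)/6) and
one negative trough (at K(3 + √3)/6) and crosses zero at K/2.  Growth phases
are delimited by the times s1 < s2 < s3 < s4 where the acceleration crosses
half its maximum (s1, s2) and half its minimum (s3, s4):

| phase                | window      |
|----------------------|-------------|
| acceleration (+ lag) | t < s2      |
| mid-log              | s2 ≤ t < s3 |
| deceleration         | s3 ≤ t < s4 |
| stationary           | t ≥ s4      |

Windows are half-open with ties assigned to the later phase; this is a
measure-zero choice that makes phase assignment a deterministic, total
function.  The crossing abundances are r-independent, so s_j scales as 1/r
at fixed K; and because any positive prefactor of the acceleration scales
the half levels with the curve, the boundary times are invariant to the
prefactor (r², or any other constant).  Boundaries are computed by bracketed
Brent root-finding on the dimensionless shape u(1−u)(1−2u) (u = x/K), with
brackets at the analytic extrema, then mapped to times through the
closed-form inverse of the logistic curve; converged crossings satisfy
|a(s_j) − level| < 1e−10·a_peak.  Curves starting at x0 ≥ K/2 are rejected
by boundary construction (the observable curve starts past the acceleration
peak); the solution itself also supports x0 > K (decay toward K).

## Stochastic simulation

The stochastic variant (sLGE) adds multiplicative noise,
dx = r x (1 − x/K) dt + σ x dW (Itô), integrated by Euler–Maruyama:

    x_{j+1} = x_j + [r x_j (1 − x_j/K) − H x_j] dt + σ x_j √dt Z_j.

Defaults: dt = 0.01 (config knob; the deterministic step is refused when
r·dt > 0.5), span t0 = 1 to t_final = 100 with the initial condition imposed
at t0, 100 iterations per ensemble, paths clamped at a floor of 1e−12
(absorbing at effective zero — at the default σ and x0 = 1 the clamp is
essentially never active).  First-order step convergence is verified by
halving dt.  Each iteration draws from an independent seeded substream, so
ensembles are bit-reproducible and enlarging n_iter never reshuffles
existing paths.

H is a harvest (dilution/defecation) rate; its nonzero stable equilibrium
is K(1 − H/r) for H < r and extinction otherwise, and noise-free
simulations settle onto it to within 0.1%.

A second variant puts the noise on the carrying capacity instead: each step
uses an effective k_j = K + σK√dt Z_j (independent per step — white-noise
increments, floored at 1e−6·K) inside an otherwise deterministic logistic
update.  Fluctuating k preserves the sigmoidal shape and the phase-wise
sign structure below; note the per-step amplitude scales with √dt, the
Wiener-increment convention.

Within each phase window, the simulation-side growth proxy is the forward
difference x(t_{j+1}) − x(t_j) on the integration grid.  Per iteration, the
Pearson correlation between abundance and delta inside a window is the
phase signature: positive in acceleration (abundance and growth rate rise
together below K/2), negative in deceleration (growth falls as abundance
climbs past the inflection), near zero in mid-log (the rate peaks inside
the window), and negative for stationary *deltas* (regression to the mean
around K).  Correlations are computed per iteration and summarized by the
median (pooling across iterations is available as an option); windows with
fewer than 3 grid points yield a missing value, not an error.  At high
noise (σ ≈ 1) these signatures can be destroyed; the test suite asserts
signs only where the model predicts them robustly (acceleration and
deceleration at σ = 0.1).

## The statistical pipeline

Counts are centered log-ratio (CLR) transformed per sample — ln(count +
pseudocount) minus the sample mean of the same — with a default pseudocount
of 0.5 applied to every count (configurable; the denominator is all taxa in
the sample, with any abundance filtering applied after transformation).
Day-to-day deltas x(t+1) − x(t) are computed only for consecutive samples
collected strictly less than 3 days apart; wider gaps are dropped, never
interpolated.  Per taxon, CLR abundance is regressed on log2(PTR) (ordinary
least squares; Pearson r reported alongside), requiring strictly more than
5 matched days.  p-values are Benjamini–Hochberg adjusted within each donor
(the FDR family is the donor's eligible taxa).  Donor-level p-values from
the across-taxon regression of mean CLR on mean log2(PTR) are combined with
Fisher's method (−2 Σ ln p ~ χ² with 2k df).  Stationarity of a series is
screened with the augmented Dickey–Fuller test (automatic AIC lag order);
since the ADF null is a unit root, p < 0.1 flags the series as stationary.
A cohort-level, taxonomy-adjusted association is available as OLS of
log2(PTR) on CLR plus group (class- or species-level) indicator terms —
note this orientation is reversed relative to the per-taxon regressions;
Pearson-based sign conclusions are orientation-free.

## Phase classification

For each eligible taxon (more than 5 matched days), in order:

1. mean log2(PTR) < 0.358 → **stationary**;
2. q < 0.05 and slope > 0 → **acceleration**;
3. q < 0.05 and slope < 0 → **deceleration**;
4. otherwise → **midlog_or_indeterminate**.

The 0.358 cutoff is the empirical mean log2(PTR) of stationary-phase
E. coli in vitro, deliberately kept as a configurable constant rather than
hard-coded logic; 0.05 is the FDR level.  The stationary threshold is
applied before the slope test; a below-threshold taxon with a significant
slope keeps the stationary label and is flagged
(`significant_slope_below_stationary_threshold`).  The null outcome is
labeled `midlog_or_indeterminate`, not "mid-log", because a non-significant
slope may simply be an underpowered acceleration/deceleration call.
Ineligible taxa are carried through with phase `ineligible`.

## The synthetic-data generator

The generator emulates a dense stool time series: 60 collection days drawn
3–5 per week (so the < 3-day delta gate sees both passing and failing
gaps), 12 taxa (3 per phase) on logistic curves with r ∈ {1.0, 1.6, 2.2},
K = 100, x0 = 1 and sLGE noise σ = 0.1, sequencing depths log-spaced from
3×10⁴ to 3×10⁵ expected reads at carrying capacity.  Each stool day runs an
independent sLGE iteration of the taxon's curve, read out at a time drawn
uniformly from the taxon's true-phase window; counts are Poisson around
mean_depth · x/K and form a composition across taxa.

log2(PTR) is generated as b0 + b1·g + ε, where g = (dx/dt)/(rK/4) ∈ [0, 1]
is the normalized effective growth rate of the *deterministic* curve at the
sampled time and ε ~ N(0, 0.06²).  Two design choices matter here:

- **Absolute, deterministic rate.** Replication-rate proxies track the
  population's position along its growth program.  Mapping PTR to the
  noise-realized instantaneous rate would mechanically anti-correlate PTR
  with abundance at steady state (regression to the mean), forcing every
  stationary taxon to look like deceleration — the opposite of the null
  stationary PTR–abundance association observed in vitro.  The per-capita
  rate r(1 − x/K) would be even worse: it decreases monotonically in
  abundance, giving a negative coupling in *every* phase.
- **Calibration.** b0 = 0.30 is the zero-growth replication baseline (the
  bottom of the observed in vitro log2(PTR) range); b1 is solved per taxon
  so the mid-log-window mean equals the in vitro mid-log anchor 1.25.
  Stationary taxa are sampled one full growth-transient width past s4,
  where the deterministic rate is ≈ 0, so their mean log2(PTR) lands at
  ≈ 0.30–0.31 — below the 0.358 classification threshold, as deeply
  stationary populations should be.  (The in vitro stationary-window *mean*
  of 0.358 includes early-stationary residual replication; a generator that
  pinned simulated stationary taxa exactly at the decision threshold would
  make their truth labels unrecoverable by construction.)

What the generator does *not* emulate: compositional interactions between
taxa beyond the shared sequencing depth, PTR estimation failure modes
(missingness, genome-size effects, values below 1), multi-day ecological
perturbations, or any coupling between taxa.  Passing the recovery tests
therefore shows that the classifier recovers phases *when the generative
assumptions hold*, not that real donors satisfy those assumptions.  The in
vivo PTR noise magnitude is unknown; ptr_noise_sd is a free parameter of
the generator (default 0.06, the in vitro stationary spread), and recovery
degrades monotonically as it grows.

## Numerical and interface choices

- Time is measured in the curve's own units; collection days are 0-based
  integers since the first sample, supplied by metadata.
- File dialects: TSV for counts, metadata and phase calls; CSV for PTR
  tables (blank = missing, negative values allowed with a logged warning);
  UTF-8, '.' decimal.  Round-trip identity is tested for every writer.
- Degenerate inputs yield typed missing-result markers (None / NaN), not
  exceptions, wherever a batch must carry them: too few points, zero
  variance, empty delta lists, sub-3-point correlation windows.
- Ensembles, the generator and the CLI are fully determined by their seeds.

## Known limitations

- Forward simulation only: no inference of (r, K, σ) from trajectories.
- No alternative growth laws (Gompertz, Baranyi) and no multi-species
  coupling (Lotka–Volterra); autoregressive time-series models are
  deliberately out of scope — the sampling-rate mismatch they assume away
  is the package's starting premise.
- PTR magnitudes are treated as roughly comparable across taxa; no
  genome-size or C-period normalization is attempted.
- Euler–Maruyama is first-order; dt is configurable and convergence is
  checked, but no higher-order scheme is provided.
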