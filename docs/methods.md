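# Methods

This note documents the models, statistics, numerical choices, and known
limitations of `popcoupling`.

## Population coupling

For unit *i* with spike counts `f_i(t)` in `T` equal bins of width `Δ`
(default 0.25 s; 0.1/0.05/0.01 s exposed as robustness variants), total
spike count `N_i`, and per-unit mean counts `μ_j`,

    C_pop,i = (1/N_i) · Σ_t f_i(t) · P_i(t),
    P_i(t)  = Σ_{j≠i} (f_j(t) − μ_j).

`C_pop` is dimensionless, unbounded, typically positive, and negative for
units anticorrelated with the rest of the population.  Binning uses
half-open bins `[t, t+Δ)`; a trailing partial bin is discarded so all bins
have equal duration.  The evaluation is vectorised; the test suite checks
it against a literal double-loop implementation at 1e-10 relative
tolerance.  `C_pop` is undefined (error) for units with zero spikes and
for populations of fewer than two units.

Splits (first vs. second half; rest vs. motion, where a bin is "motion"
when its mean body speed exceeds the whole-session mean) recompute `N_i`
and `μ_j` within each partition.  A unit silent within a partition gets
NaN there, with a log entry, rather than aborting the analysis; the
spec-level precondition of ten bins per partition is deliberately not
enforced so degenerate masks degrade gracefully.

## Exclusion rules

Units with whole-session rate below 0.5 Hz are removed first; if fewer
than 5 units survive, the session is flagged excluded.  The rate is
computed over the whole session (total spikes / duration) — the simplest
reading of a rate threshold — and exclusion is idempotent.

## Kinematics

Bead positions (8 beads, 100 Hz, mm) are low-pass filtered with a
4th-order Butterworth at 5 Hz applied forward–backward (zero phase; only
the cutoff is externally prescribed, the order/topology is this package's
choice) and differentiated by central differences at the native rate.
Central differences avoid a half-sample phase shift and are exact for the
band that survives the 5 Hz filter.

The 27 movement aspects are:

1. centre-of-mass (COM) speed, with the COM the equal-weight bead mean;
2. turning angular speed: the azimuth (vs. the lab +x axis, an arbitrary
   but fixed reference — only angular *speed* is used downstream, which is
   reference-invariant) of the horizontal projection of the body vector,
   unwrapped then differentiated;
3. rearing angular speed: elevation of the body vector, differentiated;
4–27. per-bead velocity relative to the COM, projected on body-frame axes
   (rostrocaudal = horizontal heading; right–left = horizontal
   perpendicular; up–down = lab vertical), bead-major order.

The body vector is the principal axis of the three points {COM, head bead,
neck-base bead} (eigenvector of their 3×3 scatter matrix), oriented so the
head has positive projection.  Frames with a numerically vertical body
vector have no horizontal heading; heading-dependent aspects are NaN there
and counted in `degenerate_frames`.  Whether "relative to the body vector"
should subtract COM velocity before projecting is not externally
prescribed; subtraction is implemented because it makes aspects 4–27
invariant to adding a constant velocity to all beads, which is the
behaviour a posture/curvature signal should have.

## Body coupling

All triggered waveforms live on lags −1…+1 s at 10 ms (201 points) and are
low-pass filtered at 1.5 Hz (4th-order Butterworth, zero phase).  Windows
that would extend past the session edges are dropped, not padded.

* **Movement events**: threshold = whole-session mean speed; upward
  crossings are onsets, downward cessations.  Raw mean-crossings chatter
  on realistic speed noise, so a crossing must be preceded by ≥100 ms on
  the old side and followed by ≥100 ms on the new side (dwell), same-type
  events within 0.5 s of the previous kept one are suppressed, and events
  within 1 s of the session edges are dropped.  Only the crossing rule is
  externally prescribed; the debounce constants are this package's choice,
  sized well below the bout durations they must preserve.
* **BC_M**: per-lag spike rate around events (counts across triggers
  divided by `n_triggers × 10 ms`), filtered, normalized by the waveform
  mean; BC_M = (SD_onset + SD_cessation)/2.  A waveform with zero mean
  (unit silent around all events) contributes 0 with a degenerate flag.
* **BC_S**: mean body speed around spikes, filtered, mean-normalized;
  BC_S = waveform SD.  Mean normalization makes BC_M invariant to uniform
  rate rescaling and BC_S invariant to speed rescaling (both tested).
* **BC_D**: for each of the 27 aspects, the spike-triggered average is
  z-scored per lag against surrogate waveforms (default 100) from
  circularly shifted spike trains, *filtered identically to the real
  waveform* before z-scoring (identical processing avoids filter-induced
  bias; whether to filter the surrogates is not externally prescribed).
  The per-aspect score is the SD across lags of the z-waveform; BC_D is
  the maximum score and `best_aspect_index` its argmax.  Lags where the
  surrogate SD is zero get z = 0 and a log entry.  No per-unit
  significance criterion is attached to BC_D.

Surrogates circularly shift all spike times by a uniform offset in
[30 s, duration − 30 s] modulo the duration: spike count and circular ISI
structure are preserved exactly while alignment to behaviour is destroyed.
Significance of BC_M/BC_S is `value > 95th percentile` of (default) 1000
surrogate values, strict inequality, so ties are conservative.  Under the
null this flags ≈5% of units (calibrated in the acceptance tests at 200
surrogates).

## Peak inference

Candidates for the peak location `x*` are the observed x values excluding
the 10 smallest and 10 largest points ("at least 10" is implemented as
exactly 10 — the minimal reading); points exactly tied with a candidate
belong to neither flank.  For each candidate, `ρ_left` / `ρ_right` are
Spearman correlations (average ranks for ties) over the strict flanks; a
candidate is valid when `ρ_left > 0` and `ρ_right < 0`; its peakiness is
`P = min(ρ_left, −ρ_right)`; the maximizing candidate is reported, and
`P = 0` with undefined `x*` when no candidate is valid.  `P` is invariant
to strictly monotone transforms of either axis.

The permutation test shuffles y against fixed x (the two directions are
equivalent) and reports the add-one estimate
`p = (1 + #{P_shuffle ≥ P_obs}) / (1 + n_shuffles)`.  Ties are counted:
`P` has an atom at 0 (datasets with no valid candidate), and only the
tie-inclusive count keeps the estimator exactly super-uniform under the
null — with a strict inequality, null datasets landing on the atom would
receive p-values capped below 1.  For continuous `P` the two conventions
coincide.

Per-session consistency fits `y = a2·x² + a1·x + a0` by least squares
(sessions with ≥5 units only).  Criterion 1: `a2 < 0` and the fit maximum
within 10% of the *pooled x-range* from the pooled `x*` (the normalizing
quantity for "within 10%" is not externally prescribed; the pooled range
is the only scale-free choice available for an unbounded coupling axis).
Criterion 2: when more than half of the session's x-span lies on one side
of the pooled peak, the fit's mean slope over that side of the session
range (the chord slope of the quadratic) must point toward the peak.  The
count of consistent sessions is tested by globally shuffling y across all
units and sessions, recomputing the pooled peak and every fit.

Median normalization divides each session's x and y by their session
medians (sessions with |median| < 1e-9 are dropped and logged), and the
moving summary reports median/Q1/Q3 of y over fixed-count windows sliding
along sorted x.

## Network model

N = 1000 binary neurons update synchronously from an all-silent initial
state:

    p_i(t) = σ([η + Σ_j W_ij s_j(t−1)] · r_i(t)),
    r_i(t) = (1 + χ + α · Σ_{τ=t−T_r}^{t−1} s_i(τ))^-1,

with σ clipping to [0,1], α = 0.1, T_r = 100 steps, default run length
50,000 steps.  The adaptation sum runs over available history during
warm-up.  `1 + χ` must be positive (|χ| ≤ 0.2 in the standard sweeps);
since the history sum is non-negative, this keeps the denominator positive
everywhere.

W (input to *i* from *j*) is built in four steps: i.i.d. lognormal draws
with *variate* mean 0.5 and variance 1 (underlying-normal parameters by
moment matching: σ² = ln(1 + v/m²), μ = ln m − σ²/2); a uniformly random
20% of columns negated; per-row in-degrees drawn lognormally (mean 20,
variance 500), rounded and clipped to [1, N−1], with retained inputs
chosen uniformly (E/I composition of each neuron's inputs is not
preserved under pruning — uniform pruning is the simplest choice); and
global division by the spectral radius (largest eigenvalue modulus over
the generally complex spectrum, via sparse Arnoldi iteration with a dense
fallback).  The diagonal is zero: no self-coupling.

Model population coupling mimics the experimental estimate: counts in
50-step bins, neurons partitioned into 50 disjoint random subsets of 20,
each neuron's coupling computed within its subset.  Sweeps (`fig3c`: η =
8e-4, χ ∈ {±0.2, ±0.1, 0}; `fig3d`: χ = 0, η ∈ {2,4,8,16,32}e-4; `fig3e`:
the three (η, χ) pairs) average over ≥3 seeds, each seed drawing its own
W.  Mean and variance of coupling fall monotonically as χ or η rises, and
rates rise as χ falls — the directions the model exists to demonstrate.
The acceptance tests run these sweeps at 20,000 steps with 3 seeds, which
is ample for the directional effects (they are monotone already at a
fraction of that length); the default `n_steps` remains 50,000.

## Synthetic sessions

The generator emulates a 30-minute recording of a freely moving rat.
Behaviour: alternating exponential rest (mean 5 s) and movement (mean 3 s)
bouts; body speed = smoothed bout indicator × 50 mm/s plus low-pass noise;
heading oscillates at 0.4 Hz during movement (driving the turning aspect);
eight beads ride a rigid body frame (head high and forward, tail low and
back) with 1 mm low-pass posture jitter.  Units are inhomogeneous Poisson:

    λ_i(t) = r_i · max(0, 1 + a_i·L(t) + s_i·b_i·u(t − latency_i)),

with base rates lognormal (median 2 Hz, shape 0.7, clipped at 0.5 Hz), a
shared unit-variance latent L (low-pass Gaussian, 300 ms timescale)
carrying the population-coupling gains `a_i`, and `u` the z-scored
movement signal (mean body speed, or turning angular speed for
rotation-tuned units) carrying the body-coupling gain magnitudes `b_i`
with per-unit response polarities `s_i ∈ {−1,+1}`.  Random polarities
reflect the in-vivo observation that movement both raises and lowers
firing across units; they also keep movement-locked firing from
dominating pairwise count covariance, so measured `C_pop` tracks the
planted `a_i` — the separability the generator exists to provide.  Gains
default to `a ~ U(0, 2)` and `b ~ U(0, 1)`: with the latent variance fixed
at 1, the a-range carries the dynamic range of population coupling, and
its upper end reflects units whose shared fluctuations are comparable to
their mean rate.  Spikes are drawn by exact thinning: homogeneous Poisson
candidates at the intensity maximum, accepted with probability
λ(t)/λ_max, with λ evaluated by linear interpolation of the 100 Hz signal
grid.  The rectification `max(0, ·)` guarantees a valid intensity but
distorts the effective gain of units with large negative modulations.

`generate_peaked_population` plants a peaked ground truth: per session,
`b_i = exp(−(a_i − a0)²/(2·0.35²)) + N(0, 0.15)` clipped to [0, 1.5], with
`a0` at the middle of the a-range and per-session median-rate jitter
×U(0.5, 2) to exercise median normalization.  The 15% noise SD keeps the
planted relation clearly peaked while leaving realistic scatter.

What the generator does **not** emulate: spike-sorting artefacts,
non-stationary drift, camera dropouts, heterogeneous per-unit movement
tuning curves (the movement drive is rank-one per signal, so all
movement-coupled units share one waveform shape up to sign and scale), or
drug-condition effect sizes.  One consequence worth knowing: because the
movement drive is a single shared signal, rest-vs-motion splits of
population coupling are only guaranteed to agree strongly for stationary
configurations (movement gains zero); with strong movement gains the
rank-one drive plus rectification makes the split state-dependent in a
way real data (with its diverse tuning) is not.  Passing tests therefore
demonstrate correctness of the estimators under known structure, not that
real recordings satisfy these statistical assumptions.

## Problem sizes and determinism

Every random step consumes an explicit `numpy` Generator; a single seed
fans out deterministically through generation, surrogates, shuffles, and
model runs, and identical seeds reproduce outputs bit-for-bit (tested).
The test suite sizes its simulations for tight feedback: null
calibrations use 200 shuffles / 200 surrogates (the add-one p-value floor
is then 1/201), the end-to-end recovery study uses 20 cohorts of 5 × 40
units, and the model sweeps 20,000 steps × 3 seeds.  Full-cost defaults
(1000 surrogates/shuffles, 50,000 steps) remain the package defaults and
are what the CLI uses without `--fast`.
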