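# Methods

This note documents the models behind the synthetic-data generators, the
analysis conventions, the numerically delicate choices, and what the
validation suite does and does not demonstrate.

## Recording model

All electrophysiology lives in a single `Sweep` container (time in seconds,
current in pA with inward negative, stimulus in µm or mmHg, acquisition
metadata).  Reports use ms for latencies and time constants and positive
magnitudes for amplitudes, matching the conventions of the field's figures.
Traces are filtered with a 4-pole Bessel-type low-pass applied forward only
(2.9 kHz by default), magnitude-normalised so −3 dB sits at the cutoff and
initialised at steady state so the DC level is conserved exactly.  The
filter's step-response delay is characterized numerically
(`characterize_filter_delay`), at the 50% crossing for reporting and at the
0.1% departure level for onset correction — the detection bound is a small
fraction of the eventual current step, so the relevant delay is the
departure delay, not the half-rise.

## Poking (whole-cell) generator

A ramp-and-hold displacement (13 steps × 0.4 µm, 1 µm/ms, 200 kHz sampling,
50 ms pre-stimulus, 150 ms hold by default) drives a phenomenological
current model chosen to be the simplest shape with exact ground truth:

* zero below the mechanical threshold displacement;
* above it, `i_max · B(d(t)) · V(v)` during the ramp, with a Boltzmann
  displacement-response `B(A) = 1/(1 + exp(−(A − A½)/k))` (defaults
  A½ = 3.2 µm, k = 0.4 µm, i_max = −1140 pA, so the 5.2-µm step evokes
  ≈ −1.13 nA) and a Hill velocity factor `V(v) = v^h/(v^h + v½^h)`
  normalised to 1 at 1 µm/ms (defaults h = 1, v½ = 1 give
  V(0.25) = 0.40, i.e. currents ~60% smaller at quarter speed);
* single-exponential decay with τ_inact (default 6 ms) from the end of the
  ramp;
* plus leak (−20 pA) and Gaussian noise (10 pA SD), then the Bessel filter.

The Boltzmann/Hill forms are this package's choice: they are smooth,
saturating, and match the qualitative shapes of measured
displacement-response and velocity-response curves; no specific functional
form is claimed by the assays themselves.

## Pressure-clamp (single-channel) generator

Each channel is an independent two-state continuous-time Markov chain
simulated exactly (Gillespie).  The closing rate is 1/mean_open_dwell
(default 2 ms) and the opening rate is set so the stationary open
probability follows a Boltzmann of pressure,
`P_open(p) = 1/(1 + exp((p − p½)/s))` (defaults p½ = −40 mmHg,
s = 8 mmHg; suction increases P_open).  Open channels add the Ohmic
unitary current `i = g (V_hold − E_rev)/1000` pA (default g = 23.4 pS,
E_rev = 0).  Outside the pressure step channels gate at `P_open(0)`, which
is small but non-zero — resting openings are real, and tests whose oracles
assume a quiescent baseline use parameters that make `P_open(0)`
negligible.  Every open interval in the stimulus window is booked in the
sweep metadata (event count, total open time, dwell times, implied charge),
providing the oracles for charge-transfer and dwell-statistics tests.

## Whole-cell analysis conventions

* **Baseline** = the pre-stimulus segment minus its first 5 ms; leak
  subtraction removes the baseline mean and records it.
* **Onset rule**: first sample at/after stimulus onset with
  I < mean − k·SD (k = 6).  A noise-free trace has SD exactly 0 and no
  SD-relative bound; callers analysing noiseless synthetic sweeps pass an
  explicit `sd_floor`.  Latency is corrected by the departure delay and the
  threshold is clamped at the ramp amplitude when onset falls in the hold.
* **Inactivation fit**: t0 is fixed at the peak, making C1/C2 identifiable;
  initial values come from the tail mean and a 1/e crossing; a flat segment
  raises a "no decay component" error rather than returning a spurious τ.
* **Velocity series**: stability CV = sd/mean of the last three
  reference-velocity amplitudes, exclusion at CV > 0.2 (sample SD); the
  ratio is mean-of-test over mean-of-reference.
* **Reversal potential**: linear interpolation between the sign-change
  pair; extrapolation from the OLS line is flagged.

## Pressure-clamp analysis conventions

* **Charge transfer**: trapezoidal |∫I dt| over the stimulus window on the
  leak-subtracted trace, reported in pC (sign kept alongside).
* **Amplitude histogram**: bin width max(0.1 pA, 2·noise_sd/5); a
  two-component Gaussian mixture (tied variance — both levels see the same
  recording noise) initialised from the two largest separated histogram
  modes, closed level = mean nearer 0 pA.  Samples on the filter-smeared
  opening/closing edges (local slope above 3× the median, dilated by twice
  the characterized group delay) are excluded before fitting: edge samples
  pull the level means together, while the Bessel filter's slight step
  overshoot pushes them apart; both bias the unitary current at the 0.1%
  level, and removing the settling window eliminates the bias at its
  source.  A fit that collapses to one effective component (weight < 2% or
  separation below 2·SD/√n) raises "no resolvable openings".
* **Responder criterion** (a stand-in; no published definition exists):
  threshold = 5 × SD of the *signed* charge over stimulus-free segments of
  stimulus duration.  The magnitude of a zero-mean integral is
  half-normal, whose SD understates the spread by ~40%; using it would
  turn 5×SD into an effective 3σ bound with an ~11% false-positive rate
  over four pressure steps, whereas the signed-charge SD keeps measured
  specificity at 0–2.5% false positives.
* **Patch QC**: excluded when |leak| > 4 pA (strict) or |baseline drift| >
  2 pA/s (the drift bound is this package's configurable choice).
* No stretch "peak current" is computed anywhere: non-inactivating
  responses make it ill-defined, so charge is the only stimulus-response
  quantity.

## TIRF generator and analysis

Movies are 16-bit stacks (default 10 Hz, 0.11 µm pixels) of 2D-Gaussian
spots (σ = 0.15 µm) on constant background with Gaussian photon noise.
Trajectories follow four regimes: Brownian (MSD = 4Dτ), fractional
Brownian motion with Hurst α/2 (MSD = 4Dτ^α, generated from a Cholesky
factor of the fBm covariance), Brownian reflected in a disc (confined),
and Brownian plus constant drift in a random direction (directed).

Detection is a difference-of-Gaussians matched to a 0.7-µm blob with
sub-pixel parabolic refinement; quality is the DoG response normalised by a
robust (MAD) noise estimate — third-party detector quality units are not
reproducible, so the threshold is configuration with a calibration helper
built on blank frames.  Linking solves the optimal assignment per adjacent
frame pair (squared displacement, 0.5 µm cap) — a simplification of a
global linear-assignment tracker that is exact at the simulated densities —
followed by gap closing (0.7 µm, ≤ 2 frames) and a 40-frame minimum
duration.  MSD is time-averaged over all overlapping pairs per lag up to a
quarter of the duration.

Classification replaces a trained random-forest approach with a transparent
threshold rule validated on synthetic motion models: α = log-log MSD slope
over the first 5 lags; directed if α ≥ 1.5 or straightness ≥ 0.6; confined
if α < 0.3 or confinement ratio < 0.3; subdiffusion if 0.3 ≤ α < 0.85; else
normal diffusion.  The confinement ratio compares the MSD at the 10th lag
with the Brownian extrapolation from the first lag, so it is ≈1 for free
diffusion, ≈`L^(α−1)` for anomalous power laws, and ≪ 1 when the MSD
saturates; the 10th lag keeps the estimate inside the well-averaged part of
the curve.  The validation panel uses well-separated parameters
(D = 0.05 µm²/s; α = 0.7; corral 0.15 µm with D = 0.1; drift 1 µm/s with
D = 0.005) — with a 0.7 subdiffusion exponent and a corral smaller than the
per-frame diffusion step the four classes are geometrically distinct, and
per-class accuracy is ≥ 85–90%.  Accuracy necessarily degrades as
parameters approach class boundaries; the panel demonstrates the rule's
correctness, not a universal detection limit.

Cluster diameter = 2 × the mean fitted standard deviation of a 2D Gaussian
(least squares, non-convergence flagged); density = first-frame spot count
over a caller-supplied cell area.

## Statistics

`fisher_exact_2x2` sums hypergeometric point probabilities over all
margin-preserving tables whose probability does not exceed the observed one
(sum-of-small-p, the convention of mainstream statistics packages), with
near-ties within a relative 1e-7 counted as ties.  The comparison runs in
exact integer arithmetic on binomial coefficients, so tie handling never
depends on floating-point rounding; the suite verifies exact agreement with
a brute-force enumeration for every table with n ≤ 30.  Percent summaries
round half away from zero.  Group comparisons are gated per group by the
D'Agostino–Pearson test at α = 0.05 (groups below 8 observations cannot be
screened and route to the nonparametric branch); Dunn's post test reports
raw two-sided z-test p-values with tie correction and no multiplicity
adjustment unless the caller applies one — the appropriate adjustment is a
reporting convention, not a property of the statistic.

## Synthetic cells

Per-group tables draw a Bernoulli responder flag, a Bernoulli
neurite-bearing flag, 1 + Poisson additional neurites on bearing cells, and
log-normal longest-neurite lengths.  Defaults (responder p = 0.2, bearing
p = 0.5, log-normal µ = 2.5, σ = 0.6 → mean ≈ 14.6 µm, Poisson λ = 1)
sit in the range of measured responder fractions and neurite lengths.

## What the tests show — and what they do not

The generators reproduce the statistical structure the analyses assume:
exponentially decaying currents with stationary Gaussian noise, two-state
gating with pressure-dependent occupancy, Gaussian spots on uniform
background, exchangeable cells within groups.  Real recordings add
capacitive transients, access-resistance drift, multi-conductance
sublevels, photobleaching (a bleach-correction hook is the natural
extension point; none is simulated), uneven illumination and spot merging.
Passing recovery tests therefore demonstrates correctness of the
quantification chain under its stated model, not robustness to every
artifact of real data — the QC rules (leak > 4 pA, baseline drift,
stability CV, track-duration filter) are the designed defence for those.

## Problem sizes

Validation uses: τ ∈ {2, 5, 10, 20} ms × 200 replicates at 5% noise;
thresholds {0.8, 1.6, 2.4, 3.2} µm noiseless; g ∈ {15, 25, 35, 45} pS × 20
replicates through the full pipeline (50 for the bias check); 200 Brownian
tracks of 100 frames; 4 × 100-track motility panels; 1000-replicate
false-positive runs for the onset rule.  Replicate-heavy loops use a
compact protocol (20 ms baseline, 120 ms hold, full 200 kHz sampling) and
1-s pressure steps; these sizes give recovery errors an order of magnitude
below the acceptance tolerances, so larger runs would not change any
conclusion.
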