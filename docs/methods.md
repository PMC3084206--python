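# Methods

This note documents the models implemented in `luxpulse`, the default
parameter values and why they were chosen, what the synthetic data do and
do not emulate, and the numerical choices that matter for reproducing the
package's outputs.  Units are hours, OD units of biomass, mg/ml of
substrate, and arbitrary activity/RLU units throughout; only shapes,
ratios, timings and phases of luminescence curves are meaningful, as on a
real luminometer.

## 1. Growth model

Batch growth on a ranked mixture of substrates:

    dX/dt  = ( Σ_i g_i · μmax_i · S_i/(K_i + S_i) ) · X
    dS_i/dt = − μ_i X / Y_i

`g_i` implements catabolite repression with an induction lag: the most
preferred substrate present has `g = 1`; a less-preferred substrate is
gated by `g_i = clip(E_i, 0, 1)` with

    dE_i/dt = k_ind · [all more-preferred substrates exhausted] − k_dec · E_i .

"Exhausted" is a steep smooth indicator (Hill exponent 4, half-point
0.002 mg/ml) so the right-hand side stays integrator-friendly while the
switch is sharp.  The lag gives the diauxic pause its finite width; with
`k_ind` in the 5–20 /h range pauses last roughly 5–20 min.  `MediumSpec`
defaults to `k_ind = 20 /h`; the bundled scenarios use 5 /h, which makes
the pauses as wide as those seen on real growth curves.  An optional
first-order `lysis_rate` (default 0) lets biomass decline slowly once all
substrates are gone, producing the slightly negative stationary-phase
growth rates seen in practice; it is off in the bundled scenarios so that
the mass-balance identity

    X(t) − X(0) = Σ_i Y_i (S_i(0) − S_i(t))

holds exactly (checked to 1e-6 on every simulation; the integrator runs
at rtol 1e-8, atol 1e-10, LSODA).

The bundled `dsm` scenario represents a sporulation medium as four ranked
nutrient pools.  Exhaustion of pools a and b causes the two growth-phase
pauses (≈1.6 and 2.7 h), pool c the pause at entry to stationary phase
(≈3.8 h), and the small slow pool d ends growth at T0 ≈ 4.5 h, with the
run continuing to 8 h.  Pool sizes and Monod constants (K_s = 0.1 mg/ml)
were chosen to give evenly spaced pauses with smooth declines into them;
nothing else depends on their particular values.

## 2. Polymerase allocation and promoter classes

The passive-regulation mechanism is a single algebraic allocation: the
fraction of RNA polymerase committed to rRNA synthesis grows with growth
rate,

    f_rrn(μ) = f_max · μ/(μ + K_μ),     R_free = R_total · (1 − f_rrn),

with defaults `f_max = 0.95`, `K_μ = 0.6 /h`, `R_total = 1` in the bundled
scenarios.  `f_max` near 1 expresses that at top speed almost the whole
pool is committed (which is what gives growth pauses their large effect);
`K_μ` sets the curvature of the μ→allocation map — 0.6 /h keeps the map
roughly linear over the observed μ range, so that promoter activity is
close to an affine function of growth rate and the pause/burst
anti-correlation is strong and symmetric.

Promoter classes respond to the state algebraically:

- constitutive:  a = strength · R_free/(R_free + K_R).  With K_R = 2 ≫
  R_free the response is nearly linear in the free pool and the ratio of
  activity at μ = 0 to activity at μmax is ≈3.4, which sets the burst
  amplitude.
- rRNA-like:  a = strength · f_rrn — rises and falls with growth rate.
- repressed / activated:  the constitutive form times a repressive Hill
  factor in Spo0A~P, or an activating Hill function of Spo0A~P.
- initiating nucleotide:  a promoter whose transcript starts with G is
  multiplied by g(1 + K_iNTP)/(g + K_iNTP), where g ∈ [0, 1] is the GTP
  pool level (factor normalized to 1 at a full pool).  The GTP pool is not
  modeled mechanistically: a scenario prescribes dips directly
  (`gtp_dip_schedule`); the bundled scenario dips only during the first
  pause, so only a G-initiating variant has its first burst blunted.

The stationary-phase activation of the spo0A-like promoter (promoter
switching to the sporulation sigma factor, positive feedback) is complex
circuitry that the package deliberately does not model mechanistically;
it is scripted as signed additive activity steps (`stationary_program`).
The bundled program makes two waves after T0 plus a sustained final rise,
calibrated so the growth-phase peaks reach ~55% of the final maximum
(within the half-to-three-quarters range characteristic of these
experiments).

## 3. Spo0A~P cascade and downstream responses

    dP/dt  = A_spo0A(t) − γ_P · P
    dSp/dt = k_phos · κ(t) · P − k_deph · Sp

with κ a kinase-availability profile (constant 1 by default).  Defaults
γ_P = 3 /h, k_phos = 6 /h, k_deph = 4 /h make the cascade fast enough
(time constants 10–20 min) that each growth-phase transcription burst is
followed, with a lag of ~15–20 min, by a pulse of Spo0A~P — slower
kinetics would integrate the bursts away.  The driver promoter must not
itself be Spo0A-regulated (enforced), keeping the cascade acyclic; the
known autoregulation of the master regulator is therefore out of scope.

Targets use Hill factors with an affinity hierarchy
K_abrB (0.06) < K_comK (0.12) < K_spoIIG (0.28): the high-affinity
repressed target dips during the growth-phase pulses, the low-affinity
activated target turns on only near stationary phase.  These K values are
on the package's arbitrary Spo0A~P scale and were set relative to the
pulse (~0.11) and stationary (~0.30) levels of the bundled scenario.

Rare transitions to competence are modeled as a per-cell
inhomogeneous-Poisson first event with hazard

    λ(t) = λ0 · (A_comK(t)/K_c)^m ,

a threshold-proximity law: raising the average cell's comK expression
multiplies the transition probability.  Defaults λ0 = 0.001 /h, m = 3,
K_c = 0.5 give transitioned fractions of ~1e-5 % before the first burst
and ~0.15% after the second in the bundled scenario — the observed order
of magnitude for this bet-hedging transition.  Sampling inverts the
trapezoid-integrated cumulative hazard at uniform draws, so it is exact
for the gridded hazard and deterministic per seed.

## 4. Reporter and measurement layer

Per cell, `dl/dt = A(t) − δ·l` with δ = ln 2/t½ and t½ = 0.1 h (6 min);
emitted light is L = c·l·X with an arbitrary instrument coefficient c
(1e5 by default, giving RLU magnitudes in the 1e4–1e5 range typical of
plate luminometers).  The linear reporter, protein and phosphoform ODEs
are integrated with an exact exponential update for piecewise-linear
input, so constant-input closed forms are reproduced to machine
precision.  An optional fixed maturation delay shifts the activity input;
it defaults to 0.

Note the model has no growth-dilution term in `l`: with δ ≈ 6.9 /h ≫ μ ≤
1.4 /h, degradation dominates dilution, and the deconvolution formula
below is exact for this model.  Against data from a reporter that is also
diluted, A_dec carries a relative bias of order μ/δ (≤20% at top growth
rate, zero during pauses), which shifts baselines but not event timing.

Measurement: OD = od_background + X and RLU = L are sampled every 0.025 h
(1.5 min), each reading multiplied by independent log-normal noise with
CV = 2% (mean-preserving).  Multiplicative noise is the right first-order
model for plate readers, whose error is scale-proportional; the additive
OD background represents medium absorbance and is removed by blank wells.
The generator does not emulate: well-to-well growth heterogeneity, edge
effects, luciferin depletion late in long runs, condensation artifacts,
or signal cross-talk between wells.  Passing tests therefore demonstrate
correctness of the inference given this noise model, not robustness to
every artifact of real plates.

Translation arrest (`simulate_arrest`) zeroes all promoter activities and
freezes biomass from the arrest time; whether biomass truly freezes after
puromycin is not established, so this is a documented simplification (the
light decay, which is what the half-life fit uses, is unaffected by
modest OD drift because the fit is on RLU alone).

## 5. Estimators

Smoothing/differentiation is a Savitzky–Golay filter: default window 11
points (≈16.5 min) and degree 2.  The window is the main judgment call:
wide enough to suppress 2% noise in a derivative, narrow enough to keep
20–30 min bursts; it is exposed everywhere as a parameter.  Endpoints are
handled by polynomial fits to the terminal window (one-sided), which have
inflated variance — the pipeline therefore excludes half a window (5
samples) at each end of derivative-based series from event analysis.
Noiseless ground-truth comparisons in the tests use window 5, where the
only error is smoothing bias at the sharp pause bottoms.

Growth rate is μ̂ = d ln OD/dt (invariant to OD rescaling; negative values
are preserved as a lysis diagnostic).  Activity estimators:

- naive: A = RLU/OD (steady state c·a/δ for constant per-cell activity a);
- deconvolved: A = (dRLU/dt + δ·RLU)/OD, which recovers the simulator's
  input activity (×c) with <5% relative RMSE away from activity
  discontinuities.  Negative excursions are reported, not clipped: a
  systematically negative stretch indicates a misspecified δ.

Half-life fitting is OLS of ln RLU on time over a window defaulting to
(t_arrest + one sample, t_arrest + 0.5 h), with non-positive readings
dropped (warning) and a no-decay error if the slope is non-negative.

## 6. Event analysis

- **T0** — first time μ̂ falls below 10% of its 90th percentile and stays
  below for ≥20 consecutive samples (both configurable).  The published
  practice is to place T0 by eye; this rule reproduces it to within ~0.25 h
  on noiseless data and errs late under noise (excursions above the
  threshold postpone the qualifying run), which only widens the analysis
  window.
- **Pauses** — local minima of μ̂ with depth ≥0.2 relative to the lower of
  the two flanking maxima (scipy peak prominence on −μ̂, which is exactly
  that flank), width ≥0.1 h at half depth, and a flank floor of 25% of the
  window's 90th-percentile rate.  The floor encodes that a pause must
  interrupt genuine growth; without it, noise wiggles on the near-zero
  stationary rate (where *relative* depth is meaningless) would qualify.
  The prominence floor also merges noise sub-minima inside one dip.
- **Bursts** — local maxima with prominence ≥15% of the series' global
  *range* (max − min), which makes detection invariant to affine
  rescaling of the arbitrary RLU units (a max-normalized criterion would
  not be offset-invariant); peaks closer than 0.15 h are merged, keeping
  the higher, to avoid double-counting shouldered stationary waves.
- **Pairing** — greedy nearest-time matching within 0.3 h.
- **Phase** — both series are detrended by a quadratic over the window;
  the dominant period is the first positive-lag autocorrelation peak of
  μ̂ (error if its value is <0.2: no oscillation); the lag is taken at the
  cross-correlation extremum of larger magnitude, and a *minimum* at lag
  L means antiphase at L, so the phase is 180° + 360°·|L|/period (mod
  360).  Using the signed extremum rather than only the positive peak
  makes the estimator robust to waveform asymmetry: quasi-periodic
  growth curves decline slowly and recover fast, which skews the positive
  cross-correlation peak away from half a period, while the anti-alignment
  at small lag remains sharp.  This estimator is designed for 2–3
  oscillations, where spectral methods are unreliable.

## 7. Frequencies

Rare-event frequencies use exact Clopper–Pearson intervals because the
relevant counts include 0 and 1 positives; the zero-positive case returns
the one-sided exact upper bound (≈3/n).  Sporulation frequency is
100·spores/viable with a warning (not an error) when spores exceed the
viable count, since count inversions occur in real tables.  Fold changes
are reported unrounded.

## 8. Problem sizes and determinism

The bundled runs simulate 8 h at 1.5-min sampling (321 points), 2
replicate wells plus 2 blanks, and 20,000 cells for the transition
sampler; the whole pipeline completes in a few seconds on one CPU, and
these sizes are ample for every statistic reported.  All stochastic
stages draw from `numpy.random.default_rng` seeded from a single run
seed (the renderer uses the seed itself, the transition sampler seed+1),
so identical configuration and seed reproduce every output byte for
byte.

## 9. Known limitations

- No mechanistic stringent-response, CodY, phosphorelay or sigma-factor
  circuitry: mutant phenotypes can only be represented as parameter
  variants of the scenario (e.g. removing the GTP dip, flattening the
  stationary program), not predicted.
- The Spo0A~P scale is arbitrary; target affinities are meaningful only
  relative to it.
- Single-cell behavior is limited to the transition hazard; there is no
  intrinsic-noise model of comK expression.
- The deconvolution assumes a known, constant δ and no maturation delay;
  both are scenario parameters, not estimated jointly.
- Phase estimates assume a reasonably stable period across the window;
  strongly drifting pause spacing degrades the period estimate before it
  degrades the sign of the relationship.
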