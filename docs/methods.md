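# Methods

## Filter models

Adaptive mechanisms are modeled as first-order high-pass stages
`H(s) = g (τs + 1)/(τs + A)` with `A ≥ 1` (DC gain `g/A`, high-frequency
gain `g`), membrane integration as low-pass stages `k/(τs + 1)`.  Stages
compose multiplicatively in frequency — mechanisms are assumed in
series, with no feedback coupling between stages at this level of
description.  All public interfaces take frequencies in Hz; `ω = 2πf` is
applied internally.

Two specializations carry their mechanistic parameters explicitly:

- SFA: `H(s) = γ(τs + 1)/(τs + 1 + cF)`, from the linear system
  `y = γx − ca`, `τ da/dt = −a + Fy`.
- STD (linearized): `H(s) = γ/(1 + x₀F) · (τs + 1)/(τs + 1 + x₀F)`,
  valid for small fluctuations around the mean presynaptic rate `x₀`;
  the steady-state depression is `a₀ = 1/(1 + x₀F)`.

`cascade_magnitude_sq` evaluates the closed-form `|H|²` of the
SFA → STD → low-pass chain.  Its prefactor uses the squared low-pass
gain `k²`, so the closed form agrees identically with the product of the
individually evaluated stages (the two evaluation routes are
cross-checked to 1e-10 in the tests); with the reference value `k = 1`
used throughout the examples the distinction vanishes.

The steady-state output power of `n` depressing timescales with shared
`F` is `x₀ γ^(2n)/(1 + x₀F)^(4n)`; its maximizer `1/(4nF − F)` is
verified against a numeric grid search.  Where multi-timescale examples
need a per-mechanism `F`, a single shared value (0.5) is the default and
per-stage values remain available through explicit stage construction.

`psd_slope` is ordinary least squares on log10–log10 coordinates over a
caller-chosen band; the low-to-midrange claims in the examples use
0.1–1 Hz.  No robust-fit machinery is used — the quantity is a
descriptive exponent, not an estimator with error bars.

## Fractional operators and the constant-phase fit

`frac_transfer` evaluates `g(iω)^α` as `g ω^α exp(iαπ/2)` so the phase
is constant to machine precision.  The discrete fractional derivative
uses Grünwald–Letnikov binomial weights on a uniform grid (first-order
accurate; signals are taken to be zero before the first sample, matching
the lower limit of the Riemann–Liouville integral).  The
gamma-superposition identity `t^-k = (1/Γ(k))∫ λ^(k-1) e^(-λt) dλ` is
computed by adaptive quadrature split at `λ = 1/t` to handle the
integrable singularity for `k < 1`; the result is accepted only if the
quadrature error estimate is below 1e-7 relative.

The constant-phase fit minimizes the summed squared deviation between
the cascade phase `Σ arctan(ωτₙ) − arctan(ωτₙ/Aₙ)` and the target
`απ/2` on 50 log-spaced frequencies over the fit band, using Nelder–Mead
with the reparameterization `A = 1 + exp(u)` so the nominally
unconstrained simplex respects `A > 1`.  Initialization is `A₀ = 1 + α`
(exact in the small-α limit).  The reported residual is the maximum
absolute phase deviation over the band.  The per-stage fit is seeded
from the shared solution and falls back to it if the simplex ends on a
worse max-deviation point, which makes the nesting guarantee
(per-stage ≤ shared) hold by construction.  `α = 0` is short-circuited
to `A = 1`, residual 0.  Step responses of rational cascades are
evaluated through partial fractions of `H(s)/s` (exact on arbitrary,
e.g. logarithmic, time grids; repeated poles handled with polynomial
factors).

## Conductance-based neuron

Single-compartment Hodgkin–Huxley model with the standard parameters
(G_Na = 120, G_K = 36, G_Leak = 0.3 mS/cm²; E_Na = 50, E_K = −77,
E_Leak = −54.4 mV; C = 1 μF/cm²), using the rest-shifted modern rate
functions (resting potential ≈ −65 mV).  Integration is fixed-step RK4
at dt = 0.05 ms with the stochastic input sampled on the dt grid and
linearly interpolated at half-steps.  Spikes are upward crossings of
−10 mV separated by more than 2 ms (earlier crossing wins).

Three AHP currents `−G_AHP·a·(V − E_K)` implement SFA, with
τ = 0.3, 1, 6 s and G_AHP = [0.05, 0.006, 0.004]·G_Leak; each detected
spike increments every `a` by one at the detection sample, and `a`
decays as `da/dt = −a/τ`.  The reversal is taken at E_K because these
are slow potassium currents.  Conditions: scale 0 (none), 1 (Low SFA),
5 (High SFA).

Numerical guard: at voltages below roughly −120 mV (reachable under
strong negative noise excursions, since the subthreshold conductance is
small) the m-gate closing rate `4·exp(−(V+65)/18)` makes the gating ODEs
stiff at this dt, and raw RK4 substeps can drive `m` negative — which is
catastrophic through the `m³` term.  Gating variables are therefore
clamped to [0, 1] inside RK4 substages as well as after the full step.
The clamp is inactive in the normal operating range; halving dt changes
the spike count of a 20 s benchmark by ≤ 2%.

### Input calibration

The stimulus is zero-mean exponentially filtered (τ = 1 ms) Gaussian
noise, generated as the exactly stationary discrete OU process
`x_k = a·x_{k-1} + sd·√(1−a²)·w_k`, `a = exp(−dt/τ)` (sample SD equals
the requested SD; lag-1 ms autocorrelation `e^-1`).

The named input conditions are specified nominally as SD 10/15/20
μA/cm² but *defined* by the firing rates they must evoke in the
no-adaptation neuron: ~1, ~10 and ~20 Hz.  Injecting the nominal SD
directly drives this neuron at 55–65 Hz in all three conditions, and no
simple reading of the filter normalization reproduces the rate anchors,
so the conditions apply a fixed calibration `INPUT_CALIBRATION = 0.105`
(injected SD = 0.105 × nominal), chosen once from the measured
rate-vs-SD curve of the no-adaptation neuron.  With it the three
conditions evoke ≈ 0.9/9.7/20.8 Hz (3 × 100 s).  The calibration is a
single constant applied at the condition level;
`generate_filtered_noise` itself always delivers exactly the SD it is
asked for.

## Synaptic depression

Canonical multiplicative-depression model with exponential recovery to
one: between spikes `d(t) = 1 − (1 − d)·exp(−Δt/τ_d)` (τ_d = 0.6 s;
likewise `D` with τ_D = 9 s); at each presynaptic spike the amplitude
`G = d·D` is read out *before* depression is applied (the conductance
reflects resources available at spike arrival), then `d → f_d·d`,
`D → f_D·D`.  High STD: f_d = 0.4, f_D = 0.995; Low STD: 0.7/0.999.
Facilitation is omitted.  Under periodic drive the fast variable reaches
the analytic fixed point `(1 − e)/(1 − f_d·e)`, `e = exp(−Δt/τ_d)`,
which the tests verify to 1e-10.

The LFP proxy is the amplitude impulse train summed across neurons and
convolved with a causal exponential (τ = 0.3 s), evaluated with exact
spike-time phase (each impulse enters the first sample at/after its
spike, pre-decayed by the sub-sample offset) — no spike-time binning
error.  No postsynaptic membrane integration is modeled; the filtered
amplitude sum *is* the proxy.

## Population experiments

100 neurons (default) with independent noise realizations (neuron `i`
seeds its generator with `base_seed + i`); a shared-noise fraction is
exposed (default 0, i.e. fully independent drive) since cross-neuron
input correlation is not part of the reference conditions.  No recurrent
connectivity.  The proxy is sampled at 200 Hz; Welch PSDs use 20 s Hann
segments with 50% overlap after discarding a 10 s burn-in, resolving the
0.05–5 Hz band where adaptation acts while averaging ≥ 14 segments at
the default 300 s duration.  Band summaries use 0.01–1, 1–10 and
30–50 Hz; "broadband" is 0.05–100 Hz.  Crossing frequencies between two
conditions' PSDs are located on spectra smoothed by a 7-bin moving
geometric mean (raw Welch ratios are too noisy to define a stable
crossing), with log-linear interpolation of the crossing point.

The spiking tests run the population at 20 neurons, 300 s and 3 seeds
(base seeds 0/1000/2000).  Twenty neurons keep the full suite at
desk scale; the asserted quantities are rank orderings of band powers of
the *summed* proxy, which are insensitive to population size (they held
identically at 20 and at larger populations during development).  The
depression stage is a deterministic post-processing of spike trains, so
the Hodgkin–Huxley runs are shared between STD conditions of the same
(input, SFA, seed) cell.

## What the generator does and does not emulate

The synthetic stimulus is stationary filtered Gaussian noise: it
emulates the aggregate synaptic bombardment of an asynchronous input
population with a 1 ms correlation time, and the rate anchors tie its
three amplitude levels to defined operating points.  It does not emulate
oscillatory or non-stationary drive, input correlations between neurons,
conductance (rather than current) noise, or recurrent feedback.
Passing tests therefore demonstrate the mechanistic chain — adaptation
filters shape spectra; depression makes output power non-monotonic in
input — under these idealized conditions, not that real EEG spectra are
quantitatively reproduced.

## Known limitations

- The fractional approximation is band-limited by the chosen timescales;
  outside ~0.05–5 Hz (for τ = 0.05/0.5/5 s) the cascade reverts to
  ordinary first-order behavior, and the fit degrades as α → 1.
- The Grünwald–Letnikov scheme is first-order accurate; the semigroup
  property holds only to discretization error.
- The STD linearization is a small-signal description; the spiking
  pipeline carries the full nonlinearity.
- The input calibration constant is tied to this neuron variant; a
  different gating convention would need recalibration against the same
  rate anchors.
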