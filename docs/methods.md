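# Methods

## Model

The neuron is a single isopotential compartment (C = 4 pF) with six
voltage-dependent or leak membrane currents and an electrogenic Na/K pump.
The sodium currents are a fast transient current (m³h kinetics, activation
midpoint −29.13 mV) and a small persistent current (first-order activation,
midpoint −48.77 mV, τ = 1 ms); potassium currents are a fast
delayed-rectifier with two inactivation components mixed 95:5 (the minor
component has a fixed 116 ms time constant) and a slow non-inactivating
n⁴ current; both leaks are ohmic.  All gating steady states are Boltzmann
functions of voltage and all time constants are sigmoid functions of
voltage; the full parameter set is in `core_model.py` and is the package's
single source of truth.

The pump current is a time-constant-free sigmoid of intracellular sodium
(half activation NaH = 40 mM, slope NaS = 10 mM, maximum 75 pA).  Although
the pump itself has no memory, the sodium pool does: during spiking the
voltage-gated sodium influx overwhelms extrusion and [Na⁺] climbs by a few
mM; after spiking ends the inward and outward fluxes nearly balance, so the
excess decays over tens of seconds.  That slow decay, read out through the
pump current and (in the DynDyn variant) through the depressed Nernst
reversal, is the mechanism behind the long AHP, the test-pulse excitability
suppression, ramp hysteresis, and pump-driven bursting.

Units are fixed package-wide to mV, ms, nS, pA, pF, mM and pL, chosen so
that nS·mV = pA and pA/pF = mV/ms identically.  The only conversion
constant in the model is 1/(F·Vol) ≈ 1.888×10⁻⁵ mM·ms⁻¹·pA⁻¹ in the sodium
balance (F = 96485.332 C/mol, Vol = 0.549 pL).  The Nernst equation uses
natural logarithms with T = 298.15 K (RT/F = 25.693 mV), which reproduces
the reference resting reversal of 31.2 mV at [Na⁺] = 40.08 mM to within
0.001 mV; decade-logarithm approximations are deliberately not used.

### Variants

The concentration switch freezes [Na⁺] at 40.08 mM; the reversal switch
freezes E_Na at 31.2 mV.  The combination "frozen concentration, dynamic
reversal" is physically meaningless and the constructor rejects it.  The
frozen values are the (rounded) fixed point of the fully dynamic model, so
the three variants share the resting state to within microvolts and diverge
only after a perturbation.

## Numerics

Reference integrator: LSODA (adaptive step, automatic stiffness switching,
via `scipy.integrate.odeint`) with absolute tolerance 1.49012×10⁻⁸ and
relative tolerance 1×10⁻¹⁰.  These follow the published configuration
verbatim, including the unusual assignment of the larger number to the
absolute tolerance; the results are insensitive to a tenfold tightening
(tested: every spike time in a 5 s, 50 pA run moves by < 1 ms).  Spikes are
~1 ms events riding on ~10 s sodium dynamics, so an adaptive stiff-capable
solver is the appropriate reference; a fixed-step classical RK4 integrator
is kept purely as a cross-validation oracle and agrees with the reference
to < 0.1 mV away from spike flanks at dt = 1 µs.

Stimulus protocols report their breakpoints (step onsets/offsets, ramp
vertices, zap midpoint) and the integrator restarts at each one, so
discontinuities are never smeared across a solver step.  Stimulus windows
are half-open [onset, offset): the sample at the offset carries 0 pA, which
makes charge accounting unambiguous.  Traces are sampled on a uniform
output grid (default 0.05 ms; long protocols use 0.1–0.2 ms); sampling is
interpolation only and does not influence the solution.

Cold starts initialise gating at its steady state for the initial voltage.
The resting state is found by relaxing for 200 s without stimulus — robust
in the face of multistability — then polishing the endpoint with a root
solve of the reduced fixed-point system (gating eliminated at x_∞(V); for
dynamic-sodium variants the two unknowns V and [Na⁺] solve zero net
membrane current and zero net sodium flux simultaneously).  Regimes that
are still oscillating at the end of relaxation (endogenous bursters, e.g.
pump parameters 60 pA/10 mM/3 mM) are reported as "no stable rest" rather
than as an error, since they are legitimate dynamical regimes.

## Stimuli

* Step: rectangular, half-open window.
* Bidirectional ramp: piecewise-linear 0 → peak → 0, continuous.
* Zap: I(t) = I_max·(0.5 + 0.5·cos(2π f_zap t + π)) where
  2π f_zap t = 2π f₀ (e^{λt} − 1)/λ is the accumulated phase of an
  exponential chirp f₀e^{λt}, λ = ln(f_max/f₀)/τ_half (defaults 0.1→5 Hz
  over τ_half = 20 s).  The printed compact form of f_zap is ambiguous;
  the phase-consistent reading f₀(e^{λt}−1)/(λt) is used because it is the
  only one for which the instantaneous frequency reaches exactly f_max at
  τ_half.  The deceleration half is the exact time mirror of the
  acceleration current waveform, so the full 40 s stimulus satisfies
  I(t) = I(40 s − t) to machine precision.
* Test-pulse memory protocol: a 22 pA/200 ms pulse probing baseline
  excitability, a 5 s silent gap, the 50 pA/5 s main stimulus, and the same
  test pulse again a configurable delay after the offset.  Each delay is an
  independent simulation from the same rest state.  The pre-pulse is placed
  5 s before the main stimulus; the post-pulse results are insensitive to
  this placement (checked for gaps of 5–30 s and with the pre-pulse
  removed).

## Analysis measures

Spikes are upward crossings of −20 mV with linearly interpolated crossing
times and a 2 ms refractory merge.  Model spikes overshoot ~0 mV while
subthreshold dynamics stay below ~−40 mV, so counts are
threshold-insensitive (identical for −20 and 0 mV thresholds on step
responses).  The instantaneous firing rate (IFR) of each interspike
interval is 1000/ISI Hz, time-stamped at the later spike.

* IFR_ini / IFR_fin: inverse of the first / last ISI during a step.
* Adaptation slope s_adapt: take the last 19 IFR values, drop the very last
  (its ISI may be truncated by the stimulus ending mid-spike), split the
  remaining 18 into two consecutive groups of 9, and divide the difference
  of the group means by the time between the middle (5th) entries of the
  groups.  Undefined below 20 spikes.
* AHP amplitude: minimum post-offset voltage minus the voltage immediately
  before stimulus onset; "no AHP" when the undershoot is below 0.05 mV.
  AHP half-duration T_1/2: time from stimulus offset until the voltage
  first recovers to baseline + AHPamp/2 (AHPs here last tens of seconds, so
  step experiments simulate a 60 s tail).
* Step classification: subthreshold (no spikes); depolarization block
  (> 200 ms contiguously above −30 mV without spiking during the
  injection); premature termination (gap from last spike to stimulus offset
  exceeding max(250 ms, 3× the last ISI) — i.e. spiking stopped well before
  the stimulus did); otherwise sustained.
* Burst segmentation: boundaries at ISIs > 5× the median ISI (within-burst
  ISIs are ≲ 0.1 s, interburst gaps ≳ 1 s in the bursting regimes, so the
  factor is uncritical); gap detection runs on the full train, then bursts
  starting in the first 20 % of the record are discarded as transient.
  Period = mean interval between burst onsets; duration = mean first-to-last
  spike span over bursts whose termination is confirmed by a following gap;
  duty cycle = duration/period.  Fewer than three burst onsets, or no
  qualifying gaps, is "not bursting".
* Ramp hysteresis: each IFR sample is paired with the momentary injected
  current; the metric is the mean (up-phase − down-phase) IFR over 2 pA
  current bins populated in both phases.  An isolated ISI longer than 5×
  the median and 3× both neighbours spans a silent gap (e.g. the
  depolarization-block window at the ramp peak) and is not a momentary
  rate, so it is excluded; uniformly slow spiking is kept.
* Zap cycle analysis: cycle edges at the chirp's phase multiples of 2π
  (mirrored for the deceleration half); per-cycle spike counts, first/last
  cycle voltage peaks, and a symmetry score = mean |count difference|
  between each cycle and its time mirror.

## Synthetic fixtures

The metric layer is tested against generators with analytically known
answers, not against simulations: constant-rate and linear-IFR spike trains
(the latter built by inverting the target IFR profile into ISIs, so the
measured adaptation slope must round-trip), periodic burst trains, voltage
traces with triangular spikes, and AHP traces with a linear dip and
exponential recovery (ground-truth amplitude and half-duration in closed
form).  These fixtures emulate the *measured* structure of model output —
they contain no channel noise, no spike-shape variability and no drift, so
passing them validates the measurement code, not the biophysics; the
biophysics is validated by the reproduction suites in
`tests/test_acceptance.py`.

## Problem sizes and defaults

Step experiments use a 1 s pre-stimulus baseline, 5 s steps and 60 s
post-stimulus tails (AHP recovery).  FI threshold searches run at 1 pA
resolution (bisection over integers in the library, exhaustive scan in the
acceptance script); the four-way monotonicity check samples four currents
in the sustained range.  Ramp experiments use 2/10/40 s total durations at
70 pA peak; zaps 40 s; burst surveys 50 s of injection (100 s for the
zero-injection endogenous burster, whose period is ~15 s).  All experiments
are pure functions of their configuration — there is no randomness anywhere
in the package.

## Known limitations

* Potassium and extracellular concentrations are static; temperature is
  fixed at 25 °C; the pump has no voltage dependence; single compartment
  only.
* Near-threshold knife edges (the zap amplitude at which the
  constant-concentration variant just avoids spiking; the test-pulse delay
  at which the spike count recovers its final spike) are sensitive at the
  sub-percent level to parameter rounding, and absolute agreement with
  other implementations cannot be expected there; all non-marginal
  behaviours are insensitive to these choices.
* The DynCon variant (dynamic concentration, frozen reversal) is a
  deliberately artificial construct for separating concentration effects
  from driving-force effects; only ConCon and DynDyn map onto physical
  recording conditions.
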