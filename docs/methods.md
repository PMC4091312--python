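# Methods

`tracefit` fits the parameters of neuronal models to electrophysiological
target traces by minimizing a weighted combination of normalized trace-
comparison costs with bound-constrained global or local optimizers. This
note documents the models, the cost definitions, the optimizer behavior,
the surrogate study conditions, the numerical choices, and the known
limitations — in that order.

## Trace representation and alignment

All data are uniformly sampled time series in canonical units (mV, nA,
ms); sample *i* of a trace lies at `t0 + i*dt` with `t0 = 0` for loaded
data. Trace files are plain text, one column per trace, no header and no
time column — the sampling interval is declared alongside the file.
Units are converted on load by exact powers of ten (V/mV/uV, uA/nA/pA);
cross-kind conversion is an error.

Because every cost compares traces point by point, target and simulation
must share one grid. The rule is applied once, up front: if the target is
sampled *faster* than the model step, the simulation step is adjusted
down to the target's `dt`; if *slower*, the target is linearly
interpolated onto the model grid and the re-sampled set replaces the
original from then on. After alignment, mismatched `dt` or length in a
cost call is an error, never a silent resample.

## Spike detection and features

A spike is a maximal contiguous excursion at or above a user-set
detection threshold (default 0 mV); onset and offset are the linearly
interpolated threshold crossings, the peak is the largest sample of the
excursion, and an excursion still open at the end of the trace is closed
at the last sample. The threshold voltage attributed to a spike is the
detection threshold itself — no dV/dt criterion — which makes the
features reproducible and parameter-free:

* **amplitude** = peak voltage − threshold voltage;
* **width** = time spent above the half-amplitude level
  (threshold + amplitude/2), linearly interpolated at both crossings;
* **AHP depth** = threshold − minimum voltage between a spike's offset
  and the next spike's onset (the last spike searches to the stimulus
  end, when one is configured, or the trace end).

For traces produced by the adaptive exponential integrate-and-fire
backend, the natural detection threshold is the model's own cutoff
`V_cut = VT + 5·deltaT`, where the spike samples are drawn.

## Cost functions

Eleven features are available, each normalized toward [0, 1] so that
user weights express relative importance; for multi-trace data every
feature is summed over corresponding trace pairs, and the total is the
weighted sum over features (weights optionally normalized to unit sum).
With simulated trace `s`, target `x`, trace duration `T` and target
range `R = max(x) − min(x)`:

| feature | definition |
|---|---|
| `mse` | mean((s−x)²) / R² |
| `mse_excl_spikes` | the same mean restricted to samples outside ±h around every spike peak detected in either trace (h = 5 ms default); normalization uses the full-trace R |
| `deriv_diff` | mean squared difference of temporal derivatives (central differences, one-sided ends), normalized by the squared range of the target derivative |
| `spike_count` | \|n_s − n_x\| / (n_s + n_x + 1) |
| `spike_count_stim` | the same, counting only peaks inside the stimulus window |
| `isi_diff` | Σ\|ISI_s,k − ISI_x,k\| / T over the first min(n_s, n_x) − 1 interval pairs (0 if either train has < 2 spikes) |
| `latency` | (t_s,1 − t_x,1)² / T², a spikeless trace contributing latency T (capped at 1) |
| `ap_overshoot` | mean squared amplitude difference over order-paired spikes / (max target amplitude)² |
| `ap_width` | mean squared width difference / (mean target width)² |
| `ahp_depth` | (mean of per-pair depth differences)² / (subthreshold target range)² |
| `pptd` | total-variation distance between the normalized 2-D histograms of (V, dV/dt) points of the two traces on a shared G×G grid (G = 64) spanning their joint bounding box |

Design choices where the definitions were genuinely open:

* Exclusion windows are centered on spike peaks with a configurable
  half-width (default 5 ms).
* Spike pairing for the shape features is by order of occurrence,
  truncated to the shorter train; with no pairs at all the value is the
  worst case 1 when the counts differ and 0 when both trains are empty.
  ISIs and latencies are measured between peak times.
* `ahp_depth` squares the *mean* of the differences (the literal reading
  of "squared average of the differences"); a documented switch
  (`ahp_mean_of_squares`) averages the squared differences instead.
  The "subthreshold range of the target" is the range after removing
  the exclusion windows.
* The phase-plane density comparison uses the total-variation distance:
  bounded in [0, 1], symmetric, zero exactly on identical histograms.
  A fully degenerate bounding box (two constant, equal traces) scores 0;
  a zero-width axis is padded by ±0.5 before binning.

Every feature is checked against an independent, loop-based
re-implementation of its formula on randomized trace pairs (agreement to
1e−12 relative).

## Simulator backends

**Hodgkin-Huxley step (current clamp).** A single cylindrical
compartment (default 10 μm × 100 μm, area π·d·L) carrying the classical
squid-axon Na⁺/K⁺/leak conductances at 6.3 °C: reversals 50 / −77 /
−54.3 mV, C_m = 1 μF/cm², the canonical rate functions, gating
initialized at steady state for `v_init`. The three density parameters
(S/cm²) are tunable. Integration is classical fixed-step RK4 at the
protocol `dt` (default 0.025 ms) with NEURON-style tabulated rate
functions (linear interpolation on a 0.05 mV grid over ±200 mV, exact
evaluation outside). If the explicit scheme blows up — possible when a
candidate's conductance densities push the membrane time constant below
the step — the sweep is retried with doubled sub-stepping (up to 256×);
large-but-finite excursions (a near-passive membrane ramping under
constant current) are left alone. Halving `dt` leaves the spike count of
the reference protocol unchanged and moves peak times by < 0.5 ms.

The default initial potential is −70 mV, the standard holding level of
the voltage-clamp study and a common initialization for current-clamp
experiments. Note that a membrane initialized at −70 mV (below the
squid-axon resting potential) fires one anode-break-style spike on
release at the sweep start; the reference target's 28 action potentials
comprise this initial spike plus 27 during the 200 pA step.

**Double-exponential synapse under ideal voltage clamp.** The same
compartment held exactly at the clamp level; the holding current is the
steady-state ionic current, and each input spike adds a conductance
transient g(t) = w·N·(e^(−t'/τ₂) − e^(−t'/τ₁)) (t' measured from spike
time + delay, N normalizing the peak to w), reversal 0 mV (excitatory).
The recorded clamp current, outward positive, is
I_ion(V_hold) + g·(V_hold − E_rev); it is evaluated in closed form, with
no ODE integration. Tunable parameters: rise τ₁, decay τ₂ (ms), peak
conductance w (μS), delay (ms). Following the common two-state kinetic
synapse convention, τ₁ ≥ τ₂ is clamped to 0.999·τ₂ rather than rejected —
the fitting bounds of the two time constants overlap, so candidates in
that region must remain evaluable.

**Adaptive exponential integrate-and-fire (current clamp).** The
two-variable reduced model C·dV/dt = −gL(V−EL) + gL·ΔT·e^((V−VT)/ΔT) − w
+ I(t), τ_w·dw/dt = a(V−EL) − w, with all ten parameters tunable. When V
reaches V_cut = VT + 5ΔT the crossing is located by linear interpolation
within the step, the crossing sample is drawn at V_cut (so a fixed
threshold detector finds exactly one sample per spike), V resets to Vr
and stays clamped for t_ref while w (incremented by b) keeps relaxing.
The exponential argument is capped at (V_cut−VT)/ΔT = 5 to preclude
overflow. RK4 on (V, w) between spikes. In the a = b = 0, small-ΔT limit
the subthreshold step response reproduces the closed-form RC charging
curve to < 1%.

**External black boxes.** Any executable honors the contract: parameter
values appended to its argv in declared order at full precision; the
process writes the trace file in the package dialect; nonzero exit
status, timeouts and malformed output files are reported with the
command and stage. A `user_mapping` hook on any backend translates
abstract optimization parameters into backend parameters first (e.g. one
scale factor controlling several densities); the hook is a pure function,
so mapping-then-simulating equals simulating pre-mapped values.

## Optimizers

All algorithms search the unit cube: x_i = l_i + u_i(h_i − l_i) with
mandatory finite bounds per parameter. No objective evaluation ever
leaves [0,1]^d (enforced and tested); all randomness flows from one
seeded generator, so a fixed seed reproduces a fit bit for bit.

**Evolutionary (EO).** Generational replacement with weak elitism — the
single best individual always survives, so the best-so-far cost is
non-increasing. Per generation: tournament selection (size 4), blend
(BLX-α) crossover with α = 0.5, per-gene Gaussian mutation with
probability 0.25, offspring clipped (reflection available). The mutation
scale anneals geometrically from `mutation_sigma` (0.3) to
`mutation_sigma_final` (1e−6 normalized units) across the configured
generations; setting both equal disables annealing. The wide blend
interval lets the population extrapolate along correlated parameter
valleys (the synaptic task couples rise time, weight and delay), and the
annealed mutation turns the converged population into a fine local
search — at the full budget the synaptic study recovers all four
generating parameters to < 0.01% on every tested seed. Population
default 100; a user-supplied start vector replaces one initial member.

**Simulated annealing (SA).** Single state, Gaussian proposals
(s.d. `mutation_sigma`), Metropolis acceptance, geometric cooling
T ← cooling·T every `dwell` evaluations from T0 until Tf or the
evaluation budget. One implementation with a configurable schedule.

**Nelder-Mead (NM) and L-BFGS-B.** scipy's implementations behind the
same interface; L-BFGS-B with native box constraints and forward
finite-difference gradients (step 1e−6), NM with projection onto the
cube plus a quadratic infeasibility penalty (plain clipping leaves the
landscape flat outside the cube and can strand the simplex there). Local
searches start from the user start or the cube center.

Every run records per-generation best/mean/median/worst fitness and the
populations (for allele statistics), the final population, the seed and
the evaluation count. `grid_slices` evaluates one-dimensional scans of
the cost through the optimum for parameter-sensitivity plots;
`population_stats` summarizes the final population.

## Surrogate study conditions

The three built-in cases generate their targets from known parameters —
so zero-error solutions exist by construction, and fitting them measures
the machinery, not the model class:

* `uc1_hh`: 200 pA step (200–700 ms of a 1000 ms sweep, dt 0.025 ms)
  into the HH compartment at densities 0.12/0.036/0.0003 S/cm²; a single
  voltage trace with 28 spikes at the 0 mV threshold. Fitting searches
  gna ∈ [0,1], gk ∈ [0,0.3], gl ∈ [0,0.003] S/cm² under
  0.5·`mse_excl_spikes` + 0.5·`spike_count`.
* `uc2_synapse_vc`: clamp current at −70 mV with the synapse at
  (0.3 ms, 3 ms, 0.01 μS, 2 ms) driven by 4 spikes 100 ms apart
  (onsets 10–310 ms, 420 ms sweep); plain `mse` cost; bounds
  [0.1,5]×[0.5,10]×[0.001,0.1]×[0.1,10].
* `uc5_adexp_like`: a CA3-pyramidal-like AdExpIF parameter set (C 0.12
  nF, gL 8 nS, EL −70, VT −50, Vr −56, t_ref 2 ms, ΔT 2 mV, a 4 nS,
  b 0.03 nA, τ_w 100 ms — input resistance 125 MΩ, τ_m 15 ms, rheobase
  ≈ 0.17 nA, moderate adaptation) responding to 0.30/0.35/0.40/0.45 nA
  steps, 1100 ms sweeps at 5 kHz. This case exercises the multi-trace
  path; it represents a plausible reduced CA3 cell, not a fit to any
  particular recording.

Optional additive Gaussian noise (seeded) emulates recording noise only;
the generator reproduces none of the other features of real data —
electrode artifacts, drift, trial-to-trial variability, or model
mismatch (a real neuron is never a member of the fitted model class).
Passing the recovery studies therefore demonstrates that the costs,
simulators and optimizers compose correctly, not that any model will fit
any cell.

On identifiability, the two fitting studies deliberately differ. The
synaptic problem is well-posed: the cost has a single basin and every
seed converges to the generating parameters. The conductance-density
problem is degenerate under its subthreshold-plus-count cost: many
density combinations (roughly ratio-preserving, up to several times the
generating values) reproduce the subthreshold trajectory and the spike
count while spike times shift within the exclusion windows. Different
seeds end at materially different conductance vectors with similarly
low costs, and the full-trace mean squared error of such solutions is
dominated by spike-time misalignment (tens to hundreds of mV²) even
though the fitted cost is ~1e−4. This degeneracy is a property of the
problem, not a failure of the search.

## Sessions, configuration, artifacts

An XML file under a versioned `<settings>` root holds one tag per
option: data description, backend and its settings, parameters with
bounds, protocol, cost terms and shared feature parameters, optimizer
hyperparameters, output directory. Validation is strict — missing
required tags and unknown tags are reported by name at load time. A run
writes the best trace (text, 9 significant digits), a target-vs-best PNG
(EPS on request), an HTML report (settings, fitted parameters, weighted
per-feature breakdown that sums to the reported total), a key=value
result summary, and a config XML that reproduces the run exactly
(same seed → byte-identical summary). The `tracefit` console command is
a thin wrapper: `tracefit -c conf.xml [--seed N] [--out DIR]
[--generations N]`.

## Problem sizes used by the shipped studies

The test suite runs the conductance-density study at population 100
with 30 generations and the synaptic study at 40 generations (best of
3 fixed seeds each) — reduced budgets at which the synaptic study
already recovers all parameters within a few percent. The
reproduction script (`scripts/acceptance.py`) keeps population 100
with 30 generations for the conductance-density study and uses the
full 100 generations for the synaptic study, where every tested seed
then recovers the generating parameters essentially exactly.

## Known limitations

* Single-objective only; no Pareto treatment of multiple features.
* One trace set of one kind per session (no mixed voltage + spike-time
  targets).
* Built-in models are single-compartment; multi-compartment or other
  model classes enter only through the external black-box contract.
* Fixed-step integration only.
* The width/threshold/AHP conventions are this package's own (documented
  above); spike-shape feature values are comparable within the package,
  not across tools with different conventions.
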