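# tracefit

Fitting the parameters of neuronal models to electrophysiological
traces.

Building a usable neuron model — whether a conductance-based membrane or
a reduced integrate-and-fire cell — almost always ends in the same
problem: several model parameters must be tuned simultaneously so that
the simulated response matches a recorded (or reference) trace under a
given stimulation protocol. The match criterion matters as much as the
search algorithm: a pointwise error cares about every sample, while
spike-feature errors care about what the physiologist cares about —
how many spikes, when, how wide, how deep the after-hyperpolarization.
`tracefit` is a library for composing exactly these studies, aimed at
computational neuroscientists and experimentalists who use model-based
analysis of current- and voltage-clamp data.

## What it provides

* **Trace handling** — plain-text trace files, unit conversion
  (V/mV/μV, μA/nA/pA), and a single up-front sampling-alignment rule
  (linear interpolation of the slower-sampled side).
* **Cost functions** — eleven normalized dissimilarity measures between
  a simulated trace set and a target: pointwise MSE `(1/n)Σ(s_i−x_i)²/R²`,
  subthreshold MSE (spike windows excluded), derivative difference,
  spike count `|n_s−n_x|/(n_s+n_x+1)` (whole trace or stimulus window),
  inter-spike-interval difference, latency to first spike, AP
  overshoot, AP width, AHP depth, and a phase-plane trajectory density
  distance on (V, dV/dt) histograms. Arbitrary weighted combinations,
  accumulated over trace pairs.
* **Simulators** — built-in backends for a single-compartment
  Hodgkin-Huxley membrane (current-clamp steps), a double-exponential
  conductance synapse under ideal voltage clamp, and the adaptive
  exponential integrate-and-fire model (V_cut = V_T + 5Δ_T); plus a
  file-based contract for arbitrary external simulators driven as
  black boxes.
* **Optimizers** — bound-constrained minimization over 0–1 normalized
  parameters: a generational evolutionary algorithm with weak elitism,
  blend crossover and annealed Gaussian mutation; simulated annealing;
  Nelder-Mead; and L-BFGS-B. Full per-generation history, final-
  population statistics and one-dimensional cost slices around the
  optimum.
* **Sessions** — XML-configured end-to-end runs (strictly validated),
  writing the best trace, comparison figure, HTML report, result
  summary and a reproducing configuration; a thin `tracefit` CLI for
  non-interactive use.
* **Surrogate studies** — generators for targets with known ground
  truth, so parameter recovery can be verified without any external
  data.

## Worked example: recovering synaptic parameters

A membrane is held at −70 mV in ideal voltage clamp while a
double-exponential synapse (rise 0.3 ms, decay 3 ms, peak 10 nS, axonal
delay 2 ms) is driven by four input spikes; the evolutionary algorithm
then searches all four synaptic parameters from scratch against the
recorded clamp current (`examples/fit_synapse.py`, reduced budget of
population 40 × 25 generations):

```text
evaluations: 1040, final normalized cost: 7.459e-08
raw clamp-current MSE: 3.655e-08 nA^2
 parameter     true     fitted    error
      tau1      0.3    0.29782    0.73%
      tau2        3      3.004    0.13%
    weight     0.01  0.0099925    0.08%
     delay        2      2.002    0.10%
```

All four parameters come back within a percent of the generating
values; the residual clamp-current error (3.7e−8 nA², RMS ≈ 0.2 pA
against ~0.7 nA deflections) says the fitted and target currents are
visually indistinguishable. At the full budget (population 100 × 100
generations) every seed recovers the parameters to below 0.01%.

Other entry points, one capability each, live in `examples/`:
simulating the Hodgkin-Huxley step response, scoring trace pairs with
the cost library, cost-landscape slices around an optimum, driving an
external simulator, and a complete XML-configured session.

## Documentation

`docs/methods.md` describes the models and their assumptions, every
cost definition with its normalization, the optimizer internals and
defaults, the surrogate study conditions, numerical choices, and known
limitations.
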