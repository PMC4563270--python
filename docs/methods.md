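# Methods

## Problem

Time-driven simulators for spiking neuronal networks exploit the fact that
chemical synapses act with a delay: every neuron can be advanced
independently for the duration of the smallest delay `d_min`, and processes
only exchange spikes once per `d_min`. Gap junctions (electrical synapses)
break this scheme, because the coupling current

    I_gap,ij(t) = g_ij (V_i(t) - V_j(t))

depends on the partner's membrane potential instantaneously. The common
workaround — freeze the partner potentials at their start-of-step values
for one computation step h (the *single-step* method) — communicates every
step and, for realistic coupling strengths, produces a systematic temporal
shift of the membrane-potential time course that shrinks only slowly with
h.

`gapwave` implements the alternative: Jacobi waveform relaxation. The
network ODE system is partitioned into one subsystem per neuron. Over a
communication interval the subsystems are solved independently, each
treating its gap partners' membrane-potential trajectories ("waveforms")
from the previous iteration as given input; iterating this to convergence
solves the coupled system to the accuracy of the waveform representation
while retaining min-delay communication.

## Neuron model

The point neuron is the fast-spiking cortical interneuron of Mancilla et
al. (2007): Hodgkin–Huxley dynamics with a transient Na current (gates m,
h), slow Kv1 (n^4) and fast Kv3 (p^2) K currents, and a leak; synaptic
input as alpha-shaped currents, each receptor realized as two linear ODEs
driven by delta kicks of amplitude J·e/tau so the current of one input
spike peaks at exactly J (pA) one time constant after arrival. With the
membrane potential this gives nine ODEs per neuron. Defaults (the
published set): C_m = 40 pF, g_Na = 4500 nS, g_Kv1 = 9 nS, g_Kv3 =
9000 nS, g_leak = 9 nS, E_Na = 74 mV, E_K = −90 mV, E_leak = −70 mV,
tau_ex = 0.2 ms, tau_in = 2 ms, threshold 0 mV, refractory period 2 ms.
Under a 200 pA constant drive the model fires repetitively at ~21 Hz with
spikes peaking near +62 mV.

A spike is emitted when V crosses the threshold while the neuron is not
refractory; the spike time is stamped at the first grid point at which V
decreases relative to the previous grid point (i.e. the first grid point
after the maximum). If the maximum falls exactly on a grid point, the tie
breaks toward the earlier grid point, applying the rule verbatim.
Refractoriness lasts `round(tau_r/h)` grid steps and only suppresses spike
emission; the dynamics evolve unchanged (no voltage clamp). Gating
variables are not clamped to [0, 1]; boundedness is asserted in the tests
rather than enforced, since clamping would alter the ODE being solved.

## Waveform representation

Within one computation step, a membrane-potential waveform is the
polynomial V((s+x)h) = sum_m a_m x^m, x in [0, 1], of order 0 (constant,
left value), 1 (secant) or 3 (cubic Hermite from both endpoint values and
derivatives; the derivative enters scaled by h). The endpoint derivatives
are the ODE right-hand side evaluated at the grid points, including the
gap current from the accumulator of the current iteration. Each receiving
neuron reduces all incoming waveforms to `order + 2` parameters per step,

    I_gap = -g_bar V + sum_m g_tilde[m] x^m,

with g_bar the summed incoming conductance and g_tilde the
conductance-weighted coefficient sums. In-process, this accumulation is a
sparse matrix product of the symmetric conductance matrix with the
coefficient array (an in-process mailbox standing in for message passing
between processes; the serialization framing of a distributed
implementation is not reproduced).

## Scheduler

Per interval (either `d_min` or a single step h, depending on the
communication strategy):

1. deliver the waveforms broadcast at the end of the previous interval
   (at t = 0: the constant initial potential);
2. preliminary updates: every gap-coupled neuron re-integrates the
   interval from its stored left-edge state, collects its waveform
   coefficients, and tests convergence; then all waveforms are exchanged
   (Jacobi: iteration k reads only iteration k−1's output). Repeat until
   every neuron's grid-point potentials changed by less than `prelim_tol`
   (a grid point violates convergence when |V_last − V| >= prelim_tol,
   following the operational pseudocode; the boundary case of exact
   equality is counted as a violation) or the iteration cap is reached,
   which increments a warning counter surfaced in the run summary;
3. one final update: advances the state, applies buffered synaptic kicks
   at the right edge of each step, detects spikes, and broadcasts the
   constant extrapolation V(t_right) (higher coefficients zero) as the
   next interval's initial guess. V_last is then reset to 0, which forces
   at least two preliminary iterations per interval; a `v_last_reset =
   "current"` override keeps the final grid values instead, but the
   reference behavior is the default.

Preliminary updates never emit spikes, so spike delivery is identical in
every iteration of an interval. The single-step baseline is this machinery
with zero preliminary iterations per step: the broadcast constant
extrapolation is exactly the partner's start-of-step potential.

Defaults: `prelim_tol = 1e-4` mV, cap 15 iterations. The two-neuron
accuracy experiments that probe the displacement floor use `prelim_tol =
1e-6` (the solver accuracy, below which further tightening is pointless).

## Single-neuron integration

Each neuron is advanced over each step h by an embedded
Runge-Kutta-Fehlberg 4(5) pair with adaptive internal sub-stepping:
absolute error control with tolerance 1e-6 per sub-step (relative
tolerance unused), max-component error norm, safety factor 0.9, step-size
change clipped to [0.2, 5], advancing the fifth-order solution. A
non-finite trial stage forces rejection. The first sub-step of a grid step
is seeded with the controller's last proposal for that neuron (clipped to
h) rather than restarting at h; this removes a rejected trial per step
during fast dynamics, is fully deterministic, and leaves the error control
unchanged. Sub-step underflow below `1e-8·h` raises an error.

## Measures

* RMSE: piecewise-linear traces, exact integral of the squared difference,
  epsilon = sqrt((1/3T) Σ Δt_n (ΔV_n² + ΔV_{n+1}² + ΔV_n ΔV_{n+1})).
  Mismatched grids resample the reference linearly.
* Temporal displacement: delta = argmin over tau in [0, tau*] of the RMS
  difference between V*(t) and V(t+tau) (linear interpolation, comparison
  window and T recomputed per tau). tau* defaults to 5 ms and the scan
  resolution to one hundredth of the grid spacing — the measured shifts
  span 1e-6 to a few ms, well inside that window; a coarse-to-fine scan is
  followed by a bounded local refinement. Strictly periodic signals can
  alias (a shift of one period is invisible); the measure is meaningful
  for the aperiodic-enough traces used here.
* Synchrony: chi = sigma of the population-mean potential over the RMS
  single-cell sigma, time averages by the trapezoidal rule; 1 = fully
  synchronous, ~1/sqrt(N) for independent cells; NaN (with a warning) for
  all-constant traces.
* Rates: count-based, nu = n(T)/T, population average arithmetic.

## Benchmark networks

* Pair (1a): two identical neurons, one 30 nS junction (the typical
  *total* coupling of a neuron, concentrated in one junction), 200 pA
  drive, d_min = 1 ms. By symmetry I_gap = 0, so the uncoupled pair is an
  exact reference and any displacement is integration artifact.
* Ring (1b): N neurons, each coupled to its 30 neighbors on either side at
  0.5 nS; the per-neuron summed conductance stays 30 nS, so single-neuron
  dynamics are independent of N (verified: trajectories for N = 100 and
  N = 150 coincide).
* Inhibitory network (2): 500 neurons, initial potentials uniform in
  [−80, −40] mV (gates initialized at steady state for the drawn
  potential, avoiding an artificial onset transient), 50 inhibitory inputs
  per neuron (J_I, 1 ms delay) from distinct randomly chosen partners
  (fixed in-degree), 500 Hz excitatory Poisson drive per neuron (J_E =
  300 pA, same delay), and 60·N/2 gap junctions of uniform weight g drawn
  as random unordered pairs without self-pairs, duplicates allowed and
  accumulating — the simplest sampling consistent with an average gap
  degree of 60. Increasing g moves the network from asynchronous
  irregular activity to synchrony; g is the bifurcation parameter.

  For this network both receptors use a 1 ms alpha-function rise time.
  The choice is dictated by the balance the experiment relies on: the
  neuron's rheobase is ~95 pA, and the mean current of an alpha-synapse
  Poisson drive is rate·J·e·tau. At the model's sub-millisecond
  excitatory default the stated drive would average ~81 pA — subthreshold,
  leaving the network silent with no inhibitory balance and no transition
  — whereas 1 ms rise times give ~408 pA of drive balanced by recurrent
  inhibition of comparable size, producing the asynchronous-irregular
  baseline (tens of Hz) that synchronizes as g grows.

The external Poisson trains are generated per source from independent
streams spawned from the run seed (total count drawn first, emission times
uniform on the grid — exactly a homogeneous Poisson process in
distribution), so runs are reproducible and sources independent.

## Experiment scales

The error-vs-iterations and iteration-count experiments use the pair over
0.4–1 s of biological time at h = 0.05 ms; the displacement floor uses
h = 0.01 ms over 1 s. The synchronization transition uses 3 s runs of the
500-neuron network at h = 0.05 ms with the first 500 ms discarded as
warm-up (random initial conditions would otherwise bias chi), asserting
the ordering of synchrony with g and of firing rates between methods;
resolving the full transition curves takes one to two orders of magnitude
more biological time and is outside the scope of the bundled experiments.

Network-scale runs default to the per-step communication strategy, which
converges in the fewest iterations per exchange and is the fastest option
in a single-process setting where exchanges are cheap; converged results
are strategy-independent (verified to within the convergence tolerance),
so this is purely a run-time choice.

## Known limitations

* Single-process only: the communication strategies reproduce the
  *semantics* (exchange points, payloads, iteration control) of a
  distributed implementation; actual message passing, buffers and their
  benchmarks are out of scope. The communication-count and payload-size
  helpers quantify those costs analytically.
* The linear-order error plateau over long runs is dominated by
  accumulated temporal shift and therefore grows with the measurement
  window, unlike the stationary interpolation error of the waveform
  itself; the plateau-vs-interpolation-error comparison is made for the
  cubic order at the 1 s reference window.
* Voltage-dependent gap junctions, multi-compartment neurons, off-grid
  spike times, and plasticity are not implemented.
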