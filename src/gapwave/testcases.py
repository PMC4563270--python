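"""Reproducible builders for the benchmark networks and experiment drivers.

Three standard configurations probe the integrator at increasing levels of
complexity:

* ``1a`` — a symmetric pair of identical neurons, mutually coupled by one
  30 nS gap junction and driven by a constant 200 pA current. Because both
  neurons behave identically, the gap current vanishes exactly and the
  uncoupled pair is an exact reference solution, exposing the pure
  integration error of a gap-junction scheme.
* ``1b`` — the pair scaled to a ring of N neurons, each coupled to its 30
  neighbors on either side at 0.5 nS, keeping the per-neuron summed gap
  conductance at 30 nS so single-neuron dynamics are independent of N.
* ``2`` — an inhibitory network of 500 neurons with balanced external
  Poisson drive that transitions from asynchronous-irregular to
  synchronous activity as the uniform gap weight g grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hh_neuron import DEFAULT_PARAMETERS
from .measures import Trace, rmse, spike_rate, synchrony_chi
from .network import Network
from .wfr_engine import SimulationConfig, Simulator

__all__ = [
    "ExperimentSpec",
    "build_testcase_1a",
    "build_testcase_1b",
    "build_testcase_2",
    "run_convergence_experiment",
    "run_transition_sweep",
]


@dataclass
class ExperimentSpec:
    """Configuration of one experiment run or sweep."""

    testcase: str = "1a"
    N: int = 2
    h: float = 0.05
    order: int = 3
    strategy: str = "dmin"
    prelim_tol: float = 1e-4
    max_iterations: int = 15
    t_end: float = 1000.0
    seed: int = 1
    g: float = 30.0
    J_I: float = -50.0
    warmup: float = 500.0
    iteration_counts: tuple = tuple(range(1, 13))
    g_grid: tuple = (0.3, 0.54, 0.7)

    def __post_init__(self):
        if self.h <= 0 or self.t_end <= 0:
            raise ValueError("timing parameters must be positive")

    def config(self, **overrides) -> SimulationConfig:
        kw = dict(
            h=self.h,
            order=self.order,
            strategy=self.strategy,
            prelim_tol=self.prelim_tol,
            max_iterations=self.max_iterations,
            seed=self.seed,
        )
        kw.update(overrides)
        return SimulationConfig(**kw)


def build_testcase_1a(g: float = 30.0, I_const: float = 200.0) -> Network:
    """Gap-coupled pair: one 30 nS junction, 200 pA drive, d_min = 1 ms.

    ``g=0`` yields the uncoupled twin network used as the exact reference.
    """
    net = Network(2, DEFAULT_PARAMETERS.with_(I_const=I_const), d_min=1.0)
    if g != 0.0:
        net.connect_gap(0, 1, g)
    return net


def build_testcase_1b(N: int, g: float = 0.5, I_const: float = 200.0) -> Network:
    """Ring of N neurons, each gap-coupled to its 60 nearest neighbors.

    Neuron i is coupled to indices (i - 30 + N) mod N .. (i + 30) mod N,
    i.e. the 30 neurons before and after it on the ring, at g = 0.5 nS
    each, so the summed conductance per neuron matches the 30 nS pair.
    """
    if N <= 61:
        raise ValueError("the ring needs more than 61 neurons")
    net = Network(N, DEFAULT_PARAMETERS.with_(I_const=I_const), d_min=1.0)
    for i in range(N):
        for off in range(1, 31):
            net.connect_gap(i, (i + off) % N, g)
    return net


def build_testcase_2(
    g: float,
    J_I: float = -50.0,
    seed: int = 1,
    N: int = 500,
    n_inhibitory_inputs: int = 50,
    poisson_rate: float = 500.0,
    J_E: float = 300.0,
    delay: float = 1.0,
    gap_connections_per_neuron: float = 60.0,
    tau_syn: float = 1.0,
) -> Network:
    """Inhibitory network with Poisson drive and random gap junctions.

    N neurons start from random potentials uniform in [-80, -40] mV (gates
    at steady state). Each neuron receives ``n_inhibitory_inputs``
    inhibitory synapses (weight J_I, delay 1 ms) from distinct randomly
    chosen other neurons, an excitatory external Poisson input (rate
    ``poisson_rate`` Hz, weight J_E, same delay), and the network carries
    N * 60 / 2 gap junctions of uniform weight g drawn as unordered random
    pairs (no self-pairs; duplicates allowed and accumulating), giving an
    average gap degree of 60.

    Both receptors use a 1 ms rise time (``tau_syn``): with the stated
    drive this puts the network in the balanced regime (mean excitatory
    drive a few times rheobase, inhibitory feedback comparable) whose
    asynchronous-irregular state synchronizes as g grows; the model's
    sub-millisecond excitatory default would leave the drive subthreshold
    and the network silent.
    """
    if g < 0:
        raise ValueError("gap weight must be non-negative")
    params = DEFAULT_PARAMETERS.with_(tau_ex=tau_syn, tau_in=tau_syn)
    net = Network(N, params, d_min=delay)
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_init, rng_syn, rng_gap = (np.random.default_rng(s) for s in ss)

    net.set_initial_potentials(rng_init.uniform(-80.0, -40.0, size=N))

    others = np.arange(N - 1)
    for i in range(N):
        pre = rng_syn.choice(others, size=n_inhibitory_inputs, replace=False)
        pre = np.where(pre >= i, pre + 1, pre)  # skip self
        for j in pre:
            net.connect_chemical(int(j), i, J_I, delay, receptor="inhibitory")

    n_gaps = int(round(gap_connections_per_neuron * N / 2.0))
    if g > 0.0:
        for _ in range(n_gaps):
            i = int(rng_gap.integers(N))
            j = int(rng_gap.integers(N - 1))
            if j >= i:
                j += 1
            net.connect_gap(i, j, g)

    for i in range(N):
        net.add_poisson(i, poisson_rate, J_E, delay)
    return net


def run_convergence_experiment(spec: ExperimentSpec | None = None):
    """Integration error of the coupled pair vs. number of iterations.

    For each communication strategy and interpolation order, the symmetric
    pair is run with a fixed number of preliminary iterations per interval
    and the RMSE against the uncoupled reference (same step size, no gap
    junctions) is measured, producing the error-vs-iterations curve that
    decreases to the interpolation-limited plateau. The same setup is also
    run once per strategy with the adaptive iteration control to obtain
    mean iteration counts.

    Returns ``(table, mean_adaptive_iterations)`` where ``table`` has
    columns strategy / order / iterations / epsilon_mV.
    """
    spec = spec or ExperimentSpec()
    reference = Simulator(build_testcase_1a(g=0.0), spec.config(strategy="dmin")).run(
        spec.t_end
    )
    ref_trace = Trace(reference.times, reference.voltages[0])

    rows = []
    means = {}
    for strategy in ("h", "dmin"):
        for order in (1, 3):
            for k in spec.iteration_counts:
                res = Simulator(
                    build_testcase_1a(g=spec.g),
                    spec.config(strategy=strategy, order=order, fixed_iterations=int(k)),
                ).run(spec.t_end)
                eps = rmse(Trace(res.times, res.voltages[0]), ref_trace)
                rows.append(
                    dict(strategy=strategy, order=order, iterations=int(k),
                         epsilon_mV=eps)
                )
        adaptive = Simulator(
            build_testcase_1a(g=spec.g), spec.config(strategy=strategy)
        ).run(spec.t_end)
        means[strategy] = adaptive.mean_iterations
    return pd.DataFrame(rows), means


def run_transition_sweep(
    g_grid=(0.3, 0.54, 0.7),
    J_I: float = -25.0,
    t_end: float = 3000.0,
    seed: int = 1,
    h: float = 0.05,
    order: int = 3,
    strategy: str = "h",
    single_step: bool = False,
    warmup: float = 500.0,
    N: int = 500,
    record_stride: int = 4,
    prelim_tol: float = 1e-4,
) -> pd.DataFrame:
    """Mean rate and synchrony of the inhibitory network across gap weights.

    For each g the network is simulated, the first ``warmup`` ms are
    discarded (transients of the random initial condition would bias chi),
    and the population mean spike rate and the synchrony measure chi are
    computed over the remainder. Returns one row per g.
    """
    rows = []
    for g in g_grid:
        net = build_testcase_2(float(g), J_I=J_I, seed=seed, N=N)
        cfg = SimulationConfig(
            h=h,
            order=order,
            strategy="single-step" if single_step else strategy,
            prelim_tol=prelim_tol,
            seed=seed,
            record_stride=record_stride,
        )
        res = Simulator(net, cfg).run(t_end)
        keep = res.times >= warmup
        chi = synchrony_chi(res.voltages[:, keep])
        T_meas = t_end - warmup
        rates = [
            spike_rate(res.spike_train(i) - warmup, T_meas) for i in range(N)
        ]
        rows.append(
            dict(
                g_nS=float(g),
                rate_hz=float(np.mean(rates)),
                chi=chi,
                mean_iterations=res.mean_iterations,
                cap_warnings=res.cap_warnings,
            )
        )
    return pd.DataFrame(rows)
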