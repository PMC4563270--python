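"""Network container: neurons, chemical synapses, gap junctions, inputs.

Chemical synapses are delayed current kicks delivered through per-neuron
ring buffers; gap junctions are instantaneous symmetric conductances whose
coupling is resolved by the waveform-relaxation engine. Times are in ms,
grid index 0 is t = 0, intervals are half-open (t_left, t_right], and spikes
are stamped at the right edge of the step in which they are detected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp

from .hh_neuron import DEFAULT_PARAMETERS, NeuronParameters, steady_state_gating
from ._kernels import NSTATE

__all__ = [
    "ChemicalSynapse",
    "GapJunction",
    "PoissonSource",
    "SpikeRingBuffer",
    "Network",
    "build_poisson_trains",
]

#: a delta kick of amplitude J*e/tau makes the alpha current peak at J
_KICK_SCALE = math.e


@dataclass(frozen=True)
class ChemicalSynapse:
    """Delayed current-based synapse; sign of the weight J encodes E/I."""

    source: int
    target: int
    weight: float  # pA, peak amplitude of the alpha current
    delay: float  # ms
    receptor: str = ""  # 'excitatory' | 'inhibitory'; default: sign of J

    def __post_init__(self):
        if self.receptor == "":
            object.__setattr__(
                self, "receptor", "inhibitory" if self.weight < 0 else "excitatory"
            )
        if self.receptor not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown receptor {self.receptor!r}")


@dataclass(frozen=True)
class GapJunction:
    """Symmetric electrical coupling between neurons i and j (g in nS)."""

    i: int
    j: int
    g: float

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("self gap junctions are not allowed")
        if self.g < 0:
            raise ValueError("gap conductance must be non-negative")


@dataclass(frozen=True)
class PoissonSource:
    """Homogeneous Poisson spike source feeding one target neuron."""

    target: int
    rate: float  # spikes/s
    weight: float  # pA
    delay: float  # ms

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be non-negative")


class SpikeRingBuffer:
    """Per-neuron accumulated synaptic kick amplitudes by future grid step.

    Two (N, L) float arrays, one per receptor, indexed modulo L by absolute
    grid-step index. L must cover the longest delay plus one communication
    interval; slots are cleared once their grid point has been consumed by
    a final update.
    """

    def __init__(self, n_neurons: int, length: int):
        self.length = int(length)
        self.ex = np.zeros((n_neurons, self.length))
        self.inh = np.zeros((n_neurons, self.length))

    def add(self, targets, steps, amplitudes, excitatory) -> None:
        """Accumulate kicks for (target, absolute step) pairs."""
        slots = np.asarray(steps, dtype=np.int64) % self.length
        amplitudes = np.asarray(amplitudes, dtype=np.float64)
        exc = np.asarray(excitatory, dtype=bool)
        tgt = np.asarray(targets, dtype=np.int64)
        np.add.at(self.ex, (tgt[exc], slots[exc]), amplitudes[exc])
        np.add.at(self.inh, (tgt[~exc], slots[~exc]), amplitudes[~exc])

    def clear_steps(self, first_step: int, last_step: int) -> None:
        idx = np.arange(first_step, last_step + 1) % self.length
        self.ex[:, idx] = 0.0
        self.inh[:, idx] = 0.0


class Network:
    """Neurons plus their chemical, electrical and external connectivity.

    Parameters may be shared (a single :class:`NeuronParameters`) or given
    per neuron. Initial membrane potentials default to E_leak with gating
    variables at their steady state for the initial potential.
    """

    def __init__(
        self,
        n_neurons: int,
        params: NeuronParameters | list[NeuronParameters] = DEFAULT_PARAMETERS,
        d_min: float = 1.0,
    ):
        if n_neurons < 1:
            raise ValueError("need at least one neuron")
        if not d_min > 0:
            raise ValueError("d_min must be positive")
        self.n_neurons = int(n_neurons)
        self.d_min = float(d_min)
        if isinstance(params, NeuronParameters):
            self.params = [params] * self.n_neurons
        else:
            if len(params) != n_neurons:
                raise ValueError("one parameter set per neuron required")
            self.params = list(params)
        self.gap_junctions: list[GapJunction] = []
        self.synapses: list[ChemicalSynapse] = []
        self.poisson_sources: list[PoissonSource] = []
        self.initial_state = np.empty((self.n_neurons, NSTATE))
        self.set_initial_potentials(
            np.array([p.E_leak for p in self.params], dtype=np.float64)
        )

    # -- construction -----------------------------------------------------

    def set_initial_potentials(self, V) -> None:
        """Set per-neuron initial V; gates go to steady state for that V."""
        V = np.broadcast_to(np.asarray(V, dtype=np.float64), (self.n_neurons,))
        for i, v in enumerate(V):
            m, h, n, p = steady_state_gating(float(v))
            self.initial_state[i] = (v, m, h, n, p, 0.0, 0.0, 0.0, 0.0)

    def connect_gap(self, i: int, j: int, g: float) -> None:
        """Add a symmetric gap junction; duplicate pairs accumulate."""
        self._check_index(i)
        self._check_index(j)
        self.gap_junctions.append(GapJunction(i, j, g))

    def connect_chemical(
        self, source: int, target: int, weight: float, delay: float, receptor: str = ""
    ) -> None:
        self._check_index(source)
        self._check_index(target)
        if delay < self.d_min:
            raise ValueError(
                f"chemical delay {delay} ms below the minimal delay {self.d_min} ms"
            )
        self.synapses.append(ChemicalSynapse(source, target, weight, delay, receptor))

    def add_poisson(self, target: int, rate: float, weight: float, delay: float) -> None:
        self._check_index(target)
        if delay < self.d_min:
            raise ValueError("Poisson delay below the minimal delay")
        self.poisson_sources.append(PoissonSource(target, rate, weight, delay))

    def _check_index(self, i: int) -> None:
        if not 0 <= i < self.n_neurons:
            raise IndexError(f"neuron index {i} out of range")

    # -- derived quantities ----------------------------------------------

    def gap_matrix(self) -> sp.csr_matrix:
        """Symmetric (N, N) conductance matrix; duplicates accumulate."""
        if not self.gap_junctions:
            return sp.csr_matrix((self.n_neurons, self.n_neurons))
        ii = [gj.i for gj in self.gap_junctions] + [gj.j for gj in self.gap_junctions]
        jj = [gj.j for gj in self.gap_junctions] + [gj.i for gj in self.gap_junctions]
        gg = [gj.g for gj in self.gap_junctions] * 2
        return sp.csr_matrix(
            (gg, (ii, jj)), shape=(self.n_neurons, self.n_neurons)
        )

    def total_gap_conductance(self) -> np.ndarray:
        """Summed incoming gap conductance g_bar per neuron (nS)."""
        return np.asarray(self.gap_matrix().sum(axis=1)).ravel()

    def gap_degree(self) -> np.ndarray:
        m = self.gap_matrix()
        m.sum_duplicates()
        return np.diff(m.indptr)

    def validate_grid(self, h: float) -> None:
        """Check that d_min and every delay sit on the h-grid."""
        if not h > 0:
            raise ValueError("h must be positive")
        r = self.d_min / h
        if abs(r - round(r)) > 1e-9 or round(r) < 1:
            raise ValueError(f"d_min={self.d_min} is not an integer multiple of h={h}")
        for syn in self.synapses:
            q = syn.delay / h
            if abs(q - round(q)) > 1e-9:
                raise ValueError(f"delay {syn.delay} not on the h={h} grid")
        for src in self.poisson_sources:
            q = src.delay / h
            if abs(q - round(q)) > 1e-9:
                raise ValueError(f"delay {src.delay} not on the h={h} grid")

    # -- spike delivery ---------------------------------------------------

    def synapse_arrays(self, h: float):
        """CSR-style adjacency (per source) for spike delivery.

        Returns (indptr, targets, delay_steps, kick_amplitudes, excitatory)
        with synapses grouped by source neuron.
        """
        ns = len(self.synapses)
        src = np.array([s.source for s in self.synapses], dtype=np.int64)
        order = np.argsort(src, kind="stable")
        indptr = np.zeros(self.n_neurons + 1, dtype=np.int64)
        np.add.at(indptr, src + 1, 1)
        indptr = np.cumsum(indptr)
        tgt = np.empty(ns, dtype=np.int64)
        dst = np.empty(ns, dtype=np.int64)
        amp = np.empty(ns, dtype=np.float64)
        exc = np.empty(ns, dtype=bool)
        for k, idx in enumerate(order):
            s = self.synapses[idx]
            tgt[k] = s.target
            dst[k] = int(round(s.delay / h))
            tau = (
                self.params[s.target].tau_ex
                if s.receptor == "excitatory"
                else self.params[s.target].tau_in
            )
            amp[k] = _KICK_SCALE * s.weight / tau
            exc[k] = s.receptor == "excitatory"
        return indptr, tgt, dst, amp, exc

    def deliver_spikes(
        self, events, buffer: SpikeRingBuffer, h: float, synapse_arrays=None
    ) -> None:
        """Route spike events into the targets' ring buffers at lag d.

        ``events`` is an iterable of (source_id, grid_step) pairs; every
        spike lands in each chemical target's buffer exactly once at
        spike step + delay/h.
        """
        if synapse_arrays is None:
            synapse_arrays = self.synapse_arrays(h)
        indptr, tgt, dst, amp, exc = synapse_arrays
        for source, step in events:
            lo, hi = indptr[source], indptr[source + 1]
            if hi > lo:
                buffer.add(tgt[lo:hi], step + dst[lo:hi], amp[lo:hi], exc[lo:hi])

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        """Reproducible JSON dump of the full network description."""
        doc = {
            "n_neurons": self.n_neurons,
            "d_min": self.d_min,
            "params": [asdict(p) for p in self.params],
            "initial_state": self.initial_state.tolist(),
            "gap_junctions": [asdict(g) for g in self.gap_junctions],
            "synapses": [asdict(s) for s in self.synapses],
            "poisson_sources": [asdict(s) for s in self.poisson_sources],
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Network":
        doc = json.loads(text)
        net = cls(
            doc["n_neurons"],
            [NeuronParameters(**p) for p in doc["params"]],
            d_min=doc["d_min"],
        )
        net.initial_state = np.array(doc["initial_state"], dtype=np.float64)
        net.gap_junctions = [GapJunction(**g) for g in doc["gap_junctions"]]
        net.synapses = [ChemicalSynapse(**s) for s in doc["synapses"]]
        net.poisson_sources = [PoissonSource(**s) for s in doc["poisson_sources"]]
        return net


def build_poisson_trains(
    sources: list[PoissonSource], t_end: float, h: float, seed: int
):
    """Draw the external Poisson spike trains for a whole run.

    Each source gets an independent, reproducible stream (spawned from
    ``seed``). Emission times are homogeneous Poisson on (0, t_end],
    stamped on the h-grid. Returns (source_index, emission_step) arrays
    sorted by step within each source.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    n_steps = int(round(t_end / h))
    streams = np.random.SeedSequence(seed).spawn(len(sources))
    idx_out = []
    step_out = []
    for k, (src, ss) in enumerate(zip(sources, streams)):
        rng = np.random.default_rng(ss)
        n = rng.poisson(src.rate * t_end / 1000.0)
        steps = np.sort(rng.integers(1, n_steps + 1, size=n))
        idx_out.append(np.full(n, k, dtype=np.int64))
        step_out.append(steps.astype(np.int64))
    if idx_out:
        return np.concatenate(idx_out), np.concatenate(step_out)
    return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
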