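"""Hodgkin-Huxley point neuron with alpha-current synapses and gap coupling.

The model is the fast-spiking cortical interneuron of Mancilla et al. (2007,
J. Neurosci.), widely used to study synchronization of electrically coupled
interneuron pairs. It carries a transient sodium current (gates m, h), a
slow Kv1 and a fast Kv3 potassium current (gates n and p), and a leak:

    C_m dV/dt = -I_ionic(V, m, h, n, p) + I_ex + I_in + I_const + I_gap

    I_ionic = g_Na m^3 h (V - E_Na) + (g_Kv3 p^2 + g_Kv1 n^4)(V - E_K)
              + g_leak (V - E_leak)

Each gate obeys first-order kinetics dq/dt = alpha_q(V)(1-q) - beta_q(V) q.
Synaptic input enters as alpha-shaped currents, realized as two linear ODEs
per receptor driven by delta kicks of amplitude J*e/tau so that a single
spike of weight J produces a current peaking at exactly J one time constant
after arrival. Together with V this gives a system of nine ODEs per neuron.

The gap current received through electrical synapses is reduced to the
coupling parameters held by a :class:`~gapwave.wfr_engine.GapInputAccumulator`:

    I_gap = -g_bar * V + sum_m g_tilde[m] * x**m,   x in [0, 1]

where x is the fraction of the current computation step and the polynomial
interpolates the senders' membrane-potential waveforms.

A spike is emitted when the membrane potential crosses the threshold while
the neuron is not refractory; the spike time is stamped at the first grid
point after V reaches its maximum. Emitting a spike makes the neuron
refractory for tau_r (spiking suppressed, dynamics untouched).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from ._kernels import NSTATE

__all__ = [
    "NeuronParameters",
    "NeuronState",
    "SpikeEvent",
    "DEFAULT_PARAMETERS",
    "channel_rates",
    "steady_state_gating",
    "derivatives",
    "propagate_step",
    "detect_spike",
]


@dataclass(frozen=True)
class NeuronParameters:
    """Parameters of the gap-junction-capable HH point neuron.

    Units: capacitance pF, conductances nS, potentials mV, times ms,
    currents pA. Defaults are the published Mancilla et al. (2007)
    fast-spiking interneuron set.
    """

    C_m: float = 40.0
    g_Na: float = 4500.0
    g_Kv1: float = 9.0
    g_Kv3: float = 9000.0
    g_leak: float = 9.0
    E_Na: float = 74.0
    E_K: float = -90.0
    E_leak: float = -70.0
    tau_ex: float = 0.2
    tau_in: float = 2.0
    theta: float = 0.0
    tau_r: float = 2.0
    I_const: float = 0.0

    def __post_init__(self) -> None:
        if not self.C_m > 0:
            raise ValueError("C_m must be positive")
        for name in ("g_Na", "g_Kv1", "g_Kv3", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("tau_ex", "tau_in", "tau_r"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.C_m,
                self.g_Na,
                self.g_Kv1,
                self.g_Kv3,
                self.g_leak,
                self.E_Na,
                self.E_K,
                self.E_leak,
                self.tau_ex,
                self.tau_in,
                self.theta,
                self.tau_r,
                self.I_const,
            ],
            dtype=np.float64,
        )

    def with_(self, **kwargs) -> "NeuronParameters":
        return replace(self, **kwargs)


DEFAULT_PARAMETERS = NeuronParameters()


@dataclass
class NeuronState:
    """Dynamical state plus spike/refractory bookkeeping of one neuron."""

    V: float
    m: float
    h: float
    n: float
    p: float
    dI_ex: float = 0.0
    I_ex: float = 0.0
    dI_in: float = 0.0
    I_in: float = 0.0
    refractory_steps_left: int = 0
    crossed_threshold: bool = False
    V_prev_step: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if self.refractory_steps_left < 0:
            raise ValueError("refractory_steps_left must be >= 0")
        if math.isnan(self.V_prev_step):
            self.V_prev_step = self.V

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.V,
                self.m,
                self.h,
                self.n,
                self.p,
                self.dI_ex,
                self.I_ex,
                self.dI_in,
                self.I_in,
            ],
            dtype=np.float64,
        )

    @classmethod
    def from_array(cls, y: np.ndarray, **bookkeeping) -> "NeuronState":
        return cls(*[float(v) for v in y[:NSTATE]], **bookkeeping)

    @classmethod
    def resting(
        cls, params: NeuronParameters = DEFAULT_PARAMETERS, V: float | None = None
    ) -> "NeuronState":
        """State at potential V (default E_leak) with gates at steady state."""
        if V is None:
            V = params.E_leak
        m, h, n, p = steady_state_gating(V)
        return cls(V=float(V), m=m, h=h, n=n, p=p)


@dataclass(frozen=True)
class SpikeEvent:
    """A spike of neuron ``source_id`` stamped on the h-grid at ``time`` ms."""

    source_id: int
    time: float


def channel_rates(V: float):
    """Gate opening/closing rates (1/ms) at membrane potential V (mV).

    Returns (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n, alpha_p,
    beta_p); all are non-negative for finite V.
    """
    if not math.isfinite(V):
        raise ValueError(f"membrane potential must be finite, got {V}")
    return _kernels.channel_rates(float(V))


def steady_state_gating(V: float):
    """Steady-state values m_inf, h_inf, n_inf, p_inf at fixed V."""
    am, bm, ah, bh, an, bn, ap, bp = channel_rates(V)
    return (am / (am + bm), ah / (ah + bh), an / (an + bn), ap / (ap + bp))


def _gap_for_step(gap, order: int, step: int) -> tuple[float, np.ndarray]:
    if gap is None:
        return 0.0, np.zeros(order + 1)
    g_tilde = np.asarray(gap.g_tilde, dtype=np.float64)
    nc = order + 1
    if g_tilde.size == nc:
        gts = g_tilde
    else:
        gts = g_tilde[(step - 1) * nc : step * nc]
    if gts.size != nc:
        raise ValueError(
            f"gap accumulator holds {g_tilde.size} coefficients, "
            f"cannot index step {step} at order {order}"
        )
    return float(gap.g_bar), np.ascontiguousarray(gts)


def derivatives(
    state: NeuronState,
    x: float,
    gap,
    params: NeuronParameters = DEFAULT_PARAMETERS,
    order: int = 3,
    step: int = 1,
) -> np.ndarray:
    """Time derivatives of the nine state components.

    ``x`` is the fraction of the current computation step in [0, 1] at which
    the gap-coupling polynomial is evaluated; ``gap`` is a
    GapInputAccumulator (or None for an uncoupled neuron) indexed for
    ``step`` of the current interval.
    """
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite neuron state")
    gbar, gts = _gap_for_step(gap, order, step)
    dy = np.empty(NSTATE)
    _kernels.rhs(y, params.as_array(), gbar, gts, order, float(x), dy)
    return dy


def propagate_step(
    state: NeuronState,
    h: float,
    gap,
    params: NeuronParameters = DEFAULT_PARAMETERS,
    abs_tol: float = 1e-6,
    order: int = 3,
    step: int = 1,
    min_substep_fraction: float = 1e-8,
) -> tuple[NeuronState, float]:
    """Advance the neuron by one computation step h with adaptive RKF45.

    Returns the state at the right grid point and dV/dt there (needed for
    the cubic waveform coefficients). Deterministic: repeated calls with
    identical inputs are bitwise identical.

    Raises ``RuntimeError`` if the internal sub-step underflows
    ``h * min_substep_fraction``.
    """
    if not h > 0:
        raise ValueError("h must be positive")
    if not abs_tol > 0:
        raise ValueError("abs_tol must be positive")
    y = state.as_array()
    gbar, gts = _gap_for_step(gap, order, step)
    p = params.as_array()
    status, _ = _kernels.rkf45_propagate(
        y, p, gbar, gts, order, float(h), float(abs_tol),
        h * min_substep_fraction, float(h),
    )
    if status != 0:
        raise RuntimeError("RKF45 sub-step underflow while covering one step h")
    dy = np.empty(NSTATE)
    _kernels.rhs(y, p, gbar, gts, order, 1.0, dy)
    new = NeuronState.from_array(
        y,
        refractory_steps_left=state.refractory_steps_left,
        crossed_threshold=state.crossed_threshold,
        V_prev_step=state.V,
    )
    return new, float(dy[0])


def detect_spike(
    state: NeuronState,
    step_index: int,
    params: NeuronParameters = DEFAULT_PARAMETERS,
    h: float = 0.1,
    source_id: int = 0,
) -> SpikeEvent | None:
    """Grid-point spike test; call once per grid point of final updates.

    ``state.V`` must hold the potential at grid point ``step_index`` and
    ``state.V_prev_step`` the potential one grid point earlier. An upward
    threshold crossing while not refractory arms the detector; the spike is
    stamped at the first grid point where V decreases relative to the
    previous grid point, after which the neuron is refractory for tau_r
    (``round(tau_r / h)`` grid steps). Mutates the bookkeeping fields.
    """
    spike = None
    if state.refractory_steps_left > 0:
        state.refractory_steps_left -= 1
    else:
        if not state.crossed_threshold and state.V > params.theta:
            state.crossed_threshold = True
        if state.crossed_threshold and state.V < state.V_prev_step:
            spike = SpikeEvent(source_id=source_id, time=step_index * h)
            state.crossed_threshold = False
            state.refractory_steps_left = int(round(params.tau_r / h))
    return spike
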