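"""Jacobi waveform relaxation for gap-junction coupled neuron networks.

The network ODE system is partitioned into one subsystem per neuron. Over
each communication interval the subsystems are solved independently, with
the gap-coupled partners' membrane potentials represented by piecewise
polynomials (order 0, 1 or 3) interpolating the previous iteration's
trajectory. Iterations repeat until the maximum change of any grid-point
potential between successive iterations falls below ``prelim_tol`` (checked
as: a point violates convergence when ``|V_last - V| >= prelim_tol``) or an
iteration cap is hit, after which a single final update emits spikes and
broadcasts a constant extrapolation as the initial guess of the next
interval. Preliminary iterations never emit spikes, so the set of spikes
delivered in an interval is identical across its iterations.

Two communication strategies are provided: exchanging waveforms once per
minimal synaptic delay (T = d_min, one communication per delay) or once per
computation step (T = h, faster convergence, more communications). The
classical single-step baseline — partner potentials frozen at their
start-of-step values, no iteration — is the T = h schedule with zero
preliminary iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from ._kernels import NSTATE
from .network import Network, SpikeRingBuffer, build_poisson_trains, _KICK_SCALE

__all__ = [
    "InterpolationWaveform",
    "GapInputAccumulator",
    "CommunicationSchedule",
    "IterationControl",
    "SimulationConfig",
    "SimulationResult",
    "Simulator",
    "interpolation_coefficients",
    "handle_gap_event",
    "convergence_check",
    "reference_solve",
    "communication_counts",
    "crossover_r",
    "payload_size",
]

_ORDERS = (0, 1, 3)


def interpolation_coefficients(order, V0, V1=None, V0p=None, V1p=None, h=None):
    """Polynomial coefficients (a_0, ..., a_order) for one step.

    The membrane potential within a step is V((s+x) h) = sum_m a_m x^m with
    x in [0, 1]. Order 0 holds the left value, order 1 the secant, order 3
    the cubic Hermite polynomial through both endpoint values and
    derivatives (the derivative terms enter scaled by h).
    """
    if order not in _ORDERS:
        raise ValueError(f"interpolation order must be one of {_ORDERS}, got {order}")
    if order == 0:
        return (V0,)
    if V1 is None:
        raise ValueError("V1 required for order >= 1")
    if order == 1:
        return (V0, V1 - V0)
    if V0p is None or V1p is None or h is None:
        raise ValueError("V0p, V1p and h required for order 3")
    return (
        V0,
        h * V0p,
        -3.0 * V0 + 3.0 * V1 - h * (2.0 * V0p + V1p),
        2.0 * V0 - 2.0 * V1 + h * (V0p + V1p),
    )


@dataclass
class InterpolationWaveform:
    """Piecewise-polynomial membrane-potential trajectory over one interval.

    ``coefficients`` is flat with (order + 1) values per step s = 1..r'.
    """

    order: int
    coefficients: np.ndarray
    h: float
    t_left: float = 0.0

    def __post_init__(self):
        if self.order not in _ORDERS:
            raise ValueError(f"unsupported interpolation order {self.order}")
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.size % (self.order + 1):
            raise ValueError("coefficient array length must be r' * (order + 1)")

    @property
    def n_steps(self) -> int:
        return self.coefficients.size // (self.order + 1)

    @classmethod
    def from_grid(cls, order, values, derivatives=None, h=1.0, t_left=0.0):
        """Build the waveform from grid values (and derivatives, order 3)."""
        values = np.asarray(values, dtype=np.float64)
        r = values.size - 1
        nc = order + 1
        coeffs = np.empty(r * nc)
        for s in range(r):
            coeffs[s * nc : (s + 1) * nc] = interpolation_coefficients(
                order,
                values[s],
                values[s + 1],
                None if derivatives is None else derivatives[s],
                None if derivatives is None else derivatives[s + 1],
                h,
            )
        return cls(order, coeffs, h, t_left)

    def __call__(self, t):
        """Evaluate the waveform at absolute time(s) t."""
        t = np.asarray(t, dtype=np.float64)
        x_all = (t - self.t_left) / self.h
        s = np.clip(np.floor(x_all).astype(np.int64), 0, self.n_steps - 1)
        x = x_all - s
        nc = self.order + 1
        c = self.coefficients.reshape(self.n_steps, nc)
        out = np.zeros_like(x_all)
        for m in range(nc - 1, -1, -1):
            out = out * x + c[s, m]
        return out


@dataclass
class GapInputAccumulator:
    """Reduced gap coupling received by one neuron for one interval.

    ``g_bar`` is the summed incoming conductance and ``g_tilde[i]`` the
    conductance-weighted sum of the senders' interpolation coefficients,
    laid out as in the waveform (N_coeff = r' * (order + 1) values).
    """

    g_bar: float = 0.0
    g_tilde: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self):
        self.g_tilde = np.asarray(self.g_tilde, dtype=np.float64)

    @classmethod
    def zeros(cls, n_coeff: int) -> "GapInputAccumulator":
        return cls(0.0, np.zeros(n_coeff))

    def reset(self) -> None:
        self.g_bar = 0.0
        self.g_tilde[:] = 0.0


def handle_gap_event(
    acc: GapInputAccumulator, weight: float, coefficients
) -> GapInputAccumulator:
    """Fold one incoming waveform event into the receiver's accumulator.

    Accumulates g_bar += g_ij and g_tilde[i] += g_ij * coefficients[i].
    """
    coefficients = np.asarray(coefficients, dtype=np.float64)
    if coefficients.shape != acc.g_tilde.shape:
        raise ValueError(
            f"event carries {coefficients.size} coefficients, receiver expects "
            f"{acc.g_tilde.size}"
        )
    acc.g_bar += weight
    acc.g_tilde += weight * coefficients
    return acc


def convergence_check(V_new, V_last, prelim_tol: float) -> bool:
    """Stopping test of the iteration control for one neuron.

    True iff no grid point violates ``|V_last - V_new| >= prelim_tol``.
    ``V_last`` is overwritten with ``V_new`` in place.
    """
    V_new = np.asarray(V_new, dtype=np.float64)
    if V_new.shape != V_last.shape:
        raise ValueError("grid mismatch between iterations")
    ok = bool(np.all(np.abs(V_last - V_new) < prelim_tol))
    V_last[:] = V_new
    return ok


@dataclass(frozen=True)
class CommunicationSchedule:
    """Timing of waveform exchanges: step h, minimal delay, strategy T."""

    h: float
    d_min: float
    strategy: str = "dmin"  # 'dmin' | 'h' | 'single-step'

    def __post_init__(self):
        if self.strategy not in ("dmin", "h", "single-step"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        r = self.d_min / self.h
        if not self.h > 0 or abs(r - round(r)) > 1e-9 or round(r) < 1:
            raise ValueError("d_min must be a positive integer multiple of h")

    @property
    def r(self) -> int:
        """Computation steps per minimal-delay interval."""
        return int(round(self.d_min / self.h))

    @property
    def interval_steps(self) -> int:
        """Computation steps per iteration interval (1 for T = h)."""
        return self.r if self.strategy == "dmin" else 1


@dataclass
class IterationControl:
    """Adaptive stopping of the relaxation iterations.

    Iterate until every neuron's grid-point potentials changed by less than
    ``prelim_tol`` (mV) since the previous iteration, capped at
    ``max_num_prelim_iterations`` (a cap hit raises a warning counter, not
    an error). ``fixed_iterations`` disables the adaptive test and runs an
    exact number of preliminary iterations instead.
    """

    prelim_tol: float = 1e-4
    max_num_prelim_iterations: int = 15
    fixed_iterations: int | None = None


@dataclass(frozen=True)
class SimulationConfig:
    """Full numerical configuration of one simulation run."""

    h: float = 0.05  # computation step (ms)
    order: int = 3  # waveform interpolation order: 0, 1 or 3
    strategy: str = "dmin"  # 'dmin' | 'h' | 'single-step'
    prelim_tol: float = 1e-4  # convergence tolerance (mV)
    max_iterations: int = 15
    fixed_iterations: int | None = None
    abs_tol: float = 1e-6  # RKF45 absolute accuracy per step
    min_substep_fraction: float = 1e-8
    v_last_reset: str = "zero"  # 'zero' (reference behavior) | 'current'
    record_v: object = "all"  # 'all' | sequence of ids | None
    record_stride: int = 1
    seed: int = 1

    def __post_init__(self):
        if self.order not in _ORDERS:
            raise ValueError(f"interpolation order must be one of {_ORDERS}")
        if self.strategy not in ("dmin", "h", "single-step"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.v_last_reset not in ("zero", "current"):
            raise ValueError("v_last_reset must be 'zero' or 'current'")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SimulationResult:
    """Grid traces, spikes and iteration bookkeeping of one run."""

    times: np.ndarray  # recorded grid times (ms)
    voltages: np.ndarray  # (n_recorded, len(times)) membrane potentials
    recorded_ids: np.ndarray
    spike_senders: np.ndarray
    spike_times: np.ndarray  # ms, on the h-grid
    iterations: np.ndarray  # preliminary iterations used per interval
    cap_warnings: int  # intervals terminated by the iteration cap
    t_end: float
    config: SimulationConfig

    @property
    def mean_iterations(self) -> float:
        return float(np.mean(self.iterations)) if self.iterations.size else 0.0

    @property
    def max_iterations_used(self) -> int:
        return int(np.max(self.iterations)) if self.iterations.size else 0

    def trace(self, neuron_id: int):
        """(times, values) pair for one recorded neuron."""
        pos = np.where(self.recorded_ids == neuron_id)[0]
        if pos.size == 0:
            raise KeyError(f"neuron {neuron_id} was not recorded")
        return self.times, self.voltages[pos[0]]

    def spike_train(self, neuron_id: int) -> np.ndarray:
        return self.spike_times[self.spike_senders == neuron_id]


class Simulator:
    """Time-driven scheduler running the waveform-relaxation loop.

    The per-interval cycle follows the reference scheduler semantics:
    deliver the waveforms broadcast at the end of the previous interval,
    run preliminary updates (Jacobi: every update of iteration k reads only
    waveforms produced in iteration k-1) until converged or capped, then
    run exactly one final update that advances the state, emits spikes and
    broadcasts the constant extrapolation. With strategy 'single-step' the
    preliminary loop is skipped entirely.
    """

    def __init__(self, network: Network, config: SimulationConfig):
        network.validate_grid(config.h)
        self.network = network
        self.config = config
        self.schedule = CommunicationSchedule(config.h, network.d_min, config.strategy)
        self.control = IterationControl(
            config.prelim_tol, config.max_iterations, config.fixed_iterations
        )
        self._params = np.stack([p.as_array() for p in network.params])
        self._G = network.gap_matrix()
        self._G.sum_duplicates()
        self._gbar = np.asarray(self._G.sum(axis=1)).ravel()
        self._prelim_mask = self._gbar > 0
        self._refr_steps = np.array(
            [int(round(p.tau_r / config.h)) for p in network.params], dtype=np.int64
        )
        # debug hook: when a list, each preliminary iteration appends
        # (g_tilde inputs read, coefficients produced)
        self.debug_capture = None

    # -- pieces of the interval loop -------------------------------------

    def _exchange(self, coeffs: np.ndarray) -> np.ndarray:
        """Jacobi waveform exchange: accumulate g_tilde = G @ coefficients."""
        return self._G.dot(coeffs)

    def run(self, t_end: float) -> SimulationResult:
        """Simulate ``t_end`` ms of biological time.

        Uses a compiled multi-interval driver; when ``debug_capture`` is a
        list, falls back to the interval-by-interval Python loop (same
        kernels, bitwise-identical results) and appends per-iteration
        (g_tilde_in, coefficients_out) snapshots to it.
        """
        setup = self._prepare(t_end)
        if self.debug_capture is not None:
            return self._run_python(t_end, setup)
        return self._run_chunked(t_end, setup)

    def _prepare(self, t_end: float) -> dict:
        cfg = self.config
        net = self.network
        h = cfg.h
        n_steps = int(round(t_end / h))
        if abs(n_steps * h - t_end) > 1e-9 or n_steps < 1:
            raise ValueError("t_end must be a positive multiple of h")
        rp = self.schedule.interval_steps
        if n_steps % rp:
            raise ValueError("t_end must cover whole communication intervals")
        nc = cfg.order + 1
        n_coeff = rp * nc
        N = net.n_neurons

        y = net.initial_state.copy()
        # constant initial waveform guess: the initial membrane potential
        coeffs = np.zeros((N, n_coeff))
        coeffs[:, ::nc] = y[:, [0]]
        gt = self._exchange(coeffs)
        V_last = np.zeros((N, rp))

        syn_arrays = net.synapse_arrays(h)
        max_delay_steps = rp
        if net.synapses:
            max_delay_steps = max(max_delay_steps, int(np.max(syn_arrays[2])))
        pois_delay_steps = np.array(
            [int(round(s.delay / h)) for s in net.poisson_sources], dtype=np.int64
        )
        if pois_delay_steps.size:
            max_delay_steps = max(max_delay_steps, int(np.max(pois_delay_steps)))
        buffer = SpikeRingBuffer(N, max_delay_steps + rp + 1)

        # external Poisson drive for the whole run, delivered at emission + d
        if net.poisson_sources:
            src_idx, emit_steps = build_poisson_trains(
                net.poisson_sources, t_end, h, cfg.seed
            )
            pois_tgt = np.array(
                [s.target for s in net.poisson_sources], dtype=np.int64
            )[src_idx]
            pois_amp = np.array(
                [
                    _KICK_SCALE
                    * s.weight
                    / (
                        net.params[s.target].tau_ex
                        if s.weight >= 0
                        else net.params[s.target].tau_in
                    )
                    for s in net.poisson_sources
                ]
            )[src_idx]
            pois_exc = np.array(
                [s.weight >= 0 for s in net.poisson_sources], dtype=bool
            )[src_idx]
            arrive = emit_steps + pois_delay_steps[src_idx]
            order_arr = np.argsort(arrive, kind="stable")
            arrive = arrive[order_arr]
            pois_tgt = pois_tgt[order_arr]
            pois_amp = pois_amp[order_arr]
            pois_exc = pois_exc[order_arr]
        else:
            arrive = np.empty(0, dtype=np.int64)
            pois_tgt = np.empty(0, dtype=np.int64)
            pois_amp = np.empty(0, dtype=np.float64)
            pois_exc = np.empty(0, dtype=bool)
        pois_ptr = 0

        if cfg.record_v is None:
            rec_ids = np.empty(0, dtype=np.int64)
        elif isinstance(cfg.record_v, str) and cfg.record_v == "all":
            rec_ids = np.arange(N, dtype=np.int64)
        else:
            rec_ids = np.asarray(cfg.record_v, dtype=np.int64)
        stride = int(cfg.record_stride)
        rec_steps = np.arange(0, n_steps + 1, stride)
        voltages = np.empty((rec_ids.size, rec_steps.size))
        if rec_ids.size:
            voltages[:, 0] = y[rec_ids, 0]

        return dict(
            n_steps=n_steps, rp=rp, nc=nc, n_coeff=n_coeff, N=N, y=y,
            coeffs=coeffs, gt=gt, V_last=V_last, syn_arrays=syn_arrays,
            buffer=buffer, arrive=arrive, pois_tgt=pois_tgt,
            pois_amp=pois_amp, pois_exc=pois_exc, rec_ids=rec_ids,
            rec_steps=rec_steps, voltages=voltages,
        )

    def _result(self, t_end, setup, senders, steps_all, iterations, cap_warnings):
        order_sp = np.lexsort((senders, steps_all))
        return SimulationResult(
            times=setup["rec_steps"] * self.config.h,
            voltages=setup["voltages"],
            recorded_ids=setup["rec_ids"],
            spike_senders=senders[order_sp],
            spike_times=steps_all[order_sp] * self.config.h,
            iterations=iterations,
            cap_warnings=cap_warnings,
            t_end=t_end,
            config=self.config,
        )

    def _run_chunked(self, t_end: float, setup: dict) -> SimulationResult:
        cfg = self.config
        h = cfg.h
        N = setup["N"]
        rp = setup["rp"]
        n_steps = setup["n_steps"]
        buffer = setup["buffer"]
        L = buffer.length
        y, coeffs, gt, V_last = (
            setup["y"], setup["coeffs"], setup["gt"], setup["V_last"],
        )
        rec_ids, rec_steps, voltages = (
            setup["rec_ids"], setup["rec_steps"], setup["voltages"],
        )
        indptr, tgt, dst, amp, exc = setup["syn_arrays"]
        G = self._G
        single_step = cfg.strategy == "single-step"
        adaptive = self.control.fixed_iterations is None
        cap = (
            self.control.max_num_prelim_iterations
            if adaptive
            else self.control.fixed_iterations
        )
        has_gaps = bool(self._prelim_mask.any())

        refr = np.zeros(N, dtype=np.int64)
        crossed = np.zeros(N, dtype=np.bool_)
        vprev = y[:, 0].copy()
        dt_carry = np.full(N, h)
        n_intervals = n_steps // rp
        iterations = np.zeros(n_intervals, dtype=np.int64)
        chunk_intervals = max(1, 4096 // rp)
        chunk_steps = chunk_intervals * rp
        min_refr = max(1, int(np.min(self._refr_steps)))
        spike_cap = N * (chunk_steps // min_refr + 2)
        spike_n = np.empty(spike_cap, dtype=np.int64)
        spike_step = np.empty(spike_cap, dtype=np.int64)
        vtrace_chunk = np.empty((N, chunk_steps))
        senders_parts: list[np.ndarray] = []
        steps_parts: list[np.ndarray] = []
        cap_warnings = 0
        pois_ptr = 0
        interval0 = 0
        while interval0 < n_intervals:
            m = min(chunk_intervals, n_intervals - interval0)
            k0 = interval0 * rp
            status, pois_ptr, nsp, warns = _kernels.run_chunk(
                y, self._params, self._prelim_mask, has_gaps, single_step,
                rp, cfg.order, h, cfg.abs_tol, h * cfg.min_substep_fraction,
                k0, m, L, self._gbar, gt, coeffs, V_last, cfg.prelim_tol,
                cfg.v_last_reset == "current", adaptive, cap,
                buffer.ex, buffer.inh,
                G.indptr, G.indices, G.data,
                refr, crossed, vprev, self._refr_steps, dt_carry,
                indptr, tgt, dst, amp, exc,
                setup["pois_tgt"], setup["arrive"], setup["pois_amp"],
                setup["pois_exc"], pois_ptr,
                vtrace_chunk, spike_n, spike_step,
                iterations[interval0 : interval0 + m],
            )
            if status == 1:
                raise RuntimeError("RKF45 sub-step underflow")
            if status == 2:  # pragma: no cover - capacity bound is generous
                raise RuntimeError("spike buffer overflow")
            cap_warnings += warns
            if nsp:
                senders_parts.append(spike_n[:nsp].copy())
                steps_parts.append(spike_step[:nsp].copy())
            if rec_ids.size:
                lo = np.searchsorted(rec_steps, k0 + 1)
                hi = np.searchsorted(rec_steps, k0 + m * rp, side="right")
                if hi > lo:
                    cols = rec_steps[lo:hi] - (k0 + 1)
                    voltages[:, lo:hi] = vtrace_chunk[np.ix_(rec_ids, cols)]
            interval0 += m
        senders = (
            np.concatenate(senders_parts)
            if senders_parts
            else np.empty(0, np.int64)
        )
        steps_all = (
            np.concatenate(steps_parts) if steps_parts else np.empty(0, np.int64)
        )
        return self._result(t_end, setup, senders, steps_all, iterations, cap_warnings)

    def _run_python(self, t_end: float, setup: dict) -> SimulationResult:
        cfg = self.config
        net = self.network
        h = cfg.h
        N = setup["N"]
        rp = setup["rp"]
        n_steps = setup["n_steps"]
        buffer = setup["buffer"]
        y, coeffs, gt, V_last = (
            setup["y"], setup["coeffs"], setup["gt"], setup["V_last"],
        )
        rec_ids, rec_steps, voltages = (
            setup["rec_ids"], setup["rec_steps"], setup["voltages"],
        )
        arrive = setup["arrive"]
        pois_tgt, pois_amp, pois_exc = (
            setup["pois_tgt"], setup["pois_amp"], setup["pois_exc"],
        )
        syn_arrays = setup["syn_arrays"]
        pois_ptr = 0

        refr = np.zeros(N, dtype=np.int64)
        crossed = np.zeros(N, dtype=np.bool_)
        vprev = y[:, 0].copy()
        dt_carry = np.full(N, h)
        spike_flags = np.zeros((N, rp), dtype=np.int8)
        vtrace = np.empty((N, rp))
        done = np.zeros(N, dtype=np.bool_)
        single_step = cfg.strategy == "single-step"
        adaptive = self.control.fixed_iterations is None

        spike_senders: list[np.ndarray] = []
        spike_steps: list[np.ndarray] = []
        iterations = np.zeros(n_steps // rp, dtype=np.int64)
        cap_warnings = 0
        L = buffer.length

        for interval, k0 in enumerate(range(0, n_steps, rp)):
            # deliver external input arriving within (k0, k0 + rp]
            hi = np.searchsorted(arrive, k0 + rp, side="right")
            if hi > pois_ptr:
                sl = slice(pois_ptr, hi)
                buffer.add(pois_tgt[sl], arrive[sl], pois_amp[sl], pois_exc[sl])
                pois_ptr = hi

            if not single_step and self._prelim_mask.any():
                cap = (
                    self.control.fixed_iterations
                    if not adaptive
                    else self.control.max_num_prelim_iterations
                )
                used = cap
                converged = not adaptive
                for i in range(1, cap + 1):
                    gt_in = gt.copy() if self.debug_capture is not None else None
                    st = _kernels.update_interval(
                        True, y, self._params, self._prelim_mask, rp, cfg.order, h,
                        cfg.abs_tol, h * cfg.min_substep_fraction, k0, L,
                        self._gbar, gt, buffer.ex, buffer.inh,
                        V_last, cfg.prelim_tol, cfg.v_last_reset == "current",
                        coeffs, refr, crossed, vprev, self._refr_steps,
                        spike_flags, vtrace, done, dt_carry,
                    )
                    if st:
                        raise RuntimeError("RKF45 sub-step underflow")
                    gt = self._exchange(coeffs)
                    if self.debug_capture is not None:
                        # inputs read by this iteration and waveforms it produced
                        self.debug_capture.append((gt_in, coeffs.copy()))
                    if adaptive and bool(done.all()):
                        used = i
                        converged = True
                        break
                iterations[interval] = used
                if adaptive and not converged:
                    cap_warnings += 1

            spike_flags[:] = 0
            st = _kernels.update_interval(
                False, y, self._params, self._prelim_mask, rp, cfg.order, h,
                cfg.abs_tol, h * cfg.min_substep_fraction, k0, L,
                self._gbar, gt, buffer.ex, buffer.inh,
                V_last, cfg.prelim_tol, cfg.v_last_reset == "current",
                coeffs, refr, crossed, vprev, self._refr_steps,
                spike_flags, vtrace, done, dt_carry,
            )
            if st:
                raise RuntimeError("RKF45 sub-step underflow")
            gt = self._exchange(coeffs)

            if rec_ids.size:
                # recorded grid points falling in (k0, k0 + rp]
                lo = np.searchsorted(rec_steps, k0 + 1)
                hi_r = np.searchsorted(rec_steps, k0 + rp, side="right")
                if hi_r > lo:
                    cols = rec_steps[lo:hi_r] - (k0 + 1)
                    voltages[:, lo:hi_r] = vtrace[np.ix_(rec_ids, cols)]

            if spike_flags.any():
                nn, ss = np.nonzero(spike_flags)
                steps = k0 + 1 + ss
                spike_senders.append(nn.astype(np.int64))
                spike_steps.append(steps.astype(np.int64))
                net.deliver_spikes(zip(nn, steps), buffer, h, syn_arrays)

            buffer.clear_steps(k0 + 1, k0 + rp)

        senders = (
            np.concatenate(spike_senders) if spike_senders else np.empty(0, np.int64)
        )
        steps_all = (
            np.concatenate(spike_steps) if spike_steps else np.empty(0, np.int64)
        )
        return self._result(t_end, setup, senders, steps_all, iterations, cap_warnings)


def simulate(network: Network, t_end: float, **config_kwargs) -> SimulationResult:
    """Convenience wrapper: build a Simulator and run it."""
    return Simulator(network, SimulationConfig(**config_kwargs)).run(t_end)


# -- monolithic reference oracle ------------------------------------------


def reference_solve(
    network: Network,
    t_end: float,
    h: float,
    tol: float = 1e-10,
    seed: int = 1,
    method: str = "DOP853",
):
    """Solve the entire coupled network as one ODE system (ground truth).

    All 9N equations, with the exact instantaneous gap coupling
    g_ij (V_j - V_i), are integrated monolithically at tight tolerance and
    sampled on the h-grid. Intended for small networks only. Synaptic
    events (external Poisson input and recurrently emitted spikes, detected
    with the same grid rule as the time-driven scheduler) are handled by
    restarting the integration at the grid points where kicks arrive.

    Returns a SimulationResult (iterations empty).
    """
    N = network.n_neurons
    network.validate_grid(h)
    n_steps = int(round(t_end / h))
    params = np.stack([p.as_array() for p in network.params])
    G = network.gap_matrix().toarray()
    gbar = G.sum(axis=1)

    def full_rhs(t, yflat):
        y = yflat.reshape(N, NSTATE)
        dy = np.empty_like(y)
        V = y[:, 0]
        gap = G.dot(V) - gbar * V
        z = np.empty(NSTATE)
        gts = np.zeros(1)
        for i in range(N):
            _kernels.rhs(y[i], params[i], 0.0, gts, 0, 0.0, z)
            dy[i] = z
            dy[i, 0] += gap[i] / params[i, 0]
        return dy.ravel()

    y0 = network.initial_state.copy()
    times = np.arange(n_steps + 1) * h
    has_events = bool(network.synapses) or bool(network.poisson_sources)
    if not has_events:
        sol = solve_ivp(
            full_rhs, (0.0, t_end), y0.ravel(), t_eval=times,
            rtol=tol, atol=tol, method=method,
        )
        if not sol.success:
            raise RuntimeError(f"reference solver failed: {sol.message}")
        V_grid = sol.y.reshape(N, NSTATE, -1)[:, 0, :]
        final_states = sol.y[:, -1].reshape(N, NSTATE)
        senders, steps = _grid_spikes(V_grid, network, h)
    else:
        V_grid, senders, steps = _reference_stepwise(
            network, full_rhs, y0, n_steps, h, tol, seed, method
        )
    order_sp = np.lexsort((senders, steps))
    return SimulationResult(
        times=times,
        voltages=V_grid,
        recorded_ids=np.arange(N, dtype=np.int64),
        spike_senders=senders[order_sp],
        spike_times=steps[order_sp] * h,
        iterations=np.empty(0, dtype=np.int64),
        cap_warnings=0,
        t_end=t_end,
        config=SimulationConfig(h=h, seed=seed),
    )


def _grid_spikes(V_grid, network, h):
    """Apply the grid spike rule to fully computed voltage traces."""
    from .hh_neuron import NeuronState, detect_spike

    senders, steps = [], []
    for i in range(network.n_neurons):
        st = NeuronState.from_array(network.initial_state[i])
        for k in range(1, V_grid.shape[1]):
            st.V_prev_step = st.V
            st.V = V_grid[i, k]
            ev = detect_spike(st, k, network.params[i], h, source_id=i)
            if ev is not None:
                senders.append(i)
                steps.append(k)
    return np.array(senders, dtype=np.int64), np.array(steps, dtype=np.int64)


def _reference_stepwise(network, full_rhs, y0, n_steps, h, tol, seed, method):
    """Grid-step-wise monolithic integration with synaptic kick injection."""
    from .hh_neuron import NeuronState, detect_spike

    N = network.n_neurons
    syn_arrays = network.synapse_arrays(h)
    max_delay = n_steps + 1
    buffer = SpikeRingBuffer(N, max_delay + 2)
    if network.poisson_sources:
        src_idx, emit = build_poisson_trains(network.poisson_sources, n_steps * h, h, seed)
        tgt = np.array([s.target for s in network.poisson_sources], dtype=np.int64)
        dly = np.array(
            [int(round(s.delay / h)) for s in network.poisson_sources], dtype=np.int64
        )
        amp = np.array(
            [
                _KICK_SCALE
                * s.weight
                / (
                    network.params[s.target].tau_ex
                    if s.weight >= 0
                    else network.params[s.target].tau_in
                )
                for s in network.poisson_sources
            ]
        )
        exc = np.array([s.weight >= 0 for s in network.poisson_sources], dtype=bool)
        buffer.add(tgt[src_idx], emit + dly[src_idx], amp[src_idx], exc[src_idx])
    y = y0.copy()
    V_grid = np.empty((N, n_steps + 1))
    V_grid[:, 0] = y[:, 0]
    detectors = [NeuronState.from_array(y[i]) for i in range(N)]
    senders, steps = [], []
    for k in range(1, n_steps + 1):
        sol = solve_ivp(
            full_rhs, ((k - 1) * h, k * h), y.ravel(), rtol=tol, atol=tol,
            method=method,
        )
        if not sol.success:
            raise RuntimeError(f"reference solver failed: {sol.message}")
        y = sol.y[:, -1].reshape(N, NSTATE).copy()
        slot = k % buffer.length
        y[:, 5] += buffer.ex[:, slot]
        y[:, 7] += buffer.inh[:, slot]
        V_grid[:, k] = y[:, 0]
        new_events = []
        for i in range(N):
            st = detectors[i]
            st.V_prev_step = st.V
            st.V = y[i, 0]
            ev = detect_spike(st, k, network.params[i], h, source_id=i)
            if ev is not None:
                senders.append(i)
                steps.append(k)
                new_events.append((i, k))
        if new_events:
            network.deliver_spikes(new_events, buffer, h, syn_arrays)
    return V_grid, np.array(senders, dtype=np.int64), np.array(steps, dtype=np.int64)


# -- communication analytics (analytic helpers) -----------------------------


def communication_counts(iter_h, iter_dmin, r, C_dmin=1.0):
    """Total per-step-strategy communications C_h ~ (i_h / i_dmin) r C_dmin."""
    if min(iter_h, iter_dmin, r, C_dmin) <= 0:
        raise ValueError("all inputs must be positive")
    return iter_h / iter_dmin * r * C_dmin


def crossover_r(iter_h, iter_dmin, max_r: int = 10_000) -> int:
    """Smallest integer r for which C_h exceeds C_dmin."""
    for r in range(1, max_r + 1):
        if communication_counts(iter_h, iter_dmin, r) > 1.0:
            return r
    raise ValueError("no crossover found below max_r")


def payload_size(r: int, order: int) -> int:
    """Waveform payload per neuron per communication: r (order+1) doubles."""
    if r < 1:
        raise ValueError("r must be >= 1")
    if order not in _ORDERS:
        raise ValueError(f"order must be one of {_ORDERS}")
    return r * (order + 1) * 8
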