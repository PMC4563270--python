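"""Accuracy and network-state measures.

All measures operate on membrane-potential traces sampled on a time grid,
treated as piecewise linear between grid points:

* ``rmse`` — root-mean-square deviation from a reference trace, with the
  integral evaluated exactly for the piecewise-linear interpolant.
* ``temporal_displacement`` — the time shift delta in [0, tau_max] that
  minimizes the RMSE between a trace and its reference; quantifies the
  systematic phase error of an integration scheme. Misleading for strictly
  periodic signals (a shift of one period is invisible), so use it on
  windows shorter than the signal period structure allows.
* ``synchrony_chi`` — ratio of the temporal standard deviation of the
  population-mean potential to the root-mean-square single-cell standard
  deviation; 1 for a fully synchronized network, near 1/sqrt(N) for N
  independent cells.
* ``spike_rate`` / ``average_rate`` — count-based firing rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "Trace",
    "rmse",
    "temporal_displacement",
    "synchrony_chi",
    "spike_rate",
    "average_rate",
]


@dataclass
class Trace:
    """A sampled membrane-potential time course (times ms, values mV)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if self.times.size < 2:
            raise ValueError("a trace needs at least two grid points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def _as_trace(obj) -> Trace:
    if isinstance(obj, Trace):
        return obj
    times, values = obj
    return Trace(times, values)


def _rmse_from_diff(times: np.ndarray, dv: np.ndarray) -> float:
    # exact integral of the squared piecewise-linear difference
    dt = np.diff(times)
    T = times[-1] - times[0]
    s = np.sum(dt * (dv[:-1] ** 2 + dv[1:] ** 2 + dv[:-1] * dv[1:]))
    return float(np.sqrt(s / (3.0 * T)))


def rmse(trace, reference) -> float:
    """RMS deviation (mV) of ``trace`` from ``reference``.

    If the grids differ, the reference is resampled onto the trace grid by
    linear interpolation; the trace grid must lie inside the reference
    grid, otherwise an error is raised.
    """
    trace = _as_trace(trace)
    reference = _as_trace(reference)
    if trace.times.shape == reference.times.shape and np.allclose(
        trace.times, reference.times
    ):
        ref_vals = reference.values
    else:
        if (
            trace.times[0] < reference.times[0] - 1e-12
            or trace.times[-1] > reference.times[-1] + 1e-12
        ):
            raise ValueError("trace grid extends beyond the reference grid")
        ref_vals = np.interp(trace.times, reference.times, reference.values)
    return _rmse_from_diff(trace.times, ref_vals - trace.values)


def temporal_displacement(
    trace,
    reference,
    tau_max: float = 5.0,
    tau_resolution: float | None = None,
):
    """Time shift delta minimizing the RMSE between trace and reference.

    Finds delta = argmin over tau in [0, tau_max] of the RMS difference
    between V*(t) and V(t + tau), with the shifted trace evaluated by
    linear interpolation between grid points and the comparison window (and
    its duration T) recomputed per tau as the overlap. The minimization is
    a coarse-to-fine grid scan down to ``tau_resolution`` (default: grid
    spacing / 100) followed by a local bounded refinement.

    Returns ``(delta, residual_rmse)``.
    """
    trace = _as_trace(trace)
    reference = _as_trace(reference)
    if not tau_max > 0:
        raise ValueError("tau_max must be positive")
    duration = min(
        trace.times[-1] - trace.times[0], reference.times[-1] - reference.times[0]
    )
    if tau_max >= duration:
        raise ValueError("tau_max must be smaller than the trace duration")
    if tau_resolution is None:
        tau_resolution = float(np.median(np.diff(trace.times))) / 100.0

    t_ref = reference.times
    v_ref = reference.values

    def cost(tau: float) -> float:
        # compare V*(t) with V(t + tau) on the overlapping window
        mask = t_ref + tau <= trace.times[-1]
        tt = t_ref[mask]
        if tt.size < 2:
            return np.inf
        shifted = np.interp(tt + tau, trace.times, trace.values)
        return _rmse_from_diff(tt, v_ref[mask] - shifted) ** 2

    # coarse-to-fine scan: resolves structure on the scale of a spike width
    # first, then zooms until tau_resolution is reached
    lo, hi = 0.0, float(tau_max)
    step = max((hi - lo) / 500.0, tau_resolution)
    best = 0.0
    while True:
        taus = np.arange(lo, hi + step * 0.5, step)
        costs = np.array([cost(t) for t in taus])
        best = float(taus[np.argmin(costs)])
        if step <= tau_resolution:
            break
        lo = max(0.0, best - step)
        hi = min(float(tau_max), best + step)
        step = max(step / 10.0, tau_resolution)

    a = max(0.0, best - tau_resolution)
    b = min(float(tau_max), best + tau_resolution)
    res = minimize_scalar(
        cost,
        bounds=(a, b),
        method="bounded",
        options={"xatol": max(tau_resolution * 1e-6, 1e-12)},
    )
    delta = float(res.x)
    if cost(0.0) <= res.fun:
        delta = 0.0
    return delta, float(np.sqrt(cost(delta)))


def _trapezoid_mean(x: np.ndarray) -> np.ndarray:
    """Time average along the last axis by the trapezoidal rule."""
    n = x.shape[-1]
    return ((x[..., 0] + x[..., -1]) / 2.0 + x[..., 1:-1].sum(axis=-1)) / (n - 1)


def synchrony_chi(voltages) -> float:
    """Synchrony chi of a population from its membrane-potential traces.

    ``voltages`` is an (N, n_times) array on a common uniform grid. chi is
    the temporal standard deviation of the population-mean potential
    normalized by the RMS single-cell standard deviation; returns NaN (with
    a warning) when every trace is constant.
    """
    v = np.atleast_2d(np.asarray(voltages, dtype=np.float64))
    mean_v = v.mean(axis=0)
    var_mean = _trapezoid_mean(mean_v**2) - _trapezoid_mean(mean_v) ** 2
    var_i = _trapezoid_mean(v**2) - _trapezoid_mean(v) ** 2
    denom = var_i.mean()
    if denom <= 0:
        warnings.warn("synchrony undefined for all-constant traces", RuntimeWarning)
        return float("nan")
    return float(np.sqrt(max(var_mean, 0.0) / denom))


def spike_rate(spike_times, T: float) -> float:
    """Count-based rate nu = n(T)/T in spikes/s; times and T in ms."""
    if not T > 0:
        raise ValueError("T must be positive")
    spike_times = np.asarray(spike_times, dtype=np.float64)
    n = int(np.count_nonzero((spike_times > 0) & (spike_times <= T)))
    return n / (T / 1000.0)


def average_rate(spike_trains, T: float) -> float:
    """Population mean of the per-neuron count-based rates (spikes/s)."""
    rates = [spike_rate(train, T) for train in spike_trains]
    if not rates:
        raise ValueError("need at least one spike train")
    return float(np.mean(rates))
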