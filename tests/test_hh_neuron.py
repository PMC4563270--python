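"""Single-neuron dynamics: channel kinetics, solver, spikes, synapses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gapwave as gw
from gapwave.hh_neuron import (
    DEFAULT_PARAMETERS,
    NeuronState,
    channel_rates,
    derivatives,
    detect_spike,
    propagate_step,
    steady_state_gating,
)
from gapwave.wfr_engine import GapInputAccumulator, reference_solve


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.floats(min_value=-100.0, max_value=50.0))
def test_channel_rates_nonnegative_and_activation_bounded(V):
    rates = channel_rates(V)
    assert all(np.isfinite(r) and r >= 0.0 for r in rates)
    for q in steady_state_gating(V):
        assert 0.0 <= q <= 1.0


@pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
def test_channel_rates_reject_nonfinite_potential(bad):
    with pytest.raises(ValueError):
        channel_rates(bad)


def test_parameter_invariants_enforced():
    with pytest.raises(ValueError):
        DEFAULT_PARAMETERS.with_(C_m=0.0)
    with pytest.raises(ValueError):
        DEFAULT_PARAMETERS.with_(g_Na=-1.0)
    with pytest.raises(ValueError):
        DEFAULT_PARAMETERS.with_(tau_r=0.0)


def test_repetitive_firing_under_constant_drive(driven_params):
    """200 pA drives the interneuron into repetitive firing (tight oracle)."""
    net = gw.Network(1, driven_params, d_min=1.0)
    ref = reference_solve(net, 300.0, h=0.05, tol=1e-10)
    spikes = ref.spike_train(0)
    assert spikes.size >= 2
    # and the waveform-relaxation engine's solver agrees on the spike times
    sim = gw.Simulator(net, gw.SimulationConfig(h=0.05)).run(300.0)
    assert sim.spike_train(0).size == spikes.size
    np.testing.assert_allclose(sim.spike_train(0), spikes, atol=0.05 + 1e-9)


def test_linear_component_matches_exponential_decay():
    """The decoupled synaptic ODE dz/dt = -z/tau reproduces z0*exp(-h)."""
    p = DEFAULT_PARAMETERS.with_(tau_ex=1.0)
    s = NeuronState.resting(p)
    s.dI_ex = 1.0
    for h in (0.1, 0.5, 1.0):
        out, _ = propagate_step(s, h, None, p, abs_tol=1e-6)
        assert abs(out.dI_ex - np.exp(-h)) < 1e-6


def test_halving_tolerance_never_increases_error(driven_params, upstroke_state):
    ref, _ = propagate_step(upstroke_state, 0.5, None, driven_params, abs_tol=1e-13)
    errs = []
    tol = 1e-3
    while tol >= 1e-10:
        out, _ = propagate_step(upstroke_state, 0.5, None, driven_params, abs_tol=tol)
        errs.append(abs(out.V - ref.V))
        tol /= 2.0
    for a, b in zip(errs, errs[1:]):
        assert b <= a * (1.0 + 1e-9) + 1e-15


def test_propagation_bitwise_deterministic(driven_params, upstroke_state):
    a, da = propagate_step(upstroke_state, 0.05, None, driven_params)
    b, db = propagate_step(upstroke_state, 0.05, None, driven_params)
    assert a.as_array().tobytes() == b.as_array().tobytes()
    assert da == db


def test_gating_variables_bounded_along_trajectory(driven_params):
    s = NeuronState.resting(driven_params)
    lo, hi = np.inf, -np.inf
    for _ in range(2000):  # 100 ms, two spikes
        s, _ = propagate_step(s, 0.05, None, driven_params)
        g = s.as_array()[1:5]
        lo, hi = min(lo, g.min()), max(hi, g.max())
    assert lo >= -1e-3 and hi <= 1.0 + 1e-3


def test_gap_free_accumulator_is_bitwise_neutral(upstroke_state, driven_params):
    zero = GapInputAccumulator.zeros(4)
    dy0 = derivatives(upstroke_state, 0.3, None, driven_params)
    dy1 = derivatives(upstroke_state, 0.3, zero, driven_params)
    assert dy0.tobytes() == dy1.tobytes()
    a, _ = propagate_step(upstroke_state, 0.05, None, driven_params)
    b, _ = propagate_step(upstroke_state, 0.05, zero, driven_params)
    assert a.as_array().tobytes() == b.as_array().tobytes()


def test_gap_current_from_constant_waveform():
    """g = 2 nS toward a -50 mV sender at V = -60 mV adds 20 pA."""
    p = DEFAULT_PARAMETERS
    s = NeuronState.resting(p, V=-60.0)
    acc = GapInputAccumulator(g_bar=2.0, g_tilde=np.array([2.0 * -50.0, 0, 0, 0.0]))
    dy = derivatives(s, 0.0, acc, p)
    dy0 = derivatives(s, 0.0, None, p)
    assert np.isclose((dy[0] - dy0[0]) * p.C_m, 20.0, rtol=1e-12)


def test_converged_symmetric_coupling_cancels():
    """Identical neurons exchanging their own potential feel no gap current."""
    p = DEFAULT_PARAMETERS
    s = NeuronState.resting(p, V=-55.0)
    acc = GapInputAccumulator(g_bar=30.0, g_tilde=np.array([30.0 * -55.0, 0, 0, 0.0]))
    dy = derivatives(s, 0.0, acc, p)
    dy0 = derivatives(s, 0.0, None, p)
    assert abs(dy[0] - dy0[0]) < 1e-12


@pytest.mark.parametrize(
    "grid,theta,expect",
    [
        ([-70.0, -20.0, 30.0, 10.0], 0.0, 3),  # max at index 2, stamp after it
        ([-70.0, -30.0, -10.0, -30.0], 0.0, None),  # never crosses threshold
        ([-70.0, -20.0, 30.0, 40.0, 20.0, -10.0], 0.0, 4),
    ],
)
def test_spike_stamped_after_post_threshold_maximum(grid, theta, expect):
    p = DEFAULT_PARAMETERS.with_(theta=theta)
    s = NeuronState.resting(p, V=grid[0])
    hit = None
    for k, v in enumerate(grid[1:], start=1):
        s.V_prev_step = s.V
        s.V = v
        ev = detect_spike(s, k, p, h=0.1)
        if ev is not None:
            hit = k
            assert ev.time == pytest.approx(k * 0.1)
    assert hit == expect


def test_threshold_crossing_while_refractory_is_ignored():
    p = DEFAULT_PARAMETERS
    s = NeuronState.resting(p, V=-70.0)
    s.refractory_steps_left = 10
    for k, v in enumerate([-20.0, 30.0, 10.0, -40.0], start=1):
        s.V_prev_step = s.V
        s.V = v
        assert detect_spike(s, k, p, h=0.1) is None
    assert s.refractory_steps_left == 6  # counter decremented per grid point


def test_spike_sets_refractoriness_for_tau_r():
    p = DEFAULT_PARAMETERS  # tau_r = 2 ms
    s = NeuronState.resting(p, V=-70.0)
    for k, v in enumerate([30.0, 10.0], start=1):
        s.V_prev_step = s.V
        s.V = v
        ev = detect_spike(s, k, p, h=0.1)
    assert ev is not None
    assert s.refractory_steps_left == 20  # round(2.0 / 0.1)


def test_alpha_synapse_peaks_at_weight_after_tau():
    """A single spike of weight J peaks the current at J at lag tau_ex."""
    J, h = 120.0, 0.01
    p = DEFAULT_PARAMETERS  # tau_ex = 0.2 ms
    s = NeuronState.resting(p)
    s.dI_ex = J * np.e / p.tau_ex  # delta kick at t = 0
    peak, t_peak = -np.inf, None
    for k in range(1, 101):  # 1 ms
        s, _ = propagate_step(s, h, None, p, abs_tol=1e-9)
        if s.I_ex > peak:
            peak, t_peak = s.I_ex, k * h
    assert abs(peak - J) / J < 1e-3
    assert abs(t_peak - p.tau_ex) <= h
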