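"""Waveform relaxation: interpolation, accumulation, scheduling, analytics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gapwave as gw
from gapwave.wfr_engine import (
    CommunicationSchedule,
    GapInputAccumulator,
    InterpolationWaveform,
    communication_counts,
    convergence_check,
    crossover_r,
    handle_gap_event,
    interpolation_coefficients,
    payload_size,
    reference_solve,
)


@pytest.mark.parametrize(
    "args,expect",
    [
        (dict(order=0, V0=-65.0), (-65.0,)),
        (dict(order=1, V0=0.0, V1=1.0), (0.0, 1.0)),
        (dict(order=3, V0=0.0, V1=1.0, V0p=0.0, V1p=0.0, h=1.0), (0.0, 0.0, 3.0, -2.0)),
    ],
)
def test_interpolation_coefficient_table(args, expect):
    assert interpolation_coefficients(**args) == pytest.approx(expect)


def test_unsupported_interpolation_order_rejected():
    with pytest.raises(ValueError):
        interpolation_coefficients(2, 0.0, 1.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.tuples(*[st.floats(-50, 50) for _ in range(4)]), st.floats(0.01, 1.0))
def test_cubic_hermite_reproduces_cubics_exactly(c, h):
    """Sampling any cubic at the step endpoints recovers it everywhere."""
    poly = np.polynomial.Polynomial(c)
    dpoly = poly.deriv()
    coeffs = interpolation_coefficients(
        3, poly(0.0), poly(1.0), dpoly(0.0) / h, dpoly(1.0) / h, h
    )
    x = np.linspace(0.0, 1.0, 100)
    recon = sum(a * x**m for m, a in enumerate(coeffs))
    scale = max(1.0, np.max(np.abs(poly(x))))
    assert np.max(np.abs(recon - poly(x))) < 1e-12 * scale


def test_gap_event_accumulation_matches_brute_force_sum():
    acc = GapInputAccumulator.zeros(1)
    handle_gap_event(acc, 1.0, [10.0])
    handle_gap_event(acc, 2.0, [-5.0])
    assert acc.g_bar == 3.0
    assert acc.g_tilde == pytest.approx([0.0])


def test_zero_weight_event_leaves_accumulator_unchanged():
    acc = GapInputAccumulator(5.0, np.array([1.0, 2.0]))
    handle_gap_event(acc, 0.0, [3.0, 4.0])
    assert acc.g_bar == 5.0 and acc.g_tilde == pytest.approx([1.0, 2.0])


def test_event_length_mismatch_rejected():
    with pytest.raises(ValueError):
        handle_gap_event(GapInputAccumulator.zeros(4), 1.0, [1.0, 2.0])


def test_single_source_reduction_equals_pairwise_gap_current():
    """With one sender, -g_bar*V + sum g~ x^m equals g*(P(x) - V)."""
    rng = np.random.default_rng(0)
    a = rng.normal(size=4)
    g, V = 2.5, -61.0
    acc = GapInputAccumulator.zeros(4)
    handle_gap_event(acc, g, a)
    for x in np.linspace(0, 1, 11):
        P = sum(ai * x**m for m, ai in enumerate(a))
        reduced = -acc.g_bar * V + sum(gm * x**m for m, gm in enumerate(acc.g_tilde))
        assert np.isclose(reduced, g * (P - V), rtol=1e-12)


def test_accumulator_route_matches_sparse_exchange():
    """Per-event accumulation and the matrix exchange agree (dual route)."""
    rng = np.random.default_rng(42)
    net = gw.Network(6, gw.DEFAULT_PARAMETERS)
    pairs = [(0, 1, 2.0), (1, 2, 1.5), (0, 5, 0.3), (2, 5, 1.1), (0, 1, 0.7)]
    for i, j, g in pairs:
        net.connect_gap(i, j, g)
    coeffs = rng.normal(size=(6, 8))
    G = net.gap_matrix()
    gt_matrix = G.dot(coeffs)
    for i in range(6):
        acc = GapInputAccumulator.zeros(8)
        for a, b, g in pairs:
            if a == i:
                handle_gap_event(acc, g, coeffs[b])
            elif b == i:
                handle_gap_event(acc, g, coeffs[a])
        np.testing.assert_allclose(acc.g_tilde, gt_matrix[i], rtol=1e-12)
        assert np.isclose(acc.g_bar, net.total_gap_conductance()[i])


def test_convergence_check_boundary_semantics():
    V_last = np.array([0.0, 0.0])
    assert not convergence_check([-65.0, -65.0], V_last, 1e-4)  # after reset
    assert convergence_check([-65.0, -65.0], V_last, 1e-4)  # unchanged
    V_last = np.array([0.0])
    assert not convergence_check([1e-4], V_last, 1e-4)  # == tol violates
    V_last = np.array([0.0])
    assert convergence_check([0.99e-4], V_last, 1e-4)  # just below passes


def test_waveform_continuity_at_step_boundaries():
    values = np.array([-70.0, -50.0, 10.0, -30.0])
    derivs = np.array([1.0, 40.0, -5.0, -80.0])
    for order in (1, 3):
        wf = InterpolationWaveform.from_grid(order, values, derivs, h=0.5)
        for s in range(1, wf.n_steps + 1):
            # polynomial of step s at x=1 equals the stored right-edge value
            assert wf(np.array([s * 0.5 - 1e-12]))[0] == pytest.approx(
                values[s], abs=1e-8
            )


def test_communication_schedule_validates_grid():
    with pytest.raises(ValueError):
        CommunicationSchedule(h=0.07, d_min=1.0)
    sched = CommunicationSchedule(h=0.05, d_min=1.0, strategy="h")
    assert sched.r == 20 and sched.interval_steps == 1
    assert CommunicationSchedule(h=0.05, d_min=1.0).interval_steps == 20


def test_jacobi_updates_read_previous_iteration_waveforms():
    """Iteration k's gap input is assembled from iteration k-1's output."""
    net = gw.build_testcase_1a()
    sim = gw.Simulator(net, gw.SimulationConfig(h=0.1, strategy="dmin"))
    sim.debug_capture = []
    sim.run(1.0)  # a single min-delay interval
    G = net.gap_matrix()
    V0 = net.initial_state[0, 0]
    prev_coeffs = None
    assert len(sim.debug_capture) >= 2
    for gt_in, coeffs_out in sim.debug_capture:
        if prev_coeffs is None:
            # first iteration: constant initial/extrapolated waveform
            assert np.allclose(gt_in[:, 0::4][gt_in[:, 0::4] != 0], 30.0 * V0)
        else:
            np.testing.assert_array_equal(gt_in, G.dot(prev_coeffs))
        prev_coeffs = coeffs_out


def test_gap_free_network_reduces_to_plain_min_delay_simulation():
    net = gw.Network(3, gw.DEFAULT_PARAMETERS.with_(I_const=150.0), d_min=1.0)
    net.connect_chemical(0, 1, 200.0, 1.0)
    net.connect_chemical(1, 2, -150.0, 1.5)
    runs = {}
    for strat in ("dmin", "h", "single-step"):
        r = gw.Simulator(net, gw.SimulationConfig(h=0.1, strategy=strat)).run(100.0)
        runs[strat] = r
        assert r.mean_iterations == 0.0
    assert (runs["dmin"].voltages == runs["h"].voltages).all()
    assert (runs["dmin"].voltages == runs["single-step"].voltages).all()
    assert np.array_equal(runs["dmin"].spike_times, runs["h"].spike_times)


def test_symmetric_pair_trajectories_identical(pair_run_h005):
    assert (pair_run_h005.voltages[0] == pair_run_h005.voltages[1]).all()
    np.testing.assert_array_equal(
        pair_run_h005.spike_train(0), pair_run_h005.spike_train(1)
    )


def test_single_step_equals_iterative_with_zero_iterations():
    net = gw.build_testcase_1a()
    a = gw.Simulator(net, gw.SimulationConfig(h=0.05, strategy="single-step")).run(50.0)
    b = gw.Simulator(
        net, gw.SimulationConfig(h=0.05, strategy="h", fixed_iterations=0)
    ).run(50.0)
    assert (a.voltages == b.voltages).all()
    assert np.array_equal(a.spike_times, b.spike_times)


def test_strategies_agree_after_convergence():
    """Converged runs of both exchange schedules are nearly identical."""
    tol = 1e-4
    runs = [
        gw.Simulator(
            gw.build_testcase_1a(), gw.SimulationConfig(h=0.05, strategy=s,
                                                        prelim_tol=tol)
        ).run(100.0)
        for s in ("dmin", "h")
    ]
    eps = gw.rmse(
        gw.Trace(runs[0].times, runs[0].voltages[0]),
        gw.Trace(runs[1].times, runs[1].voltages[0]),
    )
    assert eps <= 10 * tol


def test_spike_delivery_independent_of_iteration_budget():
    """Spikes come only from final updates: a non-binding cap is invisible."""
    net = gw.Network(3, gw.DEFAULT_PARAMETERS.with_(I_const=200.0), d_min=1.0)
    net.connect_gap(0, 1, 10.0)
    net.connect_chemical(0, 2, 400.0, 1.0)
    runs = [
        gw.Simulator(
            net, gw.SimulationConfig(h=0.1, strategy="dmin", max_iterations=cap)
        ).run(60.0)
        for cap in (15, 40)
    ]
    assert runs[0].spike_times.size > 0
    assert np.array_equal(runs[0].spike_times, runs[1].spike_times)
    assert np.array_equal(runs[0].spike_senders, runs[1].spike_senders)
    assert (runs[0].voltages == runs[1].voltages).all()


def test_run_is_deterministic_and_reproducible():
    net = gw.build_testcase_1a()
    cfg = gw.SimulationConfig(h=0.05, strategy="dmin")
    a = gw.Simulator(net, cfg).run(100.0)
    b = gw.Simulator(net, cfg).run(100.0)
    assert a.voltages.tobytes() == b.voltages.tobytes()
    assert np.array_equal(a.iterations, b.iterations)


def test_reference_oracle_consistency():
    single = gw.Network(1, gw.DEFAULT_PARAMETERS.with_(I_const=200.0))
    one = reference_solve(single, 20.0, h=0.05, tol=1e-10)
    uncoupled = reference_solve(gw.build_testcase_1a(g=0.0), 20.0, h=0.05, tol=1e-10)
    for i in (0, 1):
        np.testing.assert_allclose(
            uncoupled.voltages[i], one.voltages[0], atol=1e-7
        )
    coupled = reference_solve(gw.build_testcase_1a(), 20.0, h=0.05, tol=1e-10)
    np.testing.assert_allclose(coupled.voltages, uncoupled.voltages, atol=1e-7)


def test_wfr_error_decays_to_interpolation_plateau():
    """More iterations monotonically approach the oracle, then plateau."""
    net = gw.build_testcase_1a()
    oracle = reference_solve(net, 10.0, h=0.05, tol=1e-12)
    errs = []
    for k in (1, 2, 3, 5, 8, 12):
        r = gw.Simulator(
            net, gw.SimulationConfig(h=0.05, strategy="dmin", fixed_iterations=k)
        ).run(10.0)
        errs.append(np.max(np.abs(r.voltages - oracle.voltages)))
    assert errs[0] > errs[-1]
    plateau = errs[-1]
    for a, b in zip(errs, errs[1:]):
        assert b <= a * 1.05 + 2 * plateau


@pytest.mark.parametrize(
    "ih,idm,r,C,expect",
    [(4.0, 8.0, 10, 1.0, 5.0), (6.0, 6.0, 1, 1.0, 1.0), (3.0, 9.0, 6, 2.0, 4.0)],
)
def test_communication_count_estimate(ih, idm, r, C, expect):
    assert communication_counts(ih, idm, r, C) == pytest.approx(expect)


def test_crossover_is_first_r_with_more_communications():
    # ratio exactly 2: r=2 gives equality, not excess, so crossover is 3
    assert crossover_r(4.0, 8.0) == 3
    assert crossover_r(5.0, 8.0) == 2
    assert crossover_r(1.0, 1.0) == 2


@pytest.mark.parametrize("r,order,expect", [(20, 3, 640), (10, 1, 160), (1, 0, 8)])
def test_payload_bytes_per_communication(r, order, expect):
    assert payload_size(r, order) == expect
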