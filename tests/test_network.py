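"""Network container: gap symmetry, spike delivery, Poisson input, I/O."""

import json

import numpy as np
import pytest

import gapwave as gw
from gapwave.network import (
    ChemicalSynapse,
    Network,
    PoissonSource,
    SpikeRingBuffer,
    build_poisson_trains,
)


def test_self_gap_junction_rejected():
    net = Network(3)
    with pytest.raises(ValueError):
        net.connect_gap(1, 1, 5.0)
    with pytest.raises(ValueError):
        net.connect_gap(0, 1, -2.0)


def test_gap_matrix_symmetric_and_accumulating():
    net = Network(4)
    net.connect_gap(0, 1, 2.0)
    net.connect_gap(1, 0, 3.0)  # duplicate pair accumulates
    net.connect_gap(2, 3, 1.0)
    G = net.gap_matrix().toarray()
    assert np.array_equal(G, G.T)
    assert G[0, 1] == 5.0
    assert net.total_gap_conductance().tolist() == [5.0, 5.0, 1.0, 1.0]


def test_zero_weight_junction_is_dynamically_inert():
    base = Network(2, gw.DEFAULT_PARAMETERS.with_(I_const=200.0))
    with_zero = Network(2, gw.DEFAULT_PARAMETERS.with_(I_const=200.0))
    with_zero.connect_gap(0, 1, 0.0)
    cfg = gw.SimulationConfig(h=0.1, strategy="dmin")
    a = gw.Simulator(base, cfg).run(50.0)
    b = gw.Simulator(with_zero, cfg).run(50.0)
    assert (a.voltages == b.voltages).all()


def test_chemical_delay_below_minimum_rejected():
    net = Network(2, d_min=1.0)
    with pytest.raises(ValueError):
        net.connect_chemical(0, 1, 100.0, 0.5)
    net.connect_chemical(0, 1, 100.0, 1.5)
    with pytest.raises(ValueError):
        net.validate_grid(0.4)  # 1.5 not on the 0.4 grid
    net.validate_grid(0.05)


def test_receptor_defaults_to_sign_of_weight():
    assert ChemicalSynapse(0, 1, -50.0, 1.0).receptor == "inhibitory"
    assert ChemicalSynapse(0, 1, 50.0, 1.0).receptor == "excitatory"
    with pytest.raises(ValueError):
        ChemicalSynapse(0, 1, 50.0, 1.0, receptor="shunting")


def test_spike_lands_at_lag_d_in_every_target():
    net = Network(3, d_min=1.0)
    h = 0.1
    net.connect_chemical(0, 1, 100.0, 1.0)
    net.connect_chemical(0, 2, 100.0, 1.0)
    buf = SpikeRingBuffer(3, 64)
    net.deliver_spikes([(0, 7)], buf, h)
    amp = 100.0 * np.e / gw.DEFAULT_PARAMETERS.tau_ex
    for tgt in (1, 2):
        nz = np.nonzero(buf.ex[tgt])[0]
        assert nz.tolist() == [17]  # 7 + 1.0 ms / 0.1 ms
        assert buf.ex[tgt, 17] == pytest.approx(amp)
    assert not buf.ex[0].any() and not buf.inh.any()


def test_kick_conservation_on_random_network():
    rng = np.random.default_rng(5)
    net = Network(10, d_min=1.0)
    for _ in range(40):
        s, t = rng.choice(10, 2, replace=False)
        net.connect_chemical(int(s), int(t), float(rng.normal(scale=80)), 1.0)
    buf = SpikeRingBuffer(10, 128)
    events = [(int(rng.integers(10)), int(rng.integers(50))) for _ in range(25)]
    net.deliver_spikes(events, buf, 0.1)
    out_deg = np.zeros(10)
    for s in net.synapses:
        out_deg[s.source] += 1
    expected = sum(out_deg[src] for src, _ in events)
    assert np.count_nonzero(buf.ex) + np.count_nonzero(buf.inh) <= expected
    # total delivered kick mass equals the sum over (spike, synapse) pairs
    total = buf.ex.sum() + buf.inh.sum()
    per_spike = sum(
        syn.weight
        * np.e
        / (
            gw.DEFAULT_PARAMETERS.tau_ex
            if syn.receptor == "excitatory"
            else gw.DEFAULT_PARAMETERS.tau_in
        )
        for src, _ in events
        for syn in net.synapses
        if syn.source == src
    )
    assert total == pytest.approx(per_spike)


def test_poisson_counts_mean_and_dispersion():
    sources = [PoissonSource(i, 500.0, 300.0, 1.0) for i in range(200)]
    idx, steps = build_poisson_trains(sources, 1000.0, 0.05, seed=11)
    counts = np.bincount(idx, minlength=200)
    assert counts.mean() == pytest.approx(500.0, rel=0.05)
    dispersion = counts.var() / counts.mean()
    assert 0.8 <= dispersion <= 1.2
    assert steps.min() >= 1 and steps.max() <= 20000


def test_poisson_zero_rate_and_reproducibility():
    src = [PoissonSource(0, 0.0, 1.0, 1.0)]
    idx, steps = build_poisson_trains(src, 100.0, 0.1, seed=1)
    assert steps.size == 0
    src = [PoissonSource(0, 200.0, 1.0, 1.0), PoissonSource(1, 200.0, 1.0, 1.0)]
    a = build_poisson_trains(src, 500.0, 0.1, seed=7)
    b = build_poisson_trains(src, 500.0, 0.1, seed=7)
    c = build_poisson_trains(src, 500.0, 0.1, seed=8)
    assert np.array_equal(a[1], b[1])
    assert not np.array_equal(a[1], c[1])
    # distinct sources use independent streams
    assert not np.array_equal(a[1][a[0] == 0], a[1][a[0] == 1])


def test_network_json_round_trip_is_byte_stable():
    net = gw.build_testcase_2(0.5, J_I=-30.0, seed=3, N=40, n_inhibitory_inputs=5)
    text = net.to_json()
    clone = Network.from_json(text)
    assert clone.to_json() == text
    doc = json.loads(text)
    assert doc["n_neurons"] == 40
    # the restored network simulates identically
    cfg = gw.SimulationConfig(h=0.1, strategy="dmin", seed=2)
    a = gw.Simulator(net, cfg).run(20.0)
    b = gw.Simulator(clone, cfg).run(20.0)
    assert (a.voltages == b.voltages).all()


def test_initial_potentials_set_gates_to_steady_state():
    net = Network(3)
    net.set_initial_potentials([-80.0, -60.0, -40.0])
    for i, v in enumerate((-80.0, -60.0, -40.0)):
        m, h, n, p = gw.steady_state_gating(v)
        assert net.initial_state[i, 0] == v
        assert net.initial_state[i, 1] == pytest.approx(m)
        assert net.initial_state[i, 4] == pytest.approx(p)
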