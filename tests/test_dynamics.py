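"""Threshold-linear dynamics: fixed points, relaxation, Euler convergence,
superposition in the linear regime, and scatter/gather equivalence."""

import numpy as np
import pytest

from dmnet.connectome import (CellTypeSpec, ConnectomeSpec, FilterEntry,
                              ParamSet, SignTable, tile)
from dmnet.dynamics import (NumericalDivergence, SimConfig, rectify, simulate,
                            steady_state, step)
from dmnet.hexlattice import enumerate_hex
from dmnet.stimuli import StimulusSequence, grey_screen


def isolated_net(v_rest=0.2, tau=40.0, photoreceptor=True):
    signs = SignTable()
    signs[("A", "A")] = 1
    spec = ConnectomeSpec(types=[CellTypeSpec("A")], filters=[], signs=signs,
                          input_types=("A",) if photoreceptor else ())
    net = tile(spec, enumerate_hex(0))
    params = ParamSet(tau=np.array([tau]), v_rest=np.array([v_rest]),
                      alpha=np.zeros(0))
    return net, params


def chain_net(w=0.5):
    """A -> B with one weight; A is the photoreceptor."""
    signs = SignTable()
    signs[("A", "B")] = 1 if w >= 0 else -1
    spec = ConnectomeSpec(
        types=[CellTypeSpec("A"), CellTypeSpec("B")],
        filters=[FilterEntry("A", "B", 0, 0, 10.0)],
        signs=signs, input_types=("A",),
    )
    net = tile(spec, enumerate_hex(0))
    params = ParamSet(tau=np.array([30.0, 60.0]), v_rest=np.array([0.1, 0.3]),
                      alpha=np.array([abs(w) / 10.0]))
    return net, params


def test_rectify():
    assert rectify(2.5) == 2.5
    assert rectify(-1.0) == 0.0
    assert rectify(0.0) == 0.0


def test_isolated_neuron_fixed_point():
    net, params = isolated_net()
    V = np.array([params.v_rest[0]])
    V2 = step(V, net, np.zeros(0), params.tau, params.v_rest, np.zeros(1), dt=5.0)
    np.testing.assert_allclose(V2, V)


def test_exponential_relaxation_63_percent():
    """Constant input: at t = tau the step is ~63.2% complete (1 - 1/e)."""
    net, params = isolated_net(v_rest=0.0, tau=50.0)
    e = np.array([1.0])
    dt = 0.5
    V = np.array([0.0])
    for _ in range(int(50.0 / dt)):
        V = step(V, net, np.zeros(0), params.tau, params.v_rest, e, dt)
    assert V[0] == pytest.approx(1 - np.exp(-1), abs=5e-3)


def test_two_neuron_chain_fixed_point():
    net, params = chain_net(w=0.5)
    w = params.connection_weights(net)
    V = steady_state(net, w, params.tau, params.v_rest, luminance=0.4,
                     duration=4000.0, dt=1.0)
    a, b = net.neurons_of_type("A")[0], net.neurons_of_type("B")[0]
    v_a = 0.1 + 0.4  # V_rest + luminance input
    np.testing.assert_allclose(V[a], v_a, atol=1e-6)
    np.testing.assert_allclose(V[b], 0.3 + 0.5 * max(v_a, 0.0), atol=1e-6)


def test_steady_state_converged_and_deterministic():
    net, params = chain_net(w=-0.3)
    w = params.connection_weights(net)
    s1 = steady_state(net, w, params.tau, params.v_rest, duration=3000.0, dt=5.0)
    s2 = steady_state(net, w, params.tau, params.v_rest, duration=6000.0, dt=5.0)
    np.testing.assert_allclose(s1, s2, atol=1e-9)
    s3 = steady_state(net, w, params.tau, params.v_rest, duration=3000.0, dt=5.0)
    np.testing.assert_array_equal(s1, s3)


def test_step_shape_mismatch():
    net, params = isolated_net()
    with pytest.raises(ValueError):
        step(np.zeros(2), net, np.zeros(0), params.tau, params.v_rest, np.zeros(2), 5.0)


def test_tau_clamped_at_dt():
    """tau < dt behaves as tau = dt (one-step jump to the fixed point)."""
    net, params = isolated_net(v_rest=0.0, tau=1.0)
    V = step(np.zeros(1), net, np.zeros(0), params.tau, params.v_rest,
             np.array([2.0]), dt=10.0)
    np.testing.assert_allclose(V, [2.0])


def test_zero_weight_network_constant_trace(motif, motif_net):
    params = ParamSet(tau=motif.params.tau, v_rest=motif.params.v_rest,
                      alpha=np.zeros_like(motif.params.alpha))
    stim = grey_screen(motif_net.lattice, 200.0, 5.0)
    tr = simulate(motif_net, params, stim, SimConfig(dt=5.0, grey_warmup=500.0))
    np.testing.assert_allclose(tr.data[0], tr.data[-1], atol=1e-9)


def test_euler_first_order_convergence(motif, motif_net):
    """Halving dt halves the Euler error against a fine-dt reference."""
    from dmnet.stimuli import circular_flash

    nid = motif_net.central_neuron("D")
    errs = {}
    ref = None
    for dt in (1.0, 4.0, 8.0):
        stim = circular_flash(motif_net.lattice, 1.0, radius=3, warmup=200.0,
                              flash=200.0, dt=dt)
        cfg = SimConfig(dt=dt, grey_warmup=400.0, record=np.array([nid]))
        tr = simulate(motif_net, motif.params, stim, cfg)
        # compare at 40 ms grid points
        stride = int(40 / dt)
        errs[dt] = tr.data[stride - 1 :: stride, 0][:9]
    e8 = np.abs(errs[8.0] - errs[1.0]).max()
    e4 = np.abs(errs[4.0] - errs[1.0]).max()
    assert e4 < 0.75 * e8  # roughly first order (ratio ~0.43 in theory)


def test_superposition_in_linear_regime():
    """While all voltages stay positive, responses add linearly."""
    net, params = chain_net(w=0.4)
    lattice = net.lattice
    cfg = SimConfig(dt=2.0, grey_warmup=2000.0, grey_level=0.5)

    def resp(scale):
        frames = 0.5 + scale * 0.2 * np.sin(np.linspace(0, 4 * np.pi, 100))[:, None]
        stim = StimulusSequence(frames, 2.0, lattice)
        return simulate(net, params, stim, cfg).data

    r1, r2, r12 = resp(1.0), resp(0.5), resp(1.5)
    base = resp(0.0)
    assert (r1 > 0).all() and (r12 > 0).all()
    np.testing.assert_allclose(r12 - base, (r1 - base) + (r2 - base), atol=1e-9)


def test_divergence_raises():
    net, params = chain_net(w=0.5)
    bad = ParamSet(tau=params.tau, v_rest=np.array([1e300, 1e300]),
                   alpha=np.array([1e280]))
    with pytest.raises(NumericalDivergence):
        steady_state(net, bad.connection_weights(net), bad.tau, bad.v_rest,
                     duration=10000.0, dt=5.0)


def test_simulate_lattice_mismatch(motif, motif_net):
    stim = grey_screen(enumerate_hex(2), 100.0, 5.0)
    with pytest.raises(ValueError):
        simulate(motif_net, motif.params, stim, SimConfig(dt=5.0))
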