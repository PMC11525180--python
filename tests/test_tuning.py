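"""Tuning statistics against brute-force oracles and designed fixtures."""

import numpy as np
import pytest
from scipy import stats

from dmnet.tuning import (PeakResponse, classify_direction_selective, dsi, fri,
                          normalize_for_averaging, permutation_null,
                          preferred_direction, receptive_fields, select_models,
                          tuning_correlation)

ANGLES = tuple(range(0, 360, 30))


def peaks_from(r):
    r = np.asarray(r, dtype=float)
    return PeakResponse(r=r, intensities=(0.0, 1.0), speeds=tuple(range(r.shape[1])),
                        directions_deg=ANGLES)


# ---------------------------------------------------------------------- FRI


def test_fri_formula_cases():
    on = np.array([0.0, 3.0])
    off = np.array([0.0, 1.0])
    assert fri(on, off) == pytest.approx(0.5)
    assert fri(on, on) == 0.0
    assert fri(np.zeros(4), np.zeros(4)) is None


def test_fri_uses_global_minimum_offset():
    on = np.array([-1.0, 2.0])   # min -1 -> offset 1
    off = np.array([0.0, 1.0])
    # r_on = 2+1 = 3, r_off = 1+1 = 2
    assert fri(on, off) == pytest.approx((3 - 2) / (3 + 2))


def test_fri_positive_for_on_rectifying_relay_gain_sweep():
    """A luminance-following rectified relay prefers ON for any positive gain."""
    from dmnet.connectome import tile
    from dmnet.fixtures import make_motion_motif
    from dmnet.hexlattice import enumerate_hex
    from dmnet.tuning import measure_fri

    lat = enumerate_hex(3)
    for gain in (0.02, 0.1, 0.3):
        m = make_motion_motif(radius=3)
        m.params.alpha[:] = gain
        net = tile(m.spec, lat)
        assert measure_fri(net, m.params, "EF", flash_radius=3) > 0


# ---------------------------------------------------------------------- DSI


def test_dsi_uniform_response_is_zero():
    r = np.ones((2, 3, 12))
    assert dsi(peaks_from(r), 1.0) == pytest.approx(0.0)


def test_dsi_single_direction_is_one():
    r = np.zeros((2, 2, 12))
    r[1, :, 4] = 2.0  # dominant intensity responds at one direction
    assert dsi(peaks_from(r), 1.0) == pytest.approx(1.0)


def test_dsi_opponent_pair_cancels():
    r = np.zeros((2, 1, 12))
    r[1, 0, 0] = 1.0
    r[1, 0, 6] = 1.0  # 180 deg apart
    assert dsi(peaks_from(r), 1.0) == pytest.approx(0.0)


def test_dsi_cosine_tuning_matches_oracle(rng):
    th = np.deg2rad(ANGLES)
    r = np.zeros((2, 6, 12))
    for s in range(6):
        th0 = rng.uniform(0, 2 * np.pi)
        r[1, s] = 1 + np.cos(th - th0)
        r[0, s] = rng.uniform(0, 0.5, size=12)
    pk = peaks_from(r)
    got = dsi(pk, 1.0)
    vals = []
    for s in range(6):
        num = abs(np.sum(r[1, s] * np.exp(1j * th)))
        den = max(abs(r[0, s].sum()), abs(r[1, s].sum()))
        vals.append(num / den)
    assert got == pytest.approx(np.mean(vals), rel=1e-12)


def test_dsi_invariant_to_global_rotation(rng):
    r = rng.uniform(0, 1, size=(2, 3, 12))
    pk = peaks_from(r)
    rolled = peaks_from(np.roll(r, 4, axis=2))
    assert dsi(pk, 1.0) == pytest.approx(dsi(rolled, 1.0), rel=1e-12)


def test_preferred_direction_of_cosine():
    th = np.deg2rad(ANGLES)
    r = np.zeros((2, 1, 12))
    r[1, 0] = 1 + np.cos(th - np.deg2rad(120.0))
    assert preferred_direction(peaks_from(r), 1.0) == pytest.approx(120.0, abs=1e-9)


# ---------------------------------------------------- permutation / binomial


def test_permutation_null_constant_peaks():
    r = np.ones((2, 2, 12))
    samples, thr = permutation_null([peaks_from(r)], n_perm=10, seed=0)
    np.testing.assert_allclose(samples, samples[0])
    assert thr == pytest.approx(samples[0])


def test_permutation_null_reproducible(rng):
    r = rng.uniform(0, 1, size=(2, 2, 12))
    _, t1 = permutation_null([peaks_from(r)], seed=3)
    _, t2 = permutation_null([peaks_from(r)], seed=3)
    assert t1 == t2
    with pytest.raises(ValueError):
        permutation_null([])


def test_classify_binomial_closed_forms():
    sel, p = classify_direction_selective(np.zeros(50), threshold=0.5)
    assert not sel and p == pytest.approx(1.0)
    sel, p = classify_direction_selective(np.ones(50), threshold=0.5)
    assert sel and p == pytest.approx(0.1**50, rel=1e-9)
    d = np.concatenate([np.ones(10), np.zeros(40)])
    _, p = classify_direction_selective(d, threshold=0.5)
    tail = sum(stats.binom.pmf(k, 50, 0.1) for k in range(10, 51))
    assert p == pytest.approx(tail, rel=1e-9)


# --------------------------------------------------------- receptive fields


def test_receptive_field_baseline_and_slices(rng):
    offsets = [(0, 0), (1, 0), (0, 1)]
    traces = rng.normal(size=(3, 50)) + 2.0
    rf = receptive_fields(traces, offsets, dt=5.0)
    np.testing.assert_allclose(rf.strf[0], 0.0)
    centre = rf.strf[:, 0]
    n_star = np.argmax(np.abs(centre))
    np.testing.assert_array_equal(rf.srf, rf.strf[n_star])
    np.testing.assert_array_equal(rf.trf, centre)


def test_strf_zero_weight_network(motif, motif_net):
    """With all synapses off, only the photoreceptor in the flashed column
    responds."""
    import dmnet.dynamics as dyn
    from dmnet.connectome import ParamSet
    from dmnet.stimuli import ommatidium_flash

    params = ParamSet(tau=motif.params.tau, v_rest=motif.params.v_rest,
                      alpha=np.zeros_like(motif.params.alpha))
    nid = motif_net.central_neuron("D")
    rid = motif_net.central_neuron("R")
    cfg = dyn.SimConfig(dt=5.0, grey_warmup=500.0, record=np.array([nid, rid]))
    traces = []
    for off in [(0, 0), (1, 0)]:
        stim = ommatidium_flash(motif_net.lattice, off, 1.0, 50.0, pre=100.0,
                                post=200.0, dt=5.0)
        traces.append(dyn.simulate(motif_net, params, stim, cfg).data)
    tr = np.stack(traces)
    rf_detector = receptive_fields(tr[:, :, 0].reshape(2, -1), [(0, 0), (1, 0)], 5.0)
    np.testing.assert_allclose(rf_detector.strf, 0.0, atol=1e-12)
    rf_photo = receptive_fields(tr[:, :, 1].reshape(2, -1), [(0, 0), (1, 0)], 5.0)
    assert np.abs(rf_photo.strf[:, 0]).max() > 0.1   # own column responds
    np.testing.assert_allclose(rf_photo.strf[:, 1], 0.0, atol=1e-12)


def test_strf_amplitude_doubles_with_contrast(motif, motif_net):
    """Linear-regime cell: doubling the flash excursion doubles the STRF."""
    import dmnet.dynamics as dyn
    from dmnet.stimuli import ommatidium_flash

    rid = motif_net.central_neuron("EF")
    cfg = dyn.SimConfig(dt=5.0, grey_warmup=1000.0, record=np.array([rid]))

    def strf_amp(I):
        stim = ommatidium_flash(motif_net.lattice, (0, 0), I, 100.0, pre=100.0,
                                post=300.0, dt=5.0)
        d = dyn.simulate(motif_net, motif.params, stim, cfg).data[:, 0]
        return np.abs(d - d[0]).max()

    a1 = strf_amp(0.75)   # +0.25 excursion
    a2 = strf_amp(1.0)    # +0.5 excursion
    assert a2 == pytest.approx(2 * a1, rel=1e-6)


# ------------------------------------------------- normalization/correlation


def test_normalize_rms_and_exclusion(rng):
    nat = rng.normal(size=(5, 40))
    tr = nat[0]
    out, excluded = normalize_for_averaging(tr, nat)
    assert not excluded
    assert np.sqrt(np.mean((nat / np.sqrt(np.mean(nat**2))) ** 2)) == pytest.approx(1.0)
    np.testing.assert_allclose(out, tr / np.sqrt(np.mean(nat**2)))
    _, excluded = normalize_for_averaging(tr, np.zeros((2, 3)))
    assert excluded


def test_normalization_scale_invariance(rng):
    nat = rng.normal(size=(4, 30))
    tr = rng.normal(size=30)
    a, _ = normalize_for_averaging(tr, nat)
    b, _ = normalize_for_averaging(10 * tr, 10 * nat)
    np.testing.assert_allclose(a, b)


def test_tuning_correlation_oracle(rng):
    curves = rng.normal(size=(6, 12))
    ref = rng.normal(size=12)
    brute = max(stats.pearsonr(curves[s], ref).statistic for s in range(6))
    assert tuning_correlation(curves, ref) == pytest.approx(brute, rel=1e-12)
    assert tuning_correlation(curves[:1], curves[0]) == pytest.approx(1.0)
    assert np.isnan(tuning_correlation(np.ones((2, 12)), ref))


def test_tuning_correlation_negation():
    ref = np.arange(12.0)
    assert tuning_correlation(np.tile(-ref, (3, 1)), ref) == pytest.approx(-1.0)


# ------------------------------------------------------------ model selector


def test_select_models_criteria():
    results = [
        {"T": {"fri": 0.4, "dsi": 0.6, "pd": 40.0}},
        {"T": {"fri": -0.4, "dsi": 0.6, "pd": 40.0}},   # wrong contrast sign
        {"T": {"fri": 0.4, "dsi": 0.1, "pd": 40.0}},    # below threshold
        {"T": {"fri": 0.4, "dsi": 0.6, "pd": 50.0}},    # outside 45 deg
    ]
    targets = {"T": {"fri_sign": 1, "dsi_threshold": 0.3, "pd": 0.0, "pd_tol": 45.0}}
    assert select_models(results, targets) == [0]
    assert select_models([], targets) == []
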