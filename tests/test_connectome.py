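"""Connectome loading, tiling, weights, parameter sharing and counting."""

import io

import numpy as np
import pandas as pd
import pytest

from dmnet.autodiff import Tensor
from dmnet.connectome import (CellTypeSpec, ConnectomeSpec, FilterEntry,
                              SchemaError, SharingScheme, SignTable,
                              build_scheme_parameters, count_parameters,
                              init_parameters, load_connectome, tile, weight,
                              window_offsets, scheme_filters)
from dmnet.hexlattice import enumerate_hex


def two_type_spec():
    signs = SignTable()
    signs[("A", "B")] = 1
    return ConnectomeSpec(
        types=[CellTypeSpec("A"), CellTypeSpec("B")],
        filters=[FilterEntry("A", "B", 1, 0, 3.0)],
        signs=signs,
    )


# ------------------------------------------------------------------- loading


def test_load_connectome_roundtrip_and_counts():
    filt = pd.DataFrame(
        {"pre_type": ["A", "A"], "post_type": ["B", "B"], "du": [0, 1],
         "dv": [0, 0], "count": [2.0, 4.0]}
    )
    sgn = pd.DataFrame({"pre_type": ["A"], "post_type": ["B"], "sign": [-1]})
    cov = pd.DataFrame({"type": ["A", "A", "B"], "u": [0, 1, 0], "v": [0, 0, 0]})
    spec = load_connectome(filt, sgn, cov)
    assert spec.type_names == ["A", "B"]
    assert len(spec.filters) == 2
    assert spec.signs[("A", "B")] == -1
    assert spec.coverage_of("A") == frozenset({(0, 0), (1, 0)})


def test_load_empty_filter_table():
    filt = pd.DataFrame({"pre_type": [], "post_type": [], "du": [], "dv": [], "count": []})
    sgn = pd.DataFrame({"pre_type": ["A"], "post_type": ["A"], "sign": [1]})
    spec = load_connectome(filt, sgn)
    assert spec.filters == []


@pytest.mark.parametrize(
    "mutation",
    ["undeclared_type", "duplicate_filter", "missing_sign", "bad_sign", "bad_count"],
)
def test_schema_errors(mutation):
    filt = {"pre_type": ["A"], "post_type": ["B"], "du": [0], "dv": [0], "count": [2.0]}
    sgn = {"pre_type": ["A"], "post_type": ["B"], "sign": [1]}
    cov = None
    if mutation == "undeclared_type":
        cov = pd.DataFrame({"type": ["Z"], "u": [0], "v": [0]})
    elif mutation == "duplicate_filter":
        filt = {k: v * 2 for k, v in filt.items()}
    elif mutation == "missing_sign":
        sgn = {"pre_type": ["A"], "post_type": ["A"], "sign": [1]}
        filt["post_type"] = ["B"]
    elif mutation == "bad_sign":
        sgn["sign"] = [2]
    elif mutation == "bad_count":
        filt["count"] = [0.0]
    with pytest.raises(SchemaError):
        load_connectome(pd.DataFrame(filt), pd.DataFrame(sgn), cov)


# -------------------------------------------------------------------- tiling


def test_tile_self_filter_single_column():
    signs = SignTable()
    signs[("A", "A")] = 1
    spec = ConnectomeSpec(types=[CellTypeSpec("A")],
                          filters=[FilterEntry("A", "A", 0, 0, 1.0)], signs=signs)
    net = tile(spec, enumerate_hex(0))
    assert net.n_neurons == 1 and net.n_connections == 1


def test_tile_offset_filter_radius1():
    """One offset-(1,0) filter on radius 1: 14 neurons, 4 connections.

    Manual enumeration: the postsynaptic column (u, v) must have (u-1, v)
    inside the radius-1 hex; exactly (0,0), (1,0), (0,1) and (1,-1) qualify.
    """
    net = tile(two_type_spec(), enumerate_hex(1))
    assert net.n_neurons == 14
    assert net.n_connections == 4


def test_tile_matches_brute_force_double_loop(motif, lattice4):
    net = tile(motif.spec, lattice4)
    filt_lut = {}
    for f in motif.spec.filters:
        filt_lut[(f.pre_type, f.post_type, f.du, f.dv)] = True
    tn = motif.spec.type_names
    count = 0
    for i in range(net.n_neurons):  # postsynaptic
        ui, vi = lattice4.u[net.neuron_col[i]], lattice4.v[net.neuron_col[i]]
        for j in range(net.n_neurons):
            uj, vj = lattice4.u[net.neuron_col[j]], lattice4.v[net.neuron_col[j]]
            key = (tn[net.neuron_type[j]], tn[net.neuron_type[i]], int(ui - uj), int(vi - vj))
            if key in filt_lut:
                count += 1
    assert count == net.n_connections
    # every recorded connection offset matches its filter entry
    for c in range(net.n_connections):
        f = motif.spec.filters[net.filter_idx[c]]
        post, pre = net.post_idx[c], net.pre_idx[c]
        du = int(lattice4.u[net.neuron_col[post]] - lattice4.u[net.neuron_col[pre]])
        dv = int(lattice4.v[net.neuron_col[post]] - lattice4.v[net.neuron_col[pre]])
        assert (du, dv) == (f.du, f.dv)


def test_tiling_translation_equivariance():
    """Translating a partial coverage translates the neuron set identically."""
    lattice = enumerate_hex(2)
    base = {(0, 0), (1, 0)}
    shifted = {(u + 1, v) for u, v in base} | set()

    def neurons(cov):
        signs = SignTable()
        signs[("A", "A")] = 1
        spec = ConnectomeSpec(types=[CellTypeSpec("A", frozenset(cov))],
                              filters=[FilterEntry("A", "A", 1, 0, 1.0)], signs=signs)
        net = tile(spec, lattice)
        return {(int(lattice.u[c]), int(lattice.v[c])) for c in net.neuron_col}

    assert neurons(shifted) == {(u + 1, v) for (u, v) in neurons(base)}


# ------------------------------------------------------------------- weights


def test_weight_formula_and_ratio():
    e5 = FilterEntry("A", "B", 0, 0, 5.0)
    e10 = FilterEntry("A", "B", 0, 0, 10.0)
    assert weight(e5, 1, 0.01) / weight(e10, 1, 0.01) == pytest.approx(0.5)
    assert weight(e10, -1, 0.01) == pytest.approx(-0.1)
    assert weight(e5, 1, 0.0) == 0.0
    with pytest.raises(ValueError):
        weight(e5, 1, -0.1)


def test_init_parameters_statistics():
    signs = SignTable()
    signs[("A", "B")] = 1
    spec = ConnectomeSpec(
        types=[CellTypeSpec("A"), CellTypeSpec("B")],
        filters=[FilterEntry("A", "B", 0, 0, 2.0), FilterEntry("A", "B", 1, 0, 4.0)],
        signs=signs,
    )
    p1 = init_parameters(spec, seed=7)
    p2 = init_parameters(spec, seed=7)
    assert p1.alpha[0] == pytest.approx(0.01 / 3.0)  # <N> = 3
    assert np.all(p1.tau == 50.0)
    np.testing.assert_array_equal(p1.v_rest, p2.v_rest)
    assert not np.array_equal(init_parameters(spec, seed=8).v_rest, p1.v_rest)


# ------------------------------------------------------------------ counting


@pytest.mark.parametrize(
    "scheme, kwargs, expected",
    [
        ("unconstrained", dict(T=65, C=721), 2_196_421_955),
        ("type_convolutional", dict(T=65, C=721), 3_046_355),
        ("filter_window", dict(T=65, F=5), 384_605),
        ("connectome_sparse", dict(T=65, Q=604), 734),
        ("unconstrained", dict(T=1, C=1), 3),
    ],
)
def test_count_parameters(scheme, kwargs, expected):
    assert count_parameters(scheme, **kwargs) == expected


def test_count_parameters_unknown_scheme():
    with pytest.raises(ValueError):
        count_parameters("bogus", T=1, C=1)


# ----------------------------------------------------------- sharing schemes


def test_window_offsets_count():
    assert len(window_offsets(3)) == 19  # 3-column hex window


def test_full_scheme_trainable_count(motif, motif_net):
    sp = build_scheme_parameters(motif.spec, SharingScheme.full, seed=0, network=motif_net)
    Q = len(motif.spec.pairs)
    T = len(motif.spec.types)
    assert sp.trainable_count() == Q + 2 * T


def test_learn_signs_freezes_counts(motif, motif_net):
    sp = build_scheme_parameters(motif.spec, SharingScheme.learn_signs, seed=0,
                                 network=motif_net)
    assert set(sp.tensors) == {"tau", "v_rest", "alpha", "sigma"}
    assert np.all(np.isin(sp.tensors["sigma"].data, [-1.0, 1.0]))
    w = sp.connection_weights().data
    # magnitudes proportional to measured counts within a pair
    assert np.all(np.abs(w) > 0)


def test_learned_filter_schemes_span_window(motif):
    filters = scheme_filters(motif.spec, SharingScheme.learn_all)
    assert len(filters) == len(motif.spec.pairs) * 19


def test_scheme_seed_reproducibility(motif, motif_net):
    a = build_scheme_parameters(motif.spec, SharingScheme.learn_weights, seed=3,
                                network=motif_net)
    b = build_scheme_parameters(motif.spec, SharingScheme.learn_weights, seed=3,
                                network=motif_net)
    np.testing.assert_array_equal(a.tensors["w"].data, b.tensors["w"].data)


def test_clamp_projects_nonnegative(motif, motif_net):
    sp = build_scheme_parameters(motif.spec, SharingScheme.full, seed=0, network=motif_net)
    sp.tensors["alpha"].data[:] = -1.0
    sp.tensors["tau"].data[:] = 1.0
    sp.clamp(dt=5.0)
    assert np.all(sp.tensors["alpha"].data == 0.0)
    assert np.all(sp.tensors["tau"].data == 5.0)


def test_compiled_weights_match_naive_per_connection(motif, motif_net, rng):
    """Gather/scatter weight buffers equal the per-connection formula."""
    sp = build_scheme_parameters(motif.spec, SharingScheme.full, seed=0, network=motif_net)
    w = sp.connection_weights().data
    alpha = sp.tensors["alpha"].data
    for c in rng.choice(motif_net.n_connections, size=40, replace=False):
        f = motif.spec.filters[motif_net.filter_idx[c]]
        q = motif.spec.pairs.index((f.pre_type, f.post_type))
        sigma = motif.spec.signs[(f.pre_type, f.post_type)]
        assert w[c] == pytest.approx(alpha[q] * sigma * f.count)
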