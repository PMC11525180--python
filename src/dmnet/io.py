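"""Serialization: HDF5 model containers, trace stores, JSON reports.

Layout of a model container (version 1):

    /meta             attrs: format_version, radius, type_names (JSON)
    /neurons/type     (n_neurons,) int
    /neurons/col      (n_neurons,) int
    /connections/pre  (n_conn,) int        /connections/post, /connections/filter
    /filters/pair     (n_filters,) int     /filters/sign, /filters/count
    /filters/pairs    JSON list of [pre_type, post_type]
    /spec/...         the connectome tables needed to rebuild the spec
    /params/tau       (T,)   /params/v_rest (T,)   /params/alpha (n_pairs,)
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .connectome import (AssembledNetwork, CellTypeSpec, ConnectomeSpec,
                         FilterEntry, ParamSet, SignTable)
from .dynamics import ResponseTrace
from .hexlattice import enumerate_hex

__all__ = ["save_model", "load_model", "save_trace", "load_trace", "FormatError"]

FORMAT_VERSION = 1


class FormatError(ValueError):
    """Unreadable or version-incompatible container."""


def _spec_to_json(spec: ConnectomeSpec) -> str:
    return json.dumps(
        {
            "types": [
                {
                    "name": t.name,
                    "coverage": sorted(map(list, t.coverage)) if t.coverage is not None else None,
                    "compartment_of": t.compartment_of,
                }
                for t in spec.types
            ],
            "filters": [[f.pre_type, f.post_type, f.du, f.dv, f.count] for f in spec.filters],
            "signs": [[k[0], k[1], v] for k, v in spec.signs.items()],
            "input_types": list(spec.input_types),
            "output_types": list(spec.output_types),
        }
    )


def _spec_from_json(s: str) -> ConnectomeSpec:
    d = json.loads(s)
    signs = SignTable()
    for pre, post, v in d["signs"]:
        signs[(pre, post)] = int(v)
    return ConnectomeSpec(
        types=[
            CellTypeSpec(
                name=t["name"],
                coverage=frozenset(map(tuple, t["coverage"])) if t["coverage"] is not None else None,
                compartment_of=t["compartment_of"],
            )
            for t in d["types"]
        ],
        filters=[FilterEntry(p, q, int(du), int(dv), float(c)) for p, q, du, dv, c in d["filters"]],
        signs=signs,
        input_types=tuple(d["input_types"]),
        output_types=tuple(d["output_types"]),
    )


def save_model(path, network: AssembledNetwork, params: ParamSet | None = None):
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["format_version"] = FORMAT_VERSION
        meta.attrs["radius"] = network.lattice.radius
        meta.attrs["spec"] = _spec_to_json(network.spec)
        g = f.create_group("neurons")
        g["type"] = network.neuron_type
        g["col"] = network.neuron_col
        g = f.create_group("connections")
        g["pre"] = network.pre_idx
        g["post"] = network.post_idx
        g["filter"] = network.filter_idx
        g = f.create_group("filters")
        g["pair"] = network.f_pair
        g["sign"] = network.f_sign
        g["count"] = network.f_count
        g.attrs["pairs"] = json.dumps(network.pairs)
        if params is not None:
            g = f.create_group("params")
            g["tau"] = params.tau
            g["v_rest"] = params.v_rest
            g["alpha"] = params.alpha


def load_model(path):
    """Returns (AssembledNetwork, ParamSet | None)."""
    try:
        with h5py.File(path, "r") as f:
            if "meta" not in f or "format_version" not in f["meta"].attrs:
                raise FormatError(f"{path}: not a model container")
            ver = int(f["meta"].attrs["format_version"])
            if ver != FORMAT_VERSION:
                raise FormatError(f"{path}: format version {ver} != {FORMAT_VERSION}")
            spec = _spec_from_json(f["meta"].attrs["spec"])
            lattice = enumerate_hex(int(f["meta"].attrs["radius"]))
            pairs = [tuple(p) for p in json.loads(f["filters"].attrs["pairs"])]
            net = AssembledNetwork(
                spec=spec,
                lattice=lattice,
                type_names=spec.type_names,
                neuron_type=f["neurons/type"][:],
                neuron_col=f["neurons/col"][:],
                pre_idx=f["connections/pre"][:],
                post_idx=f["connections/post"][:],
                filter_idx=f["connections/filter"][:],
                f_pair=f["filters/pair"][:],
                f_sign=f["filters/sign"][:],
                f_count=f["filters/count"][:],
                pairs=pairs,
                pair_pre_type=np.array(
                    [spec.type_names.index(p) for p, _ in pairs], dtype=np.int64
                ),
            )
            params = None
            if "params" in f:
                params = ParamSet(tau=f["params/tau"][:], v_rest=f["params/v_rest"][:],
                                  alpha=f["params/alpha"][:])
            return net, params
    except OSError as e:
        raise FormatError(f"{path}: unreadable container ({e})") from None


def save_trace(path, trace: ResponseTrace):
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["dt"] = trace.dt
        f.attrs["meta"] = json.dumps(trace.meta, default=str)
        f["data"] = trace.data
        f["neuron_ids"] = trace.neuron_ids


def load_trace(path) -> ResponseTrace:
    try:
        with h5py.File(path, "r") as f:
            return ResponseTrace(data=f["data"][:], dt=float(f.attrs["dt"]),
                                 neuron_ids=f["neuron_ids"][:],
                                 meta=json.loads(f.attrs["meta"]))
    except (OSError, KeyError) as e:
        raise FormatError(f"{path}: unreadable trace ({e})") from None
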