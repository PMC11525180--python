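"""Connectome data model, CSV readers, network assembly and parameter sharing.

A connectome is consumed as three plain tables:

* a **filter table** ``(pre_type, post_type, du, dv, count)`` giving the
  average synapse count between cells of two types at a columnar offset
  ``(du, dv) = (u_post - u_pre, v_post - v_pre)``;
* a **sign table** ``(pre_type, post_type, sign)`` with sign in {-1, +1}
  (depolarizing/hyperpolarizing), derived upstream from neurotransmitter
  profiling and consumed here as data;
* a **coverage table** ``(type, u, v)`` listing the columns in which a cell
  of the given type exists (omitted types cover every column).

Tiling replicates this local, translation-invariant connectivity across a
hexagonal lattice: one neuron per (type, covered column), one connection per
filter entry per column pair with both endpoints instantiated.  Connections
whose presynaptic column falls outside the lattice are truncated, not
wrapped.

The synaptic weight of a connection is ``w = alpha * sigma * N``: the count
``N`` and sign ``sigma`` come from the tables, while the non-negative unitary
synapse strength ``alpha`` is shared across all connections of one type pair
and is the quantity task optimization estimates.  Alternative parameter-
sharing schemes (used to probe which connectome measurements matter) relax
parts of this: learning per-offset magnitudes, learning connectivity within
a three-column window, learning signs, or learning fully signed weights.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .hexlattice import HexArray, hex_count

__all__ = [
    "CellTypeSpec",
    "FilterEntry",
    "SignTable",
    "ConnectomeSpec",
    "ParamSet",
    "AssembledNetwork",
    "SharingScheme",
    "SchemeParameters",
    "SchemaError",
    "load_connectome",
    "tile",
    "weight",
    "init_parameters",
    "count_parameters",
    "build_scheme_parameters",
    "window_offsets",
]


class SchemaError(ValueError):
    """Malformed or referentially inconsistent connectome table."""


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    coverage: frozenset | None = None  # set of (u, v); None = every column
    compartment_of: str | None = None  # e.g. CT1(M10), CT1(Lo1) -> CT1


@dataclass(frozen=True)
class FilterEntry:
    pre_type: str
    post_type: str
    du: int
    dv: int
    count: float

    def __post_init__(self):
        if self.count <= 0:
            raise SchemaError(f"synapse count must be positive, got {self.count}")


class SignTable(dict):
    """(pre_type, post_type) -> sign in {-1, +1}."""

    def __setitem__(self, key, value):
        if value not in (-1, 1):
            raise SchemaError(f"sign must be -1 or +1, got {value}")
        super().__setitem__(key, value)


@dataclass
class ConnectomeSpec:
    types: list[CellTypeSpec]
    filters: list[FilterEntry]
    signs: SignTable
    input_types: tuple[str, ...] = ()   # photoreceptors receiving external input
    output_types: tuple[str, ...] = ()  # decoder input types
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [t.name for t in self.types]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate cell-type names")
        declared = set(names)
        seen = set()
        for i, f in enumerate(self.filters):
            if f.pre_type not in declared:
                raise SchemaError(f"filter row {i}: unknown pre_type {f.pre_type!r}")
            if f.post_type not in declared:
                raise SchemaError(f"filter row {i}: unknown post_type {f.post_type!r}")
            key = (f.pre_type, f.post_type, f.du, f.dv)
            if key in seen:
                raise SchemaError(f"filter row {i}: duplicate entry {key}")
            seen.add(key)
            if (f.pre_type, f.post_type) not in self.signs:
                raise SchemaError(
                    f"filter row {i}: missing sign for pair ({f.pre_type}, {f.post_type})"
                )

    @property
    def type_names(self) -> list[str]:
        return [t.name for t in self.types]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        """Connected type pairs in deterministic (filter-table) order."""
        out, seen = [], set()
        for f in self.filters:
            key = (f.pre_type, f.post_type)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def coverage_of(self, name: str) -> frozenset | None:
        for t in self.types:
            if t.name == name:
                return t.coverage
        raise KeyError(name)


def load_connectome(filter_table, sign_table, coverage_table=None, input_types=(),
                    output_types=()) -> ConnectomeSpec:
    """Read a connectome from CSV paths (or DataFrames) and validate it."""
    filt = filter_table if isinstance(filter_table, pd.DataFrame) else pd.read_csv(filter_table)
    sgn = sign_table if isinstance(sign_table, pd.DataFrame) else pd.read_csv(sign_table)
    cov = None
    if coverage_table is not None:
        cov = coverage_table if isinstance(coverage_table, pd.DataFrame) else pd.read_csv(coverage_table)

    for col in ("pre_type", "post_type", "du", "dv", "count"):
        if col not in filt.columns:
            raise SchemaError(f"filter table missing column {col!r}")
    for col in ("pre_type", "post_type", "sign"):
        if col not in sgn.columns:
            raise SchemaError(f"sign table missing column {col!r}")

    names = sorted(set(filt.pre_type) | set(filt.post_type) | set(sgn.pre_type) | set(sgn.post_type))
    coverage: dict[str, set] = {}
    if cov is not None:
        for col in ("type", "u", "v"):
            if col not in cov.columns:
                raise SchemaError(f"coverage table missing column {col!r}")
        unknown = set(cov.type) - set(names)
        if unknown:
            raise SchemaError(f"coverage table references undeclared types {sorted(unknown)}")
        for row in cov.itertuples():
            coverage.setdefault(row.type, set()).add((int(row.u), int(row.v)))

    types = [
        CellTypeSpec(name=n, coverage=frozenset(coverage[n]) if n in coverage else None)
        for n in names
    ]
    signs = SignTable()
    for i, row in enumerate(sgn.itertuples()):
        try:
            signs[(row.pre_type, row.post_type)] = int(row.sign)
        except SchemaError as e:
            raise SchemaError(f"sign table row {i}: {e}") from None
    filters = []
    for i, row in enumerate(filt.itertuples()):
        try:
            filters.append(
                FilterEntry(row.pre_type, row.post_type, int(row.du), int(row.dv), float(row.count))
            )
        except SchemaError as e:
            raise SchemaError(f"filter table row {i}: {e}") from None
    return ConnectomeSpec(types=types, filters=filters, signs=signs,
                          input_types=tuple(input_types), output_types=tuple(output_types))


# --------------------------------------------------------------------- tiling


@dataclass
class AssembledNetwork:
    """Neurons and connections compiled to flat index buffers.

    Neuron ids are dense, ordered by type (spec order) then by lattice
    (ring) order.  ``pre_idx/post_idx/filter_idx`` form the connection list;
    the per-filter arrays (``f_pair``, ``f_sign``, ``f_count``) let weight
    buffers be built by gather operations.
    """

    spec: ConnectomeSpec
    lattice: HexArray
    type_names: list[str]
    neuron_type: np.ndarray   # (n_neurons,) index into type_names
    neuron_col: np.ndarray    # (n_neurons,) index into lattice
    pre_idx: np.ndarray       # (n_connections,)
    post_idx: np.ndarray
    filter_idx: np.ndarray    # (n_connections,) index into filter arrays
    f_pair: np.ndarray        # (n_filters,) index into pairs
    f_sign: np.ndarray        # (n_filters,)
    f_count: np.ndarray       # (n_filters,)
    pairs: list[tuple[str, str]]
    pair_pre_type: np.ndarray  # (n_pairs,) index into type_names

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_type)

    @property
    def n_connections(self) -> int:
        return len(self.pre_idx)

    def neurons_of_type(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.neuron_type == self.type_names.index(name))

    def neuron_at(self, name: str, u: int, v: int) -> int:
        t = self.type_names.index(name)
        col = self.lattice.position(u, v)
        hits = np.flatnonzero((self.neuron_type == t) & (self.neuron_col == col))
        if len(hits) != 1:
            raise KeyError(f"no neuron of type {name} at ({u}, {v})")
        return int(hits[0])

    def central_neuron(self, name: str) -> int:
        return self.neuron_at(name, 0, 0)

    def connection_weights(self, alpha_per_pair) -> np.ndarray | Tensor:
        """w_conn = alpha[pair] * sign * count, gathered per connection."""
        per_filter = alpha_per_pair[self.f_pair] * (self.f_sign * self.f_count)
        return per_filter[self.filter_idx]


def tile(spec: ConnectomeSpec, lattice: HexArray, filters=None) -> AssembledNetwork:
    """Tile the local connectivity across the lattice (translation invariant)."""
    filters = spec.filters if filters is None else filters
    type_names = spec.type_names

    neuron_type, neuron_col = [], []
    id_of: list[dict[int, int]] = []  # per type: lattice position -> neuron id
    nid = 0
    for t, tspec in enumerate(spec.types):
        lut = {}
        for pos in range(len(lattice)):
            c = (int(lattice.u[pos]), int(lattice.v[pos]))
            if tspec.coverage is None or c in tspec.coverage:
                neuron_type.append(t)
                neuron_col.append(pos)
                lut[pos] = nid
                nid += 1
        id_of.append(lut)

    pairs, pair_index = [], {}
    for f in filters:
        key = (f.pre_type, f.post_type)
        if key not in pair_index:
            pair_index[key] = len(pairs)
            pairs.append(key)

    f_pair = np.array([pair_index[(f.pre_type, f.post_type)] for f in filters], dtype=np.int64)
    f_sign = np.array([spec.signs[(f.pre_type, f.post_type)] for f in filters], dtype=np.float64)
    f_count = np.array([f.count for f in filters], dtype=np.float64)

    pre_l, post_l, filt_l = [], [], []
    for fi, f in enumerate(filters):
        t_pre = type_names.index(f.pre_type)
        t_post = type_names.index(f.post_type)
        for pos, post_id in id_of[t_post].items():
            up = int(lattice.u[pos]) - f.du
            vp = int(lattice.v[pos]) - f.dv
            pre_pos = lattice.index.get((up, vp))
            if pre_pos is None:
                continue  # boundary truncation
            pre_id = id_of[t_pre].get(pre_pos)
            if pre_id is None:
                continue  # pre type does not cover that column
            pre_l.append(pre_id)
            post_l.append(post_id)
            filt_l.append(fi)

    pair_pre_type = np.array([type_names.index(p) for p, _ in pairs], dtype=np.int64)
    return AssembledNetwork(
        spec=spec,
        lattice=lattice,
        type_names=type_names,
        neuron_type=np.array(neuron_type, dtype=np.int64),
        neuron_col=np.array(neuron_col, dtype=np.int64),
        pre_idx=np.array(pre_l, dtype=np.int64),
        post_idx=np.array(post_l, dtype=np.int64),
        filter_idx=np.array(filt_l, dtype=np.int64),
        f_pair=f_pair,
        f_sign=f_sign,
        f_count=f_count,
        pairs=pairs,
        pair_pre_type=pair_pre_type,
    )


def weight(entry: FilterEntry, sign: int, alpha: float) -> float:
    """Synaptic weight w = alpha * sigma * N for one filter entry."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return alpha * sign * entry.count


# ----------------------------------------------------------------- parameters


@dataclass
class ParamSet:
    """Shared biophysical parameters of the fully connectome-constrained model."""

    tau: np.ndarray     # (T,) membrane time constants, ms
    v_rest: np.ndarray  # (T,) resting potentials, a.u.
    alpha: np.ndarray   # (n_pairs,) unitary synapse strengths, non-negative

    def connection_weights(self, network: AssembledNetwork) -> np.ndarray:
        return network.connection_weights(self.alpha)


def init_parameters(spec: ConnectomeSpec, seed: int = 0,
                    tau0: float = 50.0, v_rest_mean: float = 0.5,
                    v_rest_var: float = 0.05) -> ParamSet:
    """Initial parameters: tau = 50 ms, V_rest ~ N(0.5, 0.05), alpha = 0.01/<N>."""
    rng = np.random.default_rng(seed)
    T = len(spec.types)
    pairs = spec.pairs
    mean_count = np.zeros(len(pairs))
    for q, (pre, post) in enumerate(pairs):
        counts = [f.count for f in spec.filters if (f.pre_type, f.post_type) == (pre, post)]
        mean_count[q] = np.mean(counts)
    return ParamSet(
        tau=np.full(T, tau0),
        v_rest=rng.normal(v_rest_mean, np.sqrt(v_rest_var), size=T),
        alpha=0.01 / mean_count,
    )


def count_parameters(scheme: str, T: int = 0, C: int = 0, F: int = 0, Q: int = 0) -> int:
    """Free-parameter count under a sharing scheme.

    ``unconstrained``: every pairwise weight plus per-neuron tau and V_rest,
    (TC)^2 + 2TC.  ``type_convolutional``: full-lattice filters shared per
    type pair, T^2 C + 2T.  ``filter_window``: filters restricted to a
    radius-F window of P = 3F(F+1)+1 columns, T^2 P + 2T.
    ``sparse_filter_window``: only the Q connected type pairs, Q P + 2T.
    ``connectome_sparse``: one unitary synapse strength per connected type
    pair, Q + 2T.
    """
    if scheme == "unconstrained":
        if T <= 0 or C <= 0:
            raise ValueError("T and C required")
        return (T * C) ** 2 + 2 * T * C
    if scheme == "type_convolutional":
        if T <= 0 or C <= 0:
            raise ValueError("T and C required")
        return T * T * C + 2 * T
    if scheme == "filter_window":
        if T <= 0 or F <= 0:
            raise ValueError("T and F required")
        return T * T * hex_count(F) + 2 * T
    if scheme == "sparse_filter_window":
        if T <= 0 or F <= 0 or Q <= 0:
            raise ValueError("T, F and Q required")
        return Q * hex_count(F) + 2 * T
    if scheme == "connectome_sparse":
        if T <= 0 or Q <= 0:
            raise ValueError("T and Q required")
        return Q + 2 * T
    raise ValueError(f"unknown scheme {scheme!r}")


# ------------------------------------------------------------ sharing schemes


class SharingScheme(str, enum.Enum):
    full = "full"                  # measured counts + signs; learn alpha
    learn_counts = "learn_counts"  # signs + single-cell adjacency known; learn magnitudes
    learn_cell_conn = "learn_cell_conn"  # type connectivity + signs known; 3-column window
    learn_signs = "learn_signs"    # counts known; learn per-pre-type signs (+ alphas)
    learn_weights = "learn_weights"      # adjacency known; learn signed weights
    learn_all = "learn_all"        # type connectivity only; signed 3-column window


def window_offsets(max_dist: int = 3) -> list[tuple[int, int]]:
    """All hex offsets with |du|, |dv|, |du+dv| < max_dist (19 for max_dist=3)."""
    out = []
    r = max_dist - 1
    for du in range(-r, r + 1):
        for dv in range(-r, r + 1):
            if abs(du + dv) <= r:
                out.append((du, dv))
    return out


def scheme_filters(spec: ConnectomeSpec, scheme: SharingScheme) -> list[FilterEntry]:
    """Filter set to tile with: measured offsets, or a 3-column window for the
    schemes that learn single-cell connectivity."""
    scheme = SharingScheme(scheme)
    if scheme in (SharingScheme.learn_cell_conn, SharingScheme.learn_all):
        return [
            FilterEntry(pre, post, du, dv, 1.0)
            for pre, post in spec.pairs
            for du, dv in window_offsets()
        ]
    return list(spec.filters)


@dataclass
class SchemeParameters:
    """Trainable buffers for one sharing scheme, over an assembled network.

    ``tensors`` maps buffer names to autodiff Tensors; non-negativity masks
    are applied by :meth:`clamp` after each optimizer step (projected
    gradient descent).
    """

    scheme: SharingScheme
    network: AssembledNetwork
    tensors: dict
    nonneg: tuple[str, ...]
    dt_floor: float = 0.0  # tau clamp floor, set by the trainer

    @property
    def tau(self) -> Tensor:
        return self.tensors["tau"]

    @property
    def v_rest(self) -> Tensor:
        return self.tensors["v_rest"]

    def connection_weights(self, network: AssembledNetwork | None = None):
        net = network or self.network
        s = self.scheme
        if s == SharingScheme.full:
            per_filter = self.tensors["alpha"][net.f_pair] * Tensor(net.f_sign * net.f_count)
        elif s == SharingScheme.learn_counts:
            per_filter = self.tensors["m"] * Tensor(net.f_sign)
        elif s == SharingScheme.learn_cell_conn:
            per_filter = self.tensors["m"] * Tensor(net.f_sign)
        elif s == SharingScheme.learn_signs:
            sigma = self.tensors["sigma"][net.pair_pre_type]  # per pre type
            per_filter = self.tensors["alpha"][net.f_pair] * sigma[net.f_pair] * Tensor(net.f_count)
        elif s in (SharingScheme.learn_weights, SharingScheme.learn_all):
            per_filter = self.tensors["w"]
        else:  # pragma: no cover
            raise ValueError(s)
        return per_filter[net.filter_idx]

    def trainable_count(self) -> int:
        return sum(t.data.size for t in self.tensors.values() if t.requires_grad)

    def clamp(self, dt: float | None = None):
        for name in self.nonneg:
            t = self.tensors[name]
            np.maximum(t.data, 0.0, out=t.data)
        floor = self.dt_floor if dt is None else dt
        if floor > 0:
            np.maximum(self.tensors["tau"].data, floor, out=self.tensors["tau"].data)

    def parameters(self) -> list[Tensor]:
        return [t for t in self.tensors.values() if t.requires_grad]


def scheme_from_paramset(network: AssembledNetwork, params: ParamSet,
                         trainable: bool = True) -> SchemeParameters:
    """Wrap an explicit ParamSet as trainable buffers of the `full` scheme."""
    tensors = {
        "tau": Tensor(np.asarray(params.tau, dtype=float).copy(), requires_grad=trainable),
        "v_rest": Tensor(np.asarray(params.v_rest, dtype=float).copy(), requires_grad=trainable),
        "alpha": Tensor(np.asarray(params.alpha, dtype=float).copy(), requires_grad=trainable),
    }
    return SchemeParameters(scheme=SharingScheme.full, network=network,
                            tensors=tensors, nonneg=("alpha",))


def build_scheme_parameters(spec: ConnectomeSpec, scheme: SharingScheme,
                            seed: int = 0, lattice: HexArray | None = None,
                            network: AssembledNetwork | None = None) -> SchemeParameters:
    """Assemble (if needed) and lay out trainable/frozen buffers for a scheme.

    Magnitudes/weights that are learned from scratch are initialized from
    N(0, 2/n_in) (n_in = mean presynaptic connections per neuron), magnitudes
    taken non-negative by absolute value; learned signs start at +/-1 with
    equal probability.
    """
    scheme = SharingScheme(scheme)
    rng = np.random.default_rng(seed)
    if network is None:
        if lattice is None:
            raise ValueError("provide a lattice or a pre-assembled network")
        network = tile(spec, lattice, filters=scheme_filters(spec, scheme))

    T = len(spec.types)
    base = init_parameters(spec, seed=seed)
    n_in = max(network.n_connections / max(network.n_neurons, 1), 1.0)
    std = np.sqrt(2.0 / n_in)
    n_filters = len(network.f_count)

    tensors = {
        "tau": Tensor(np.full(T, 50.0), requires_grad=True),
        "v_rest": Tensor(base.v_rest.copy(), requires_grad=True),
    }
    nonneg: tuple[str, ...] = ()
    if scheme == SharingScheme.full:
        tensors["alpha"] = Tensor(base.alpha.copy(), requires_grad=True)
        nonneg = ("alpha",)
    elif scheme in (SharingScheme.learn_counts, SharingScheme.learn_cell_conn):
        tensors["m"] = Tensor(np.abs(rng.normal(0, std, size=n_filters)), requires_grad=True)
        nonneg = ("m",)
    elif scheme == SharingScheme.learn_signs:
        tensors["alpha"] = Tensor(base.alpha.copy(), requires_grad=True)
        tensors["sigma"] = Tensor(rng.choice([-1.0, 1.0], size=T), requires_grad=True)
        nonneg = ("alpha",)
    elif scheme in (SharingScheme.learn_weights, SharingScheme.learn_all):
        tensors["w"] = Tensor(rng.normal(0, std, size=n_filters), requires_grad=True)
    return SchemeParameters(scheme=scheme, network=network, tensors=tensors, nonneg=nonneg)
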