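"""Threshold-linear voltage dynamics with Euler integration.

Each point neuron i of cell type t follows

    tau_t dV_i/dt = -V_i + sum_j w_ij f(V_j) + V_rest_t + e_i,

with f(V) = max(V, 0) modelling graded, voltage-gated transmitter release
(rectification threshold fixed at 0).  External input e_i is nonzero only
for photoreceptor neurons, which receive the raw [0, 1] luminance of their
column.  Integration is first-order Euler with the time constant clamped at
the step, tau = max(tau, dt).  Before any protocol the network is relaxed on
a grey screen and every simulation starts from that steady state; the state
before the warmup is V = V_rest (the fixed point of the unconnected system).

This module is the fast numpy path used for model characterization; training
re-expresses the same update with autodiff tensors (see :mod:`dmnet.task`)
and the two are tested to agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import AssembledNetwork
from .stimuli import StimulusSequence

__all__ = [
    "SimConfig",
    "ResponseTrace",
    "NumericalDivergence",
    "rectify",
    "step",
    "steady_state",
    "simulate",
    "input_gain_matrix",
]


class NumericalDivergence(RuntimeError):
    """Voltages became non-finite; reports the first bad step."""


def rectify(V):
    """Threshold-linear transfer f(V) = max(V, 0)."""
    return np.maximum(V, 0.0)


@dataclass
class SimConfig:
    dt: float = 5.0            # integration step, ms
    grey_warmup: float = 1000.0  # grey-screen relaxation before protocols, ms
    grey_level: float = 0.5
    record: np.ndarray | None = None  # neuron ids to record (None = all)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class ResponseTrace:
    """Time x recorded-neuron voltages with its time base and metadata."""

    data: np.ndarray          # (n_steps, n_recorded)
    dt: float                 # ms
    neuron_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.dt

    def of(self, neuron_id: int) -> np.ndarray:
        pos = np.flatnonzero(self.neuron_ids == neuron_id)
        if len(pos) != 1:
            raise KeyError(f"neuron {neuron_id} not recorded")
        return self.data[:, pos[0]]


def _photoreceptor_scatter(network: AssembledNetwork):
    """(neuron ids, column ids) of neurons belonging to the input types."""
    input_types = network.spec.input_types
    tidx = [network.type_names.index(t) for t in input_types]
    mask = np.isin(network.neuron_type, tidx)
    return np.flatnonzero(mask), network.neuron_col[mask]


def input_gain_matrix(network: AssembledNetwork):
    """Precompute (photoreceptor neuron ids, their columns) for stimulus injection."""
    return _photoreceptor_scatter(network)


def step(V: np.ndarray, network: AssembledNetwork, w: np.ndarray,
         tau: np.ndarray, v_rest: np.ndarray, e: np.ndarray, dt: float) -> np.ndarray:
    """One Euler step.  `w` is the per-connection weight vector; `tau`/`v_rest`
    are per-type and are broadcast to neurons here; `e` is per neuron."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if V.shape[-1] != network.n_neurons or e.shape[-1] != network.n_neurons:
        raise ValueError("state/input length does not match network")
    tau_n = np.maximum(tau, dt)[network.neuron_type]
    syn = np.zeros_like(V)
    contrib = w * rectify(V[..., network.pre_idx])
    np.add.at(syn, (..., network.post_idx), contrib)
    drive = -V + syn + v_rest[network.neuron_type] + e
    return V + (dt / tau_n) * drive


def _external_input(network, ph_ids, ph_cols, frame, n: int):
    e = np.zeros(n)
    e[ph_ids] = frame[ph_cols]
    return e


def steady_state(network: AssembledNetwork, w, tau, v_rest,
                 luminance: float = 0.5, duration: float = 1000.0,
                 dt: float = 5.0) -> np.ndarray:
    """Relax the network on a constant grey screen and return the state."""
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n = network.n_neurons
    ph_ids, ph_cols = _photoreceptor_scatter(network)
    V = v_rest[network.neuron_type].astype(float).copy()
    e = np.zeros(n)
    e[ph_ids] = luminance
    for k in range(int(round(duration / dt))):
        V = step(V, network, w, tau, v_rest, e, dt)
        if not np.all(np.isfinite(V)):
            raise NumericalDivergence(f"non-finite state at warmup step {k}")
    return V


def simulate(network: AssembledNetwork, params, stimulus: StimulusSequence,
             config: SimConfig | None = None, V0: np.ndarray | None = None) -> ResponseTrace:
    """Integrate the network against a stimulus sequence.

    The stimulus is resampled to the integration rate by zero-order hold and
    injected as external current into the photoreceptor neurons of the
    matching column.  Recording starts at stimulus onset (after the grey
    warmup, which initializes the state unless `V0` is given).
    """
    config = config or SimConfig(dt=stimulus.frame_dt)
    if stimulus.frames.shape[1] != len(network.lattice):
        raise ValueError("stimulus lattice does not match network lattice")
    w = params.connection_weights(network)
    w = w.data if hasattr(w, "data") else np.asarray(w, dtype=float)
    tau = np.asarray(params.tau.data if hasattr(params.tau, "data") else params.tau, dtype=float)
    v_rest = np.asarray(
        params.v_rest.data if hasattr(params.v_rest, "data") else params.v_rest, dtype=float
    )

    dt = config.dt
    if V0 is None:
        V = steady_state(network, w, tau, v_rest, luminance=config.grey_level,
                         duration=config.grey_warmup, dt=dt)
    else:
        V = V0.astype(float).copy()

    n_steps = int(round(stimulus.duration / dt))
    frame_of = np.minimum(
        (np.arange(n_steps) * dt / stimulus.frame_dt).astype(int),
        stimulus.frames.shape[0] - 1,
    )
    record = np.arange(network.n_neurons) if config.record is None else np.asarray(config.record)
    out = np.empty((n_steps, len(record)))
    ph_ids, ph_cols = _photoreceptor_scatter(network)
    for k in range(n_steps):
        e = _external_input(network, ph_ids, ph_cols, stimulus.frames[frame_of[k]],
                            network.n_neurons)
        V = step(V, network, w, tau, v_rest, e, dt)
        if not np.all(np.isfinite(V)):
            raise NumericalDivergence(f"non-finite state at step {k}")
        out[k] = V[record]
    return ResponseTrace(data=out, dt=dt, neuron_ids=record,
                         meta=dict(stimulus=stimulus.meta, dt=dt))
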