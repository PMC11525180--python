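"""Optic-flow decoding and end-to-end training of the network model.

The recurrent network sees greyscale video on its photoreceptors; a
feedforward, per-frame convolutional decoder maps the rectified voltages of
the designated output cell types to a 2-D flow vector per column.  Because
the decoder has no temporal structure, any motion information must come from
the temporal dynamics of the recurrent model.  Decoder and biophysical
parameters are trained jointly by backpropagation through time against the
L2 norm between predicted and true flow, plus an activity regularizer that
keeps time-averaged central-column responses near a target level.

Decoder architecture: the hex lattice is rastered to a Cartesian grid
(axial -> offset rows, collision-free nearest-pixel scatter), then
5x5 conv -> batch norm -> softplus -> dropout -> 5x5 conv to three channels;
the third channel, passed through a softplus, divides the other two as a
shared normalization of the flow prediction.  Filter weights start
homogeneously at 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, SGD, Tensor
from .connectome import AssembledNetwork, SchemeParameters
from .dynamics import steady_state
from .hexlattice import HexArray
from .stimuli import StimulusSequence

__all__ = [
    "DecoderConfig",
    "Decoder",
    "TrainConfig",
    "RegularizerConfig",
    "TrainResult",
    "decode",
    "loss",
    "activity_regularizer",
    "epe",
    "train",
    "validation_epe",
]


# ------------------------------------------------------------------- decoder


@dataclass
class DecoderConfig:
    input_types: tuple[str, ...]   # D cell types feeding the decoder
    hidden_channels: int = 8
    kernel: int = 5
    dropout: float = 0.5
    init_weight: float = 1e-3


def _raster_index(lattice: HexArray):
    """Collision-free axial->offset pixel index; returns (flat index, H, W)."""
    r = lattice.radius
    H = W = 2 * r + 1
    rows = lattice.v + r
    cols = lattice.u + (lattice.v - (lattice.v & 1)) // 2 + r
    if (cols < 0).any() or (cols >= W).any():  # pragma: no cover - by construction
        raise AssertionError("raster overflow")
    flat = rows * W + cols
    assert len(np.unique(flat)) == len(flat)
    return flat.astype(np.int64), H, W


class Decoder:
    """Per-frame convolutional readout of optic flow from D feature maps."""

    def __init__(self, cfg: DecoderConfig, lattice: HexArray, seed: int = 0):
        self.cfg = cfg
        self.lattice = lattice
        self.pix, self.H, self.W = _raster_index(lattice)
        D, k, h = len(cfg.input_types), cfg.kernel, cfg.hidden_channels
        self.w1 = Tensor(np.full((h, D * k * k), cfg.init_weight), requires_grad=True)
        self.b1 = Tensor(np.zeros(h), requires_grad=True)
        self.gamma = Tensor(np.ones(h), requires_grad=True)
        self.beta = Tensor(np.zeros(h), requires_grad=True)
        self.w2 = Tensor(np.full((3, h * k * k), cfg.init_weight), requires_grad=True)
        self.b2 = Tensor(np.zeros(3), requires_grad=True)
        self.run_mean = np.zeros(h)
        self.run_var = np.ones(h)
        self._bn_momentum = 0.1
        self._rng = np.random.default_rng(seed)

    def parameters(self):
        return [self.w1, self.b1, self.gamma, self.beta, self.w2, self.b2]

    def __call__(self, activity: Tensor, train: bool = False) -> Tensor:
        """activity: (B, D, C) rectified voltages -> flow (B, 2, C).

        The batch axis may fold together sequences and frames; the decoder is
        purely per-frame.
        """
        B = activity.shape[0]
        D, k, h = len(self.cfg.input_types), self.cfg.kernel, self.cfg.hidden_channels
        raster = activity.scatter_add(self.pix, self.H * self.W)  # (B, D, H*W)
        raster = raster.reshape(B, D, self.H, self.W)
        cols = raster.unfold2d(k, k)                              # (B, D*k*k, H*W)
        x = self.w1.reshape(1, h, D * k * k) @ cols + self.b1.reshape(1, h, 1)
        x = self._batch_norm(x, train)
        x = x.softplus()
        if train and self.cfg.dropout > 0:
            keep = 1.0 - self.cfg.dropout
            mask = (self._rng.random(x.shape) < keep) / keep
            x = x * mask
        cols2 = x.reshape(B, h, self.H, self.W).unfold2d(k, k)
        y = self.w2.reshape(1, 3, h * k * k) @ cols2 + self.b2.reshape(1, 3, 1)
        flow = y[:, 0:2, :] / y[:, 2:3, :].softplus()
        return flow[:, :, self.pix]  # back to lattice column order

    def _batch_norm(self, x: Tensor, train: bool) -> Tensor:
        # x: (B, h, P); normalize per channel over batch and pixels
        if train:
            n = x.shape[0] * x.shape[2]
            mean = x.sum(axis=2).sum(axis=0) * (1.0 / n)           # (h,)
            cent = x - mean.reshape(1, -1, 1)
            var = (cent * cent).sum(axis=2).sum(axis=0) * (1.0 / n)
            self.run_mean = (1 - self._bn_momentum) * self.run_mean + self._bn_momentum * mean.data
            self.run_var = (1 - self._bn_momentum) * self.run_var + self._bn_momentum * var.data
        else:
            mean = Tensor(self.run_mean)
            cent = x - mean.reshape(1, -1, 1)
            var = Tensor(self.run_var)
        inv = (var + 1e-5) ** -0.5
        xhat = cent * inv.reshape(1, -1, 1)
        return xhat * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


def decoder_input_index(network: AssembledNetwork, input_types) -> np.ndarray:
    """(D, C) neuron ids of the decoder input types in lattice column order."""
    C = len(network.lattice)
    out = np.empty((len(input_types), C), dtype=np.int64)
    for d, name in enumerate(input_types):
        t = network.type_names.index(name)
        mask = network.neuron_type == t
        ids = np.flatnonzero(mask)
        cols = network.neuron_col[mask]
        if len(ids) != C:
            raise ValueError(f"decoder input type {name!r} must cover every column")
        out[d, cols] = ids
    return out


def decode(activity: np.ndarray, decoder: Decoder) -> np.ndarray:
    """Per-frame flow prediction from rectified voltages (N, D, C) -> (N, 2, C)."""
    act = np.maximum(np.asarray(activity, dtype=float), 0.0)
    return decoder(Tensor(act), train=False).data


# ------------------------------------------------------- losses and metrics


def loss(Y, Y_hat):
    """L2 norm of the flow residual (scalar Tensor if inputs are Tensors)."""
    if isinstance(Y, Tensor) or isinstance(Y_hat, Tensor):
        d = (Y_hat if isinstance(Y_hat, Tensor) else Tensor(Y_hat)) - Y
        return ((d * d).sum() + 1e-12) ** 0.5
    Y, Y_hat = np.asarray(Y, dtype=float), np.asarray(Y_hat, dtype=float)
    if Y.shape != Y_hat.shape:
        raise ValueError("shape mismatch")
    return float(np.linalg.norm(Y - Y_hat))


@dataclass
class RegularizerConfig:
    lam: float = 0.1     # overall weight lambda_V
    gamma: float = 1.0   # below-target branch
    delta: float = 0.01  # above-target branch
    a: float = 5.0       # target time-averaged activity, a.u.


def activity_regularizer(vbar, cfg: RegularizerConfig = RegularizerConfig()):
    """Piecewise-quadratic penalty around the target activity `a`.

    `vbar` is the (B, T) matrix of time-averaged central-column responses;
    branches weighted gamma (below a) / delta (above a), averaged over batch
    and types, scaled by lambda_V.
    """
    is_t = isinstance(vbar, Tensor)
    raw = vbar.data if is_t else np.asarray(vbar, dtype=float)
    B, T = raw.shape if raw.ndim == 2 else (1, raw.size)
    below = (raw <= cfg.a).astype(float)
    wts = cfg.gamma * below + cfg.delta * (1.0 - below)
    if is_t:
        d = vbar - cfg.a
        return (d * d * wts).sum() * (cfg.lam / (B * T))
    return float(cfg.lam / (B * T) * np.sum(wts * (raw - cfg.a) ** 2))


def epe(Y, Y_hat) -> float:
    """Average end-point error: mean over frames and columns of the Euclidean
    norm of the per-column flow residual.  Shapes (..., 2, C)."""
    Y, Y_hat = np.asarray(Y, dtype=float), np.asarray(Y_hat, dtype=float)
    if Y.shape != Y_hat.shape:
        raise ValueError("shape mismatch")
    d = Y - Y_hat
    return float(np.mean(np.sqrt(np.sum(d * d, axis=-2))))


# ------------------------------------------------------------------ training


@dataclass
class TrainConfig:
    """Optimizer and schedule; defaults follow the full-scale recipe
    (adaptive-moment SGD, lr decayed 5e-5 -> 5e-6 in ten steps, batch 4,
    19-frame sequences resampled to a 20 ms integration step)."""

    iterations: int = 1000
    lr_start: float = 5e-5
    lr_end: float = 5e-6
    lr_steps: int = 10
    batch: int = 4
    dt: float = 20.0            # integration step, ms
    grey_warmup: float = 500.0  # steady-state relaxation per epoch, ms
    seed: int = 0
    train_dmn: bool = True      # False: frozen-DMN control (decoder only)
    rest_sgd_lr: float = 0.0    # >0: extra plain-SGD phase on V_rest vs R(V)
    regularizer: RegularizerConfig = field(default_factory=RegularizerConfig)
    val_every: int = 50


@dataclass
class TrainResult:
    scheme: SchemeParameters
    decoder: Decoder
    val_epe: list          # (iteration, epe) checkpoints
    train_loss: list


def _resample(seq: StimulusSequence, flow: np.ndarray, dt: float):
    """Zero-order-hold frames and linearly interpolated flow at step times."""
    n_steps = int(round(seq.duration / dt))
    t_hold = np.arange(n_steps) * dt  # zero-order hold, start-of-step frame
    frame_of = np.minimum((t_hold / seq.frame_dt).astype(int), seq.frames.shape[0] - 1)
    frames = seq.frames[frame_of]
    t_step = (np.arange(n_steps) + 1) * dt
    t_frame = (np.arange(seq.frames.shape[0]) + 0.5) * seq.frame_dt
    flow_i = np.empty((n_steps,) + flow.shape[1:])
    for a in range(flow.shape[1]):
        for c in range(flow.shape[2]):
            flow_i[:, a, c] = np.interp(t_step, t_frame, flow[:, a, c])
    return frames, flow_i


def _unroll(network, scheme: SchemeParameters, frames_b: np.ndarray, V0: np.ndarray,
            dt: float, dec_idx: np.ndarray, central_idx: np.ndarray):
    """BPTT forward pass: returns (decoder activity (B*N, D, C), vbar (B, T'))."""
    B, N, C = frames_b.shape
    w = scheme.connection_weights()
    tau_n = scheme.tau.maximum(dt)[network.neuron_type]
    vrest_n = scheme.v_rest[network.neuron_type]
    ph_ids = np.flatnonzero(
        np.isin(network.neuron_type,
                [network.type_names.index(t) for t in network.spec.input_types])
    )
    ph_cols = network.neuron_col[ph_ids]
    V = Tensor(np.broadcast_to(V0, (B, network.n_neurons)).copy())
    dec_steps, central_steps = [], []
    inv_tau = Tensor(dt) / tau_n
    for n in range(N):
        e = np.zeros((B, network.n_neurons))
        e[:, ph_ids] = frames_b[:, n][:, ph_cols]
        rect = V.relu()
        syn = (rect[:, network.pre_idx] * w).scatter_add(network.post_idx, network.n_neurons)
        V = V + inv_tau * (-V + syn + vrest_n + Tensor(e))
        dec_steps.append(V.relu()[:, dec_idx.ravel()])
        central_steps.append(V[:, central_idx])
    act = ad.stack(dec_steps, axis=1)  # (B, N, D*C)
    D = dec_idx.shape[0]
    act = act.reshape(B * N, D, C)
    vbar = ad.stack(central_steps, axis=0).mean(axis=0)  # (B, T')
    return act, vbar


def _central_index(network) -> np.ndarray:
    ids = []
    centre = network.lattice.position(0, 0)
    for t in range(len(network.type_names)):
        hits = np.flatnonzero((network.neuron_type == t) & (network.neuron_col == centre))
        if len(hits):
            ids.append(hits[0])
    return np.array(ids, dtype=np.int64)


def validation_epe(network, scheme, decoder, dataset, dt: float,
                   grey_warmup: float = 500.0) -> float:
    """Mean EPE over a held-out set of (stimulus, flow) pairs."""
    dec_idx = decoder_input_index(network, decoder.cfg.input_types)
    central_idx = _central_index(network)
    w = scheme.connection_weights().data
    tau = scheme.tau.data
    vrest = scheme.v_rest.data
    V0 = steady_state(network, w, tau, vrest, duration=grey_warmup, dt=dt)
    errs = []
    for seq, flow in dataset:
        frames, flow_i = _resample(seq, flow, dt)
        act, _ = _unroll(network, scheme, frames[None], V0, dt, dec_idx, central_idx)
        pred = decoder(act, train=False).data  # (N, 2, C)
        errs.append(epe(flow_i, pred))
    return float(np.mean(errs))


def train(network: AssembledNetwork, scheme: SchemeParameters, decoder: Decoder,
          dataset, cfg: TrainConfig, val_dataset=None) -> TrainResult:
    """Joint gradient training of biophysical parameters and decoder.

    `dataset` is a list of (StimulusSequence, flow) pairs with flow of shape
    (n_frames, 2, C).  Non-negative buffers and time constants are clamped
    after every step (projected gradient descent); the grey-screen initial
    state is recomputed at the start of each epoch with the current
    parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    dec_idx = decoder_input_index(network, decoder.cfg.input_types)
    central_idx = _central_index(network)
    params = list(decoder.parameters())
    if cfg.train_dmn:
        params += scheme.parameters()
    opt = Adam(params, lr=cfg.lr_start)
    rest_opt = SGD([scheme.v_rest], lr=cfg.rest_sgd_lr) if cfg.rest_sgd_lr > 0 else None

    resampled = [_resample(seq, flow, cfg.dt) for seq, flow in dataset]
    n_steps_set = {f.shape[0] for f, _ in resampled}
    if len(n_steps_set) != 1:
        raise ValueError("all training sequences must have equal length")

    order = np.array([], dtype=int)
    V0 = None
    val_curve, loss_curve = [], []

    def lr_at(it):
        k = min(it * cfg.lr_steps // max(cfg.iterations, 1), cfg.lr_steps - 1)
        return cfg.lr_start * (cfg.lr_end / cfg.lr_start) ** (k / max(cfg.lr_steps - 1, 1))

    if val_dataset is not None:
        val_curve.append((0, validation_epe(network, scheme, decoder, val_dataset,
                                            cfg.dt, cfg.grey_warmup)))
    for it in range(cfg.iterations):
        if len(order) < cfg.batch:  # new epoch
            order = rng.permutation(len(resampled))
            V0 = steady_state(network, scheme.connection_weights().data,
                              scheme.tau.data, scheme.v_rest.data,
                              duration=cfg.grey_warmup, dt=cfg.dt)
        take, order = order[: cfg.batch], order[cfg.batch :]
        frames_b = np.stack([resampled[i][0] for i in take])
        flow_b = np.stack([resampled[i][1] for i in take])  # (B, N, 2, C)

        act, vbar = _unroll(network, scheme, frames_b, V0, cfg.dt, dec_idx, central_idx)
        pred = decoder(act, train=True)  # (B*N, 2, C)
        B, N = frames_b.shape[0], frames_b.shape[1]
        target = Tensor(flow_b.reshape(B * N, 2, -1))
        task_loss = loss(target, pred)
        total = task_loss + activity_regularizer(vbar, cfg.regularizer)

        opt.zero_grad()
        total.backward()
        opt.lr = lr_at(it)
        opt.step()
        if rest_opt is not None:
            reg = activity_regularizer(vbar, cfg.regularizer)
            rest_opt.zero_grad()
            reg.backward()
            rest_opt.step()
        scheme.clamp(cfg.dt)
        loss_curve.append(float(task_loss.data))

        if val_dataset is not None and (it + 1) % cfg.val_every == 0:
            val_curve.append((it + 1, validation_epe(network, scheme, decoder,
                                                     val_dataset, cfg.dt, cfg.grey_warmup)))
    if val_dataset is not None and (not val_curve or val_curve[-1][0] != cfg.iterations):
        val_curve.append((cfg.iterations, validation_epe(network, scheme, decoder,
                                                         val_dataset, cfg.dt, cfg.grey_warmup)))
    return TrainResult(scheme=scheme, decoder=decoder, val_epe=val_curve,
                       train_loss=loss_curve)
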