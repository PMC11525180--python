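"""Network identifiability under sparse connectivity: the simulation study.

Question: when does knowing a network's wiring (its "connectome") suffice to
recover its function by task optimization alone?  The experiment:

1. Train feedforward ground-truth networks (six hidden rectified layers,
   Dale's law: one sign per presynaptic unit) on a 10-class digit task, and
   sparsify them to a target connectivity percentage by iterative
   magnitude pruning (lottery-ticket style: prune the smallest surviving
   magnitudes layer-locally, then retrain).
2. Simulate connectome measurement: copy the adjacency and signs; in the
   "with strength" regime also record noisy magnitudes
   m~ = m * eps, eps ~ U(1 - sigma, 1 + sigma).
3. Re-fit a simulated network with the measured quantities frozen and the
   rest (magnitudes, resting potentials) task-optimized; in the
   with-strength regime the magnitudes start at m~ and a squared-distance
   penalty to m~ (weighted 10x the task objective) keeps them close.
4. Score similarity as the median Pearson correlation of rectified voltages
   of corresponding sampled neurons over a stimulus set, pooled over layers
   (and, at study scale, network pairs).

The headline property is that similarity in the connectivity-only regime
falls as connectivity density rises, while strength measurements keep it
high at every density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .autodiff import Adam, Tensor

__all__ = [
    "NetConfig",
    "GroundTruthNet",
    "MeasuredConnectome",
    "SimilarityReport",
    "train_ground_truth",
    "measure_connectome",
    "fit_simulated",
    "similarity",
    "run_experiment",
]


@dataclass
class NetConfig:
    n_in: int = 784
    n_hidden: int = 128
    n_layers: int = 6        # hidden layers
    n_out: int = 10
    lr: float = 1e-3
    batch: int = 500
    epochs: int = 4
    lr_decay: float = 0.5    # per epoch
    prune_rate: float = 0.2  # fraction of surviving weights pruned per round
    prune_epochs: int = 1    # retraining per pruning round
    accuracy_floor: float = 0.9  # fraction of unpruned accuracy to preserve


class _DaleMLP:
    """Feedforward rectified net with Dale's-law sign structure.

    Layer l computes V = (sign_pre * c * m) @ f(V_prev) + v_rest with
    m >= 0, c a binary mask, and sign_pre one sign per presynaptic unit
    (columns).  The 10-way readout is never pruned.
    """

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        self.cfg = cfg
        dims = [cfg.n_in] + [cfg.n_hidden] * cfg.n_layers + [cfg.n_out]
        self.m = []       # non-negative magnitudes, Tensors
        self.b = []       # resting potentials, Tensors
        self.c = []       # binary masks, numpy
        self.sign = []    # per-presynaptic-unit signs, numpy (columns of layer l)
        for l in range(len(dims) - 1):
            fan_in = dims[l]
            sign = rng.choice([-1.0, 1.0], size=dims[l])
            m0 = np.abs(rng.normal(0, np.sqrt(2.0 / fan_in), size=(dims[l + 1], dims[l])))
            # balance excitation and inhibition per postsynaptic unit at init:
            # without this, every unit shares the common mode sum_j sign_j m x_j
            # and feature diversity collapses through depth
            pos = sign > 0
            for i in range(dims[l + 1]):
                sp, sn = m0[i, pos].sum(), m0[i, ~pos].sum()
                if sp > 0 and sn > 0:
                    m0[i, pos] *= (sp + sn) / (2 * sp)
                    m0[i, ~pos] *= (sp + sn) / (2 * sn)
            self.m.append(Tensor(m0, requires_grad=True))
            # slightly depolarized resting potentials keep rectifiers alive at init
            self.b.append(Tensor(np.full(dims[l + 1], 0.05), requires_grad=True))
            self.c.append(np.ones((dims[l + 1], dims[l])))
            self.sign.append(sign)

    def parameters(self):
        return self.m + self.b

    def weights(self, l: int) -> Tensor:
        return self.m[l] * (self.c[l] * self.sign[l][None, :])

    def voltages(self, x: np.ndarray) -> list[Tensor]:
        """Pre-activation voltages per layer (hidden layers then readout).

        Inputs are centred (x - 0.5): without this the large positive common
        mode of [0, 1] images, through the signed-column Dale structure, can
        silence whole layers at the rectifier (an absorbing state under the
        non-negativity clamp).
        """
        h = Tensor(np.asarray(x, dtype=float) - 0.5)
        out = []
        for l in range(len(self.m)):
            V = h @ self.weights(l).transpose(1, 0) + self.b[l]
            out.append(V)
            h = V.relu()
        return out

    def logits(self, x: np.ndarray) -> Tensor:
        return self.voltages(x)[-1]

    def clamp(self):
        for m in self.m:
            np.maximum(m.data, 0.0, out=m.data)

    def accuracy(self, x: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.logits(x).data.argmax(axis=1) == y))

    def connectivity(self) -> float:
        """Fraction of surviving prunable (non-readout) connections."""
        kept = sum(c.sum() for c in self.c[:-1])
        total = sum(c.size for c in self.c[:-1])
        return float(kept / total)


def _cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    m = logits.data.max(axis=1, keepdims=True)  # detached max for stability
    z = logits - m
    lse = z.exp().sum(axis=1).log()
    picked = z[np.arange(len(y)), y]
    return (lse - picked).mean()


def _train_epochs(net: _DaleMLP, x, y, epochs: int, rng, extra_loss=None,
                  lr0: float | None = None):
    cfg = net.cfg
    opt = Adam(net.parameters(), lr=lr0 or cfg.lr, amsgrad=True)
    n = len(y)
    for ep in range(epochs):
        opt.lr = (lr0 or cfg.lr) * cfg.lr_decay**ep
        order = rng.permutation(n)
        for s in range(0, n, cfg.batch):
            idx = order[s : s + cfg.batch]
            lossv = _cross_entropy(net.logits(x[idx]), y[idx])
            if extra_loss is not None:
                lossv = lossv + extra_loss(net)
            opt.zero_grad()
            lossv.backward()
            opt.step()
            net.clamp()


@dataclass
class GroundTruthNet:
    net: _DaleMLP
    accuracy: float
    dense_accuracy: float
    pruning_rounds: int


def train_ground_truth(x_train, y_train, x_test, y_test,
                       target_connectivity: float, seed: int = 0,
                       cfg: NetConfig | None = None) -> GroundTruthNet:
    """Train a Dale's-law net and prune it to the target connectivity (%).

    Iterative magnitude pruning, layer-local, `prune_rate` of surviving
    weights per round with retraining in between (fine-tuning from the
    pruned state); input and hidden weights are pruned, the readout never.
    If accuracy falls below `accuracy_floor` x dense accuracy the pruning
    still continues to the target, and the achieved accuracy is reported.
    """
    if not (0 < target_connectivity <= 100):
        raise ValueError("connectivity % must be in (0, 100]")
    cfg = cfg or NetConfig()
    rng = np.random.default_rng(seed)
    net = _DaleMLP(cfg, rng)
    _train_epochs(net, x_train, y_train, cfg.epochs, rng)
    dense_acc = net.accuracy(x_test, y_test)

    target = target_connectivity / 100.0
    rounds = 0
    while net.connectivity() > target + 1e-9:
        before = net.connectivity()
        # prune layer-locally: drop the smallest surviving magnitudes
        frac_next = max(before * (1 - cfg.prune_rate), target)
        for l in range(len(net.c) - 1):  # never the readout
            c, m = net.c[l], net.m[l].data
            alive = c > 0
            n_keep = int(np.floor(frac_next * c.size))
            if alive.sum() <= n_keep:
                continue
            mags = np.where(alive, m, -np.inf).ravel()
            keep_idx = np.argpartition(mags, -n_keep)[-n_keep:]
            newc = np.zeros(c.size)
            newc[keep_idx] = 1.0
            net.c[l] = newc.reshape(c.shape)
            net.m[l].data *= net.c[l]
        rounds += 1
        _train_epochs(net, x_train, y_train, cfg.prune_epochs, rng)
        if net.connectivity() >= before - 1e-12:
            break  # rounding floor reached; cannot prune further
    if rounds:
        # consolidate: retrain the final sparse skeleton to convergence so the
        # pruned net keeps (near-)dense task accuracy, as the pruning
        # procedure presumes
        _train_epochs(net, x_train, y_train, cfg.epochs, rng)
    acc = net.accuracy(x_test, y_test)
    return GroundTruthNet(net=net, accuracy=acc, dense_accuracy=dense_acc,
                          pruning_rounds=rounds)


@dataclass
class MeasuredConnectome:
    c: list[np.ndarray]
    sign: list[np.ndarray]
    m_noisy: list[np.ndarray] | None  # present only in the with-strength regime
    cfg: NetConfig


def measure_connectome(gt: GroundTruthNet, noise: float = 0.5,
                       regime: str = "connectivity_only",
                       seed: int = 0) -> MeasuredConnectome:
    """Simulate a connectome measurement of a ground-truth net.

    Copies adjacency and presynaptic signs; in the `with_strength` regime
    also records magnitudes corrupted by multiplicative uniform noise
    eps ~ U(1 - noise, 1 + noise).
    """
    if regime not in ("connectivity_only", "with_strength"):
        raise ValueError(f"unknown regime {regime!r}")
    if not 0 <= noise < 1:
        raise ValueError("noise must be in [0, 1)")
    rng = np.random.default_rng(seed)
    c = [a.copy() for a in gt.net.c]
    sign = [s.copy() for s in gt.net.sign]
    m_noisy = None
    if regime == "with_strength":
        m_noisy = [
            m.data * rng.uniform(1 - noise, 1 + noise, size=m.data.shape) * cmask
            for m, cmask in zip(gt.net.m, c)
        ]
    return MeasuredConnectome(c=c, sign=sign, m_noisy=m_noisy, cfg=gt.net.cfg)


def fit_simulated(measured: MeasuredConnectome, x_train, y_train,
                  seed: int = 0, penalty_weight: float = 10.0,
                  epochs: int | None = None, restarts: int = 3) -> _DaleMLP:
    """Re-fit a network under the measured constraints.

    Adjacency and signs are frozen.  `connectivity_only`: magnitudes start
    random and are task-optimized.  `with_strength`: magnitudes start at the
    noisy measurement and a squared-distance penalty to it (mean over
    existing connections, weighted `penalty_weight` x the task objective)
    is added.  Resting potentials are always initialized randomly and
    task-optimized.  Masked-out weights stay exactly zero.
    """
    cfg = measured.cfg
    rng = np.random.default_rng(seed)
    net = _DaleMLP(cfg, rng)
    net.c = [a.copy() for a in measured.c]
    net.sign = [s.copy() for s in measured.sign]
    for l, b in enumerate(net.b):
        b.data = rng.normal(0, 0.1, size=b.data.shape)
    extra = None
    if measured.m_noisy is not None:
        targets = [t.copy() for t in measured.m_noisy]
        for m, t in zip(net.m, targets):
            m.data = t.copy()
        n_conn = sum(c.sum() for c in net.c)

        def extra(n: _DaleMLP):
            acc = None
            for m, t, cmask in zip(n.m, targets, n.c):
                d = (m - t) * cmask
                term = (d * d).sum()
                acc = term if acc is None else acc + term
            return acc * (penalty_weight / n_conn)
    else:
        for m, cmask in zip(net.m, net.c):
            m.data *= cmask
    # warm restarts: the exponential lr decay is restarted a few times, which
    # sparse masks need to train to convergence from a random initialization
    for _ in range(max(restarts, 1)):
        _train_epochs(net, x_train, y_train, epochs or cfg.epochs, rng, extra_loss=extra)
    for m, cmask in zip(net.m, net.c):
        m.data *= cmask  # exact zeros on masked connections
    return net


def run_experiment(densities=(10.0, 40.0, 80.0), n_pairs: int = 3, seed: int = 0,
                   cfg: NetConfig | None = None, regimes=("connectivity_only", "with_strength"),
                   task_kwargs: dict | None = None) -> dict:
    """Run the full identifiability study at desk scale.

    For each connectivity density and ground-truth/simulation pair, trains a
    pruned ground-truth net, measures it in each regime, refits, and scores
    similarity.  Returns {regime: {density: {"per_pair": [...], "median": x}}}.
    """
    from .fixtures import make_digit_task

    cfg = cfg or NetConfig(batch=250, epochs=6, prune_epochs=1)
    xtr, ytr, xte, yte = make_digit_task(n_train=10000, n_test=1000, seed=seed,
                                         **(task_kwargs or {}))
    out: dict = {}
    for dens in densities:
        for pair in range(n_pairs):
            gt = train_ground_truth(xtr, ytr, xte, yte, dens, seed=seed + pair, cfg=cfg)
            for reg in regimes:
                meas = measure_connectome(gt, regime=reg, seed=seed + pair)
                sim = fit_simulated(meas, xtr, ytr, seed=1000 + seed + pair)
                rep = similarity(gt, sim, xte, seed=seed)
                out.setdefault(reg, {}).setdefault(dens, {}).setdefault("per_pair", []).append(rep.pooled)
    for reg in out:
        for dens in out[reg]:
            out[reg][dens]["median"] = float(np.median(out[reg][dens]["per_pair"]))
    return out


@dataclass
class SimilarityReport:
    per_layer: list[float]     # median correlation per hidden layer
    pooled: float              # median over all sampled neurons of all layers
    n_excluded: int            # constant-response neurons dropped
    n_per_layer: int = 100


def similarity(gt: GroundTruthNet | _DaleMLP, sim: _DaleMLP, stimuli: np.ndarray,
               n_per_layer: int = 100, seed: int = 0) -> SimilarityReport:
    """Median Pearson correlation of rectified voltages of matched neurons.

    For each hidden layer, `n_per_layer` neurons are sampled (all if fewer)
    and their rectified responses over the stimulus set correlated between
    ground truth and simulation; constant responders are excluded.
    """
    gt_net = gt.net if isinstance(gt, GroundTruthNet) else gt
    rng = np.random.default_rng(seed)
    v_gt = gt_net.voltages(stimuli)
    v_sim = sim.voltages(stimuli)
    n_hidden = len(gt_net.m) - 1
    per_layer, pooled, excluded = [], [], 0
    for l in range(n_hidden):
        a = np.maximum(v_gt[l].data, 0.0)
        b = np.maximum(v_sim[l].data, 0.0)
        n_units = a.shape[1]
        pick = rng.choice(n_units, size=min(n_per_layer, n_units), replace=False)
        rs = []
        for j in pick:
            if np.ptp(a[:, j]) == 0 or np.ptp(b[:, j]) == 0:
                excluded += 1
                continue
            r = float(stats.pearsonr(a[:, j], b[:, j]).statistic)
            if np.isnan(r):
                excluded += 1
                continue
            rs.append(r)
        per_layer.append(float(np.median(rs)) if rs else np.nan)
        pooled.extend(rs)
    return SimilarityReport(per_layer=per_layer,
                            pooled=float(np.median(pooled)) if pooled else np.nan,
                            n_excluded=excluded, n_per_layer=n_per_layer)
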