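"""Ensemble-level analysis: response clustering, task-error ranking and
maximally excitatory stimuli.

An ensemble is a set of models trained from different seeds under the same
connectome and task constraints.  Per cell type, each model contributes the
concatenated central-column responses to a shared naturalistic stimulus set
(normalized per model to remove the arbitrary voltage scale); the ensemble
is embedded to 2-D and clustered with Gaussian mixtures of 2-5 components,
the count chosen by the Bayesian information criterion.  The embedding is a
pluggable contract (any deterministic 2-D reduction); the default is UMAP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .autodiff import Adam, Tensor
from .task import epe

__all__ = [
    "ClusterReport",
    "cluster_models",
    "umap_embedding",
    "pca_embedding",
    "rank_by_task_error",
    "naturalistic_mes",
    "regularized_mes",
]


@dataclass
class ClusterReport:
    embedding: np.ndarray      # (n_models, 2)
    labels: np.ndarray         # (n_models,)
    k: int                     # chosen component count
    bic: dict                  # k -> BIC
    task_error_per_cluster: dict | None = None


def umap_embedding(X: np.ndarray, seed: int = 0) -> np.ndarray:
    """Default nonlinear 2-D reduction (UMAP), deterministic under seed."""
    import umap  # deferred: heavy import

    n_neighbors = int(np.clip(X.shape[0] - 1, 2, 15))
    return umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                     random_state=seed).fit_transform(X)


def pca_embedding(X: np.ndarray, seed: int = 0) -> np.ndarray:
    """Linear fallback embedding satisfying the same contract."""
    return PCA(n_components=2, random_state=seed).fit_transform(X)


def cluster_models(responses: np.ndarray, seed: int = 0, embedding=umap_embedding,
                   k_range=(2, 3, 4, 5), task_errors=None) -> ClusterReport:
    """Embed per-model response vectors to 2-D and mixture-cluster them.

    `responses` is (n_models, n_features), already normalized per model.
    Component counts exceeding the number of models are skipped; labels are
    returned up to permutation.
    """
    X = np.asarray(responses, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two models")
    emb = np.asarray(embedding(X, seed), dtype=float)
    # z-scored copy for mixture fitting: scale-free, and the covariance floor
    # keeps duplicate/degenerate points from producing likelihood spikes
    z = (emb - emb.mean(axis=0)) / np.where(emb.std(axis=0) > 0, emb.std(axis=0), 1.0)
    bics, fits = {}, {}
    for k in k_range:
        if k > X.shape[0]:
            continue
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             random_state=seed, n_init=3, reg_covar=1e-3)
        gm.fit(z)
        bics[k] = float(gm.bic(z))
        fits[k] = gm
    if not bics:
        raise ValueError("no feasible component count")
    k_best = min(bics, key=bics.get)
    labels = fits[k_best].predict(z)
    per_cluster = None
    if task_errors is not None:
        te = np.asarray(task_errors, dtype=float)
        per_cluster = {int(c): float(te[labels == c].mean()) for c in np.unique(labels)}
    return ClusterReport(embedding=emb, labels=labels, k=k_best, bic=bics,
                         task_error_per_cluster=per_cluster)


def rank_by_task_error(errors: dict) -> list:
    """Ascending-EPE ordering of model ids given {model_id: epe}."""
    return sorted(errors, key=lambda m: errors[m])


def naturalistic_mes(responses: list[np.ndarray]) -> tuple[int, float]:
    """Index and value of the dataset sequence maximizing the cell's response.

    `responses` holds the central cell's voltage trace per candidate
    sequence; the score of a sequence is the max over time.
    """
    if not responses:
        raise ValueError("empty dataset")
    scores = [float(np.max(r)) for r in responses]
    best = int(np.argmax(scores))
    return best, scores[best]


def regularized_mes(simulate_fn, x_star: np.ndarray, n_iter: int = 200,
                    lr: float = 0.02, grey: float = 0.5):
    """Distil a naturalistic maximally excitatory stimulus.

    Minimizes  sum_n ||V(X*)[n] - V(X')[n]||^2 + (1/C) sum ||X' - grey||^2
    by gradient descent on the stimulus X', preserving the central response
    while pushing columns outside the receptive field toward grey.
    `simulate_fn` maps a stimulus Tensor (N, C) to the central-cell voltage
    trace Tensor (N,), built from autodiff primitives.

    Returns (X', objective curve).  Accepted steps never increase the
    objective (simple backtracking on the learning rate).
    """
    x_star = np.asarray(x_star, dtype=float)
    C = x_star.shape[1]
    v_ref = simulate_fn(Tensor(x_star)).data.copy()

    x = Tensor(x_star.copy(), requires_grad=True)
    opt = Adam([x], lr=lr)

    def objective(xt: Tensor) -> Tensor:
        d = simulate_fn(xt) - v_ref
        reg = (xt - grey) * (xt - grey)
        return (d * d).sum() + reg.sum() * (1.0 / C)

    curve = [float(objective(Tensor(x.data)).data)]
    for _ in range(n_iter):
        obj = objective(x)
        opt.zero_grad()
        obj.backward()
        backup = x.data.copy()
        opt.step()
        np.clip(x.data, 0.0, 1.0, out=x.data)
        new = float(objective(Tensor(x.data)).data)
        if new > curve[-1]:
            x.data = backup  # reject step
            opt.lr *= 0.5
            curve.append(curve[-1])
        else:
            curve.append(new)
    return x.data, curve
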