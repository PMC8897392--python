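"""Selector-model training: vanilla NLL, co-teaching, and an SSL-linear head.

The cleaning framework only needs a classifier that exposes calibrated
posteriors ``p(y|x)``; the selectors consume those posteriors through the
scoring module.  Backends here are softmax-regression models on feature
vectors or precomputed embeddings, trained three ways:

* **vanilla** — plain negative log-likelihood minimisation on the (noisy)
  majority labels.
* **co-teaching** — two peers with different initialisations train
  simultaneously; at each step each peer updates only on the small-loss
  fraction of the batch selected by the *other* peer.  Samples with large
  early-training loss are the ones whose labels disagree with what the model
  has learned from the easy cases, so excluding them limits memorisation of
  noise, and the peer exchange avoids a self-confirmation loop.  The forget
  rate ramps linearly from 0 to the assumed noise rate over ``T_k`` steps.
* **SSL-linear** — a linear head on fixed embeddings, with logits squashed by
  ``gamma(x) = alpha * tanh(x / alpha)`` to penalise over-confident outputs
  and cross-entropy against label-smoothed targets.  The embedding is never
  updated.

Full-batch fits use L-BFGS; co-teaching uses plain SGD steps so the small-loss
exchange happens per batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_softmax, softmax

__all__ = [
    "SoftmaxClassifier",
    "CoTeachingConfig",
    "SSLLinearConfig",
    "train_vanilla",
    "coteaching_select",
    "forget_rate_schedule",
    "train_coteaching",
    "ensemble_posterior",
    "squash_logits",
    "train_ssl_linear",
    "finetune_on_corrected",
]


def squash_logits(z, alpha: float) -> np.ndarray:
    """Elementwise ``alpha * tanh(z / alpha)``; bounded in (-alpha, alpha).

    Odd and strictly increasing; near the origin it is the identity, so small
    logits pass through while large ones saturate, bounding the confidence a
    linear head can express.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    z = np.asarray(z, dtype=float)
    if not np.isfinite(alpha):
        return z.copy()
    return alpha * np.tanh(z / alpha)


def _smoothed_targets(y: np.ndarray, C: int, smoothing: float) -> np.ndarray:
    if not 0 <= smoothing < 1:
        raise ValueError("smoothing must be in [0, 1)")
    t = np.full((y.size, C), smoothing / (C - 1) if C > 1 else 0.0)
    t[np.arange(y.size), y] = 1.0 - smoothing
    return t


class SoftmaxClassifier:
    """Multinomial logistic model with optional logit squashing.

    Minimises ``sum_i CE(t_i, softmax(gamma(W^T x_i + b))) + l2/2 ||W||^2``
    where ``t_i`` are (optionally label-smoothed) targets and ``gamma`` is the
    tanh squash (identity when ``alpha`` is None/inf).  Deterministic given
    the seed.
    """

    def __init__(self, n_features: int, n_classes: int, alpha: float | None = None,
                 smoothing: float = 0.0, l2: float = 1.0, seed: int = 0) -> None:
        if n_classes < 2:
            raise ValueError("need at least two classes")
        if alpha is not None and alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 <= smoothing < 1:
            raise ValueError("smoothing must be in [0, 1)")
        self.n_features = n_features
        self.n_classes = n_classes
        self.alpha = alpha if alpha is None or np.isfinite(alpha) else None
        self.smoothing = smoothing
        self.l2 = l2
        self.fitted = False
        self.reinit(seed)

    def reinit(self, seed: int) -> None:
        """Re-initialise parameters from a fresh seed (for ensembles/peers)."""
        rng = np.random.default_rng(seed)
        self.W = 0.01 * rng.standard_normal((self.n_features, self.n_classes))
        self.b = np.zeros(self.n_classes)
        self.fitted = False

    # -- internals -------------------------------------------------------------

    def _forward(self, X: np.ndarray):
        z = X @ self.W + self.b
        if self.alpha is None:
            return z, np.ones_like(z)
        g = self.alpha * np.tanh(z / self.alpha)
        return g, 1.0 - (g / self.alpha) ** 2  # d gamma / d z

    def _loss_grad(self, X, targets, sample_weight):
        n = X.shape[0]
        g, dgdz = self._forward(X)
        p = softmax(g, axis=1)
        ce = -(targets * log_softmax(g, axis=1)).sum(axis=1)
        loss = float((sample_weight * ce).sum()) + 0.5 * self.l2 * float((self.W ** 2).sum())
        dz = (p - targets) * dgdz * sample_weight[:, None]
        gW = X.T @ dz + self.l2 * self.W
        gb = dz.sum(axis=0)
        return loss, gW, gb

    # -- public API ------------------------------------------------------------

    def fit(self, X, y, sample_weight=None, maxiter: int = 500) -> "SoftmaxClassifier":
        """Full-batch L-BFGS fit on integer labels ``y``."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("features must be N x d aligned with labels")
        if X.shape[1] != self.n_features:
            raise ValueError("feature dimension mismatch")
        targets = _smoothed_targets(y, self.n_classes, self.smoothing)
        w = np.ones(y.size) if sample_weight is None else np.asarray(sample_weight, float)

        shapeW = self.W.shape

        def pack(W, b):
            return np.concatenate([W.ravel(), b])

        def objective(theta):
            self.W = theta[: shapeW[0] * shapeW[1]].reshape(shapeW)
            self.b = theta[shapeW[0] * shapeW[1]:]
            loss, gW, gb = self._loss_grad(X, targets, w)
            return loss, pack(gW, gb)

        res = minimize(objective, pack(self.W, self.b), jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9})
        theta = res.x
        self.W = theta[: shapeW[0] * shapeW[1]].reshape(shapeW)
        self.b = theta[shapeW[0] * shapeW[1]:]
        self.fitted = True
        return self

    def sgd_step(self, X, y, lr: float = 0.5) -> None:
        """One gradient step on a mini-batch (mean loss)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        targets = _smoothed_targets(y, self.n_classes, self.smoothing)
        w = np.full(y.size, 1.0 / y.size)
        _, gW, gb = self._loss_grad(X, targets, w)
        # keep the l2 pull proportional to the batch share of the data
        self.W -= lr * (gW - self.l2 * self.W * (1 - 1.0 / max(1, y.size)))
        self.b -= lr * gb
        self.fitted = True

    def per_sample_loss(self, X, y) -> np.ndarray:
        """Cross-entropy of each sample's label under the current posteriors."""
        p = self.predict_posterior(X)
        y = np.asarray(y, dtype=np.int64)
        return -np.log(np.maximum(p[np.arange(y.size), y], 1e-300))

    def predict_posterior(self, X) -> np.ndarray:
        """Row-stochastic N x C posterior matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        g, _ = self._forward(X)
        return softmax(g, axis=1)


@dataclass
class CoTeachingConfig:
    """Co-teaching hyper-parameters.

    ``eta_hat`` is the assumed noise rate the forget rate ramps to over
    ``T_k`` steps; the seed pair gives the two peers different initialisations.
    """

    eta_hat: float
    T_k: int = 50
    steps: int = 300
    batch_size: int = 64
    lr: float = 0.5
    seeds: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if not 0 <= self.eta_hat < 1:
            raise ValueError("eta_hat must be in [0, 1)")
        if self.T_k < 1:
            raise ValueError("T_k must be >= 1")
        if self.seeds[0] == self.seeds[1]:
            raise ValueError("peers need distinct seeds")


@dataclass
class SSLLinearConfig:
    """Linear-head hyper-parameters: squash scale, smoothing mass, fit length."""

    alpha: float = 10.0
    smoothing: float = 0.1
    epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 <= self.smoothing < 1:
            raise ValueError("smoothing must be in [0, 1)")


def train_vanilla(backend: SoftmaxClassifier | None, features, labels,
                  seed: int = 0, jitter: float = 0.0, maxiter: int = 500) -> SoftmaxClassifier:
    """Fit a backend by NLL minimisation on the given (possibly noisy) labels.

    ``jitter`` optionally adds seeded Gaussian noise to the features before
    fitting, a vector-input stand-in for image augmentation.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    if backend is None:
        backend = SoftmaxClassifier(X.shape[1], int(y.max()) + 1, seed=seed)
    if jitter > 0:
        X = X + jitter * np.random.default_rng(seed).standard_normal(X.shape)
    return backend.fit(X, y, maxiter=maxiter)


def coteaching_select(peer_losses, forget_rate: float) -> np.ndarray:
    """Indices of the ``ceil((1-R) * batch)`` smallest peer losses.

    Ties resolve to the lower index (stable sort), so ``R=0`` keeps everything
    in order.
    """
    if not 0 <= forget_rate < 1:
        raise ValueError("forget rate must be in [0, 1)")
    losses = np.asarray(peer_losses, dtype=float)
    if not np.all(np.isfinite(losses)):
        raise ValueError("losses must be finite")
    keep = math.ceil((1.0 - forget_rate) * losses.size)
    order = np.argsort(losses, kind="stable")
    return np.sort(order[:keep])


def forget_rate_schedule(t: int, T_k: int, eta_hat: float) -> float:
    """Linear ramp: ``R(t) = eta_hat * min(t / T_k, 1)``."""
    if t < 0:
        raise ValueError("step must be non-negative")
    return eta_hat * min(t / T_k, 1.0)


def train_coteaching(backend1: SoftmaxClassifier, backend2: SoftmaxClassifier,
                     features, labels, config: CoTeachingConfig):
    """Train two peers with small-loss sample exchange.

    Each step, each peer updates only on the batch subset its *peer* marks as
    small-loss under the ramped forget rate.  With ``eta_hat = 0`` this
    degenerates to two independent SGD trainings on full batches.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    backend1.reinit(config.seeds[0])
    backend2.reinit(config.seeds[1])
    rng = np.random.default_rng(config.seeds[0] * 100003 + config.seeds[1])
    n = X.shape[0]
    for t in range(config.steps):
        idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
        Xb, yb = X[idx], y[idx]
        R = forget_rate_schedule(t, config.T_k, config.eta_hat)
        keep_for_2 = coteaching_select(backend1.per_sample_loss(Xb, yb), R)
        keep_for_1 = coteaching_select(backend2.per_sample_loss(Xb, yb), R)
        backend1.sgd_step(Xb[keep_for_1], yb[keep_for_1], lr=config.lr)
        backend2.sgd_step(Xb[keep_for_2], yb[keep_for_2], lr=config.lr)
    return backend1, backend2


def ensemble_posterior(pair, features) -> np.ndarray:
    """Arithmetic mean of the two peers' posteriors."""
    b1, b2 = pair
    if not (b1.fitted and b2.fitted):
        raise ValueError("both backends must be fitted")
    return 0.5 * (b1.predict_posterior(features) + b2.predict_posterior(features))


def train_ssl_linear(embeddings, labels, config: SSLLinearConfig) -> SoftmaxClassifier:
    """Fit a linear head on fixed embeddings with squashed logits.

    Cross-entropy against smoothed targets ``(1 - eps)`` on the label and
    ``eps / (C - 1)`` elsewhere; the squash bounds the maximum expressible
    class probability at ``softmax(alpha, -alpha, ...)``.
    """
    X = np.asarray(embeddings, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    head = SoftmaxClassifier(X.shape[1], int(y.max()) + 1, alpha=config.alpha,
                             smoothing=config.smoothing, seed=config.seed)
    return head.fit(X, y, maxiter=config.epochs)


def finetune_on_corrected(backend: SoftmaxClassifier, dataset, epochs: int = 100):
    """Continue fitting on the dataset's current majority labels.

    Samples with an undecided (tied) majority are skipped; zero epochs leaves
    the backend untouched.  Used by the simulation's periodic model-update
    hook so the selector benefits from labels corrected so far.
    """
    if not backend.fitted:
        raise ValueError("backend must be fitted before fine-tuning")
    if epochs == 0:
        return backend
    if dataset.features is None:
        raise ValueError("dataset has no features to fine-tune on")
    majorities = dataset.majority_labels()
    decided = majorities >= 0
    return backend.fit(dataset.features[decided], majorities[decided], maxiter=epochs)
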