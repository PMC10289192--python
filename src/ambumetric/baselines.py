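"""Comparison methods: a plain feed-forward regressor and SMIDA.

Baseline 1 is a dense feed-forward network with the same layer count,
width, regularization, and early-stopping protocol as the metric model,
trained directly on (features -> label) squared error — parameter parity
is automatic because it reuses the same stack shape.

Baseline 2 is semi-supervised maximum independence domain adaptation with
participant-as-domain: a linear projection that maximizes projected
variance plus dependence on the available labels while penalizing
dependence (HSIC, linear kernels) on participant indicators; an ordinary
least-squares head regresses the construct from the projected space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .metric_model import EarlyStopping, ModelConfig, SiameseModel, \
    TrainedModel, build_model

__all__ = ["SmidaConfig", "SmidaProjection", "train_fnn_baseline", "hsic",
           "fit_smida", "smida_predict"]


# -- Baseline 1: feed-forward regressor ----------------------------------

def _mse_step(model: SiameseModel, X, y, rng) -> float:
    cfg = model.cfg
    B = len(X)
    E, cache = model.forward_shared(X, train=True, rng=rng)
    pred = model.predict_head(E)
    loss = float(((pred - y) ** 2).mean())
    gp = (2.0 * (pred - y) / B)[:, None]
    g_head_w = E.T @ gp
    g_head_b = gp.sum()
    gE = gp @ model.head_w.T
    grads = model.backprop_shared(cache, gE)
    lr = cfg.learning_rate
    for i, (dW, db) in enumerate(grads):
        model.weights[i] -= lr * (dW + 2 * cfg.l2_penalty * model.weights[i])
        model.biases[i] -= lr * db
    model.head_w -= lr * (g_head_w + 2 * cfg.l2_penalty * model.head_w)
    model.head_b -= lr * g_head_b
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite FNN training loss")
    return loss


def train_fnn_baseline(train_X: np.ndarray, train_y: np.ndarray,
                       val_X: np.ndarray, val_y: np.ndarray,
                       cfg: ModelConfig) -> TrainedModel:
    """Dense regressor under the metric model's training protocol."""
    train_X = np.asarray(train_X, float)
    train_y = np.asarray(train_y, float)
    if len(train_X) == 0 or len(val_X) == 0:
        raise ValueError("empty training or validation data")
    model = build_model(cfg, input_dim=train_X.shape[1])
    rng = np.random.default_rng(cfg.seed)
    history: list[float] = []
    stopper = EarlyStopping(cfg.patience)
    best_state = model.get_state()
    n = len(train_X)
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            _mse_step(model, train_X[sel], train_y[sel], rng)
        pred = model.predict_head(model.forward_shared(val_X))
        if np.std(pred) == 0 or np.std(val_y) == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(pred, np.asarray(val_y, float))[0, 1])
        history.append(r)
        stop = stopper.update(r)
        if stopper.best_epoch == stopper.epoch:
            best_state = model.get_state()
        if stop:
            break
    model.set_state(best_state)
    return TrainedModel(model=model, config=cfg, history=history,
                        best_epoch=stopper.best_epoch)


# -- Baseline 2: SMIDA ----------------------------------------------------

@dataclass(frozen=True)
class SmidaConfig:
    kernel: str = "linear"
    subspace_dim: int = 30
    independence_weight: float = 1.0   # mu: domain HSIC penalty
    label_dependence_weight: float = 1.0  # gamma: label HSIC reward
    variance_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        for name in ("subspace_dim",):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("independence_weight", "label_dependence_weight",
                     "variance_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SmidaProjection:
    components: np.ndarray   # (n_features, subspace_dim), orthonormal
    eigenvalues: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.components


def hsic(X: np.ndarray, Y: np.ndarray) -> float:
    """Empirical HSIC with linear kernels: tr(Kx H Ky H) / (n-1)^2."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have equal sample counts")
    if n < 2:
        raise ValueError("HSIC needs at least two samples")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    cross = Xc.T @ Yc
    return float((cross ** 2).sum() / (n - 1) ** 2)


def _one_hot(domains: np.ndarray) -> np.ndarray:
    _, inv = np.unique(np.asarray(domains), return_inverse=True)
    D = np.zeros((len(inv), inv.max() + 1))
    D[np.arange(len(inv)), inv] = 1.0
    return D


def fit_smida(X: np.ndarray, domains: np.ndarray,
              labels_masked: np.ndarray,
              cfg: SmidaConfig) -> SmidaProjection:
    """Learn the maximum-independence projection.

    ``X`` holds all samples (train and test features together);
    ``labels_masked`` carries NaN for held-out samples, which contribute
    nothing to the label-dependence term. Solved as a symmetric
    eigenproblem; deterministic up to component sign.
    """
    X = np.asarray(X, float)
    n, d = X.shape
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    y = np.asarray(labels_masked, float).copy()
    observed = ~np.isnan(y)
    y[~observed] = y[observed].mean() if observed.any() else 0.0
    yc = (y - y.mean())[:, None]
    D = _one_hot(domains)

    XH = H @ X
    M = cfg.variance_weight * (XH.T @ XH)
    if cfg.label_dependence_weight > 0:
        Xy = XH.T @ yc
        M += cfg.label_dependence_weight * (Xy @ Xy.T)
    if cfg.independence_weight > 0:
        XD = XH.T @ (H @ D)
        M -= cfg.independence_weight * (XD @ XD.T)
    M = 0.5 * (M + M.T)
    try:
        eigvals, eigvecs = np.linalg.eigh(M)
    except np.linalg.LinAlgError:
        warnings.warn("eigendecomposition failed; regularizing",
                      stacklevel=2)
        eigvals, eigvecs = np.linalg.eigh(M + 1e-8 * np.eye(d))
    order = np.argsort(eigvals)[::-1]
    k = min(cfg.subspace_dim, d)
    return SmidaProjection(components=eigvecs[:, order[:k]],
                           eigenvalues=eigvals[order[:k]])


def smida_predict(projection: SmidaProjection,
                  train_X: np.ndarray, train_y: np.ndarray,
                  test_X: np.ndarray) -> np.ndarray:
    """OLS on projected training samples, applied to projected test."""
    Zt = projection.transform(train_X)
    Zs = projection.transform(test_X)
    A = np.column_stack([Zt, np.ones(len(Zt))])
    coef, _, rank, _ = np.linalg.lstsq(A, np.asarray(train_y, float),
                                       rcond=None)
    if rank < A.shape[1]:
        warnings.warn("singular projected design; minimum-norm solution",
                      stacklevel=2)
    return np.column_stack([Zs, np.ones(len(Zs))]) @ coef
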