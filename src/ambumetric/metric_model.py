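"""Siamese metric-learning regressor.

Two identical branches share a dense embedding stack ``f_W`` (3-5 layers,
64 units each, ReLU, dropout between layers, per-layer L2 penalty); a
single-node linear head ``g_V`` maps the embedding to the construct value.
Training minimizes, per pair, the feature loss

    w * | ||f_W(x_a) - f_W(x_b)||_2  -  |yhat_a - yhat_b| |

plus ``loss_mix`` times the squared regression error of both branch
outputs against the raw labels, by mini-batch SGD. Early stopping watches
the validation Pearson correlation with a configurable patience and
restores the best-epoch weights.

The implementation is plain numpy with hand-written gradients: the model
is tiny (about 13k parameters) and this keeps the artifact dependency-free
of any deep-learning framework.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .pairing import PairSet
from .schema_io import ID_COL, Dataset

__all__ = ["ModelConfig", "SiameseModel", "TrainedModel", "feature_loss",
           "regression_loss", "build_model", "train", "fine_tune_split",
           "predict", "embed", "count_parameters"]

_EPS = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    n_shared_layers: int = 3
    layer_width: int = 64
    dropout: float = 0.1
    l2_penalty: float = 0.0001
    patience: int = 5
    batch_size: int = 128
    loss_mix: float = 1.0          # weight of the regression loss term
    learning_rate: float = 0.01
    max_epochs: int = 200
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_shared_layers not in (3, 4, 5):
            raise ValueError("n_shared_layers must be one of {3, 4, 5}")
        if self.layer_width < 1:
            raise ValueError("layer_width must be positive")
        # the tuned search range is [0.1, 0.3]; 0 disables dropout
        if not 0.0 <= self.dropout <= 0.3:
            raise ValueError("dropout must lie in [0, 0.3]")
        if self.patience not in (3, 5, 10):
            raise ValueError("patience must be one of {3, 5, 10}")
        if self.batch_size not in (128, 256, 512):
            raise ValueError("batch_size must be one of {128, 256, 512}")
        if self.loss_mix < 0 or self.learning_rate <= 0:
            raise ValueError("loss_mix must be >= 0, learning_rate > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


# -- losses (also the reference forms used by the batched trainer) --------

def feature_loss(emb_a: np.ndarray, emb_b: np.ndarray,
                 yhat_a: float | np.ndarray, yhat_b: float | np.ndarray,
                 weight: float | np.ndarray = 1.0) -> np.ndarray:
    """Pairwise metric loss: | embedding distance - label distance |."""
    emb_a = np.atleast_2d(np.asarray(emb_a, float))
    emb_b = np.atleast_2d(np.asarray(emb_b, float))
    if emb_a.shape != emb_b.shape:
        raise ValueError("embedding dimension mismatch")
    dist = np.linalg.norm(emb_a - emb_b, axis=-1)
    label_dist = np.abs(np.asarray(yhat_a, float)
                        - np.asarray(yhat_b, float))
    out = np.asarray(weight, float) * np.abs(dist - label_dist)
    return out if out.shape else float(out)


def regression_loss(pred: float | np.ndarray, y: float | np.ndarray,
                    weight: float | np.ndarray = 1.0) -> np.ndarray:
    """Weighted squared error of a single branch output."""
    out = (np.asarray(weight, float)
           * (np.asarray(pred, float) - np.asarray(y, float)) ** 2)
    return out if out.shape else float(out)


# -- model ----------------------------------------------------------------

class SiameseModel:
    """Shared dense stack plus a one-node linear regression head."""

    def __init__(self, cfg: ModelConfig, input_dim: int,
                 rng: np.random.Generator):
        if input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        self.cfg = cfg
        self.input_dim = input_dim
        widths = [input_dim] + [cfg.layer_width] * cfg.n_shared_layers
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            std = math.sqrt(2.0 / fan_in)  # He init for ReLU layers
            self.weights.append(rng.normal(0.0, std, (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.head_w = rng.normal(0.0, math.sqrt(1.0 / cfg.layer_width),
                                 (cfg.layer_width, 1))
        self.head_b = np.zeros(1)

    # forward -------------------------------------------------------------

    def forward_shared(self, X: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None):
        """Embed; in training mode returns the backprop cache too."""
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} input features, got "
                f"{X.shape[1]}")
        cache = []
        A = X
        n_layers = len(self.weights)
        p = self.cfg.dropout
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            Z = A @ W + b
            H = np.maximum(Z, 0.0)
            mask = None
            if train and p > 0 and i < n_layers - 1:  # dropout between layers
                mask = (rng.random(H.shape) >= p) / (1.0 - p)
                H = H * mask
            cache.append((A, Z, mask))
            A = H
        return (A, cache) if train else A

    def predict_head(self, emb: np.ndarray) -> np.ndarray:
        return (emb @ self.head_w + self.head_b).ravel()

    # parameter bookkeeping ------------------------------------------------

    def get_state(self):
        return copy.deepcopy((self.weights, self.biases,
                              self.head_w, self.head_b))

    def set_state(self, state) -> None:
        self.weights, self.biases, self.head_w, self.head_b = \
            copy.deepcopy(state)

    def backprop_shared(self, cache, grad_out: np.ndarray):
        """Gradient of the shared stack; returns per-layer (dW, db)."""
        grads = []
        g = grad_out
        for layer in range(len(cache) - 1, -1, -1):
            A, Z, mask = cache[layer]
            if mask is not None:
                g = g * mask
            g = g * (Z > 0)
            grads.append((A.T @ g, g.sum(axis=0)))
            g = g @ self.weights[layer].T
        grads.reverse()
        return grads


def count_parameters(model: SiameseModel) -> int:
    n = sum(W.size + b.size for W, b in zip(model.weights, model.biases))
    return n + model.head_w.size + model.head_b.size


def build_model(cfg: ModelConfig, input_dim: int) -> SiameseModel:
    rng = np.random.default_rng(cfg.seed)
    return SiameseModel(cfg, input_dim, rng)


@dataclass
class TrainedModel:
    model: SiameseModel
    config: ModelConfig
    history: list[float] = field(default_factory=list)  # val Pearson / epoch
    best_epoch: int = 0
    feature_columns: Optional[list[str]] = None

    @property
    def best_val_pearson(self) -> float:
        finite = [h for h in self.history if np.isfinite(h)]
        return max(finite) if finite else float("nan")


class EarlyStopping:
    """Patience-based stop on the validation Pearson correlation.

    ``update(r)`` records one epoch's score and returns True when training
    should stop; non-finite scores never count as improvements.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = 0
        self.epoch = 0
        self.wait = 0

    def update(self, r: float) -> bool:
        self.epoch += 1
        if np.isfinite(r) and r > self.best:
            self.best = r
            self.best_epoch = self.epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _sgd_step(model: SiameseModel, Xa, Xb, ya, yb, yha, yhb, w,
              rng: np.random.Generator) -> float:
    """One Siamese mini-batch update; returns the batch loss."""
    cfg = model.cfg
    B = len(Xa)
    Ea, cache_a = model.forward_shared(Xa, train=True, rng=rng)
    Eb, cache_b = model.forward_shared(Xb, train=True, rng=rng)
    pa = model.predict_head(Ea)
    pb = model.predict_head(Eb)

    diff = Ea - Eb
    dist = np.sqrt((diff ** 2).sum(axis=1) + _EPS)
    label_dist = np.abs(yha - yhb)
    lf = w * np.abs(dist - label_dist)
    lr_term = w * ((pa - ya) ** 2 + (pb - yb) ** 2)
    loss = (lf.sum() + cfg.loss_mix * lr_term.sum()) / B

    # feature-loss gradient on the embeddings
    sgn = np.sign(dist - label_dist)
    gdist = (w * sgn / (dist + _EPS) / B)[:, None]
    gEa = gdist * diff
    gEb = -gEa
    # regression-loss gradient (both branches)
    gpa = (cfg.loss_mix * w * 2.0 * (pa - ya) / B)[:, None]
    gpb = (cfg.loss_mix * w * 2.0 * (pb - yb) / B)[:, None]
    g_head_w = Ea.T @ gpa + Eb.T @ gpb
    g_head_b = gpa.sum() + gpb.sum()
    gEa = gEa + gpa @ model.head_w.T
    gEb = gEb + gpb @ model.head_w.T

    grads_a = model.backprop_shared(cache_a, gEa)
    grads_b = model.backprop_shared(cache_b, gEb)

    lr = cfg.learning_rate
    for i, ((dWa, dba), (dWb, dbb)) in enumerate(zip(grads_a, grads_b)):
        dW = dWa + dWb + 2.0 * cfg.l2_penalty * model.weights[i]
        model.weights[i] -= lr * dW
        model.biases[i] -= lr * (dba + dbb)
    model.head_w -= lr * (g_head_w + 2.0 * cfg.l2_penalty * model.head_w)
    model.head_b -= lr * g_head_b
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite training loss ({loss}); lower the learning rate")
    return float(loss)


def train(model: SiameseModel, pairs: PairSet,
          val_X: np.ndarray, val_y: np.ndarray,
          cfg: ModelConfig | None = None) -> TrainedModel:
    """Joint metric + regression training with Pearson early stopping."""
    cfg = cfg or model.cfg
    if len(pairs) == 0:
        raise ValueError("empty training pair set")
    val_X = np.asarray(val_X, float)
    val_y = np.asarray(val_y, float)
    if len(val_X) == 0:
        raise ValueError("empty validation set")
    rng = np.random.default_rng(cfg.seed)

    history: list[float] = []
    stopper = EarlyStopping(cfg.patience)
    best_state = model.get_state()
    n = len(pairs)
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            ia, ib = pairs.idx_a[sel], pairs.idx_b[sel]
            _sgd_step(model, pairs.X[ia], pairs.X[ib],
                      pairs.y[ia], pairs.y[ib],
                      pairs.yhat[ia], pairs.yhat[ib],
                      pairs.weights[sel], rng)
        val_pred = model.predict_head(model.forward_shared(val_X))
        r = _pearson(val_pred, val_y)
        history.append(r)
        stop = stopper.update(r)
        if stopper.best_epoch == stopper.epoch:
            best_state = model.get_state()
        if stop:
            break
    model.set_state(best_state)
    return TrainedModel(model=model, config=cfg, history=history,
                        best_epoch=stopper.best_epoch)


def fine_tune_split(test_data: Dataset, fraction: float,
                    seed: int = 0) -> tuple[Dataset, Dataset]:
    """Move floor(fraction * m) of each target participant's samples into a
    fine-tuning set; the remainder is the reduced test set."""
    if not 0.0 <= fraction <= 0.9:
        raise ValueError("fine-tuning fraction must lie in [0, 0.9]")
    rng = np.random.default_rng(seed)
    frame = test_data.frame
    take_idx = []
    for _, grp in frame.groupby(ID_COL, sort=False):
        m = len(grp)
        k = int(math.floor(fraction * m))
        if k > 0:
            take_idx.extend(rng.choice(grp.index.to_numpy(), size=k,
                                       replace=False))
    take = frame.index.isin(take_idx)
    fine_tune = test_data.replace_frame(
        frame[take].reset_index(drop=True))
    reduced = test_data.replace_frame(
        frame[~take].reset_index(drop=True))
    return fine_tune, reduced


def save_trained(trained: TrainedModel, path) -> None:
    """Persist a trained model (weights + config + history) as JSON."""
    import json
    from dataclasses import asdict
    from pathlib import Path
    m = trained.model
    payload = {
        "config": asdict(trained.config),
        "input_dim": m.input_dim,
        "history": trained.history,
        "best_epoch": trained.best_epoch,
        "feature_columns": trained.feature_columns,
        "weights": [w.tolist() for w in m.weights],
        "biases": [b.tolist() for b in m.biases],
        "head_w": m.head_w.tolist(),
        "head_b": m.head_b.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_trained(path) -> TrainedModel:
    import json
    from pathlib import Path
    payload = json.loads(Path(path).read_text())
    cfg = ModelConfig(**payload["config"])
    model = build_model(cfg, input_dim=payload["input_dim"])
    model.weights = [np.asarray(w, float) for w in payload["weights"]]
    model.biases = [np.asarray(b, float) for b in payload["biases"]]
    model.head_w = np.asarray(payload["head_w"], float)
    model.head_b = np.asarray(payload["head_b"], float)
    return TrainedModel(model=model, config=cfg,
                        history=payload["history"],
                        best_epoch=payload["best_epoch"],
                        feature_columns=payload["feature_columns"])


def predict(trained: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Single-branch inference: g_V(f_W(x)), dropout off."""
    emb = trained.model.forward_shared(np.asarray(X, float))
    return trained.model.predict_head(emb)


def embed(trained: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Embedding-space representation f_W(x)."""
    return trained.model.forward_shared(np.asarray(X, float))
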