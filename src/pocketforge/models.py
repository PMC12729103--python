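"""Pocket scorers: logistic regression, feedforward NN, and CNN.

Each scorer maps an N×D pocket feature matrix to a probability in [0, 1]
that the candidate is a real binding pocket.  Logistic regression (trained
to convergence or 500 iterations) serves as the linear baseline; the
feedforward network flattens the matrix to an N·D vector; the CNN treats
it as a one-channel 2-D input.  Networks train for a fixed number of
epochs under binary cross-entropy with minibatch SGD/Adam/AdamW and
dropout; the returned parameters are those of the epoch with the best
validation AUROC.  Training is fully deterministic per seed.

The decision threshold t is chosen on validation scores by maximizing
TPR − FPR (Youden's J), ties resolved toward the smallest threshold.

The gradient code here is a deliberately small, dependency-free backend:
explicit forward/backward passes over dense, convolution and max-pool
layers, sufficient for the modest model sizes this task needs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .errors import ParameterError, TrainingError
from .features import FeatureMatrix


@dataclass
class HyperParams:
    model_kind: str  # lr | nn | cnn
    learning_rate: float = 0.001
    dropout: float = 0.5
    batch_size: int = 32
    optimizer: str = "adamw"  # adam | adamw | sgd
    n_dense_layers: int = 1
    hidden_width: int = 256
    # lr only
    penalty: str = "none"  # none | l1 | l2 | elasticnet
    reg_weight: float = 1.0
    # cnn only
    filter_size: int = 3
    pool_size: int = 2
    n_conv_layers: int = 1
    n_filters: int = 8

    def __post_init__(self) -> None:
        if self.model_kind not in ("lr", "nn", "cnn"):
            raise ParameterError(f"unknown model kind {self.model_kind!r}")
        if self.optimizer not in ("adam", "adamw", "sgd"):
            raise ParameterError(f"unknown optimizer {self.optimizer!r}")
        if self.penalty not in ("none", "l1", "l2", "elasticnet"):
            raise ParameterError(f"unknown penalty {self.penalty!r}")


#: published final NN configurations (embedding-only and combined features)
PRESET_NN_B = HyperParams(
    model_kind="nn", n_dense_layers=1, batch_size=32, dropout=0.5,
    learning_rate=0.001, optimizer="adamw",
)
PRESET_NN_C = HyperParams(
    model_kind="nn", n_dense_layers=1, batch_size=64, dropout=0.4,
    learning_rate=0.01, optimizer="adam",
)


@dataclass
class TrainingHistory:
    train_auroc: list[float] = field(default_factory=list)
    val_auroc: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    seed: int = 0

    @property
    def epochs(self) -> int:
        return len(self.val_auroc)


@dataclass
class TrainedScorer:
    model_kind: str
    hyperparams: HyperParams
    params: dict  # name -> ndarray
    feature_set: str
    n_rows: int
    n_features: int
    method_order: list[str] = field(default_factory=list)
    threshold_t: Optional[float] = None
    training_seed: int = 0


# -- tiny layer backend -----------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gw = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.w.T

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def params(self):
        return []


class _Dropout:
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self.training = True

    def forward(self, x):
        if not self.training or self.p == 0:
            return x
        self._mask = self.rng.random(x.shape) >= self.p
        return x * self._mask / (1.0 - self.p)

    def backward(self, g):
        if not self.training or self.p == 0:
            return g
        return g * self._mask / (1.0 - self.p)

    def params(self):
        return []


class _Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)

    def params(self):
        return []


class _Conv2D:
    """Valid-padding stride-1 convolution over (batch, C, H, W) via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (c_in * k * k + c_out))
        self.w = rng.uniform(-limit, limit, size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.k = k

    def _im2col(self, x):
        b, c, h, w = x.shape
        k = self.k
        oh, ow = h - k + 1, w - k + 1
        cols = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        # (b, c, oh, ow, k, k) -> (b, oh, ow, c*k*k)
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh, ow, c * k * k)
        return cols, oh, ow

    def forward(self, x):
        self._x = x
        cols, oh, ow = self._im2col(x)
        self._cols = cols
        wmat = self.w.reshape(self.w.shape[0], -1)  # (c_out, c*k*k)
        out = cols @ wmat.T + self.b  # (b, oh, ow, c_out)
        return out.transpose(0, 3, 1, 2)

    def backward(self, g):
        b, c_out, oh, ow = g.shape
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, c_out)  # (b*oh*ow, c_out)
        cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.gw = (gmat.T @ cols).reshape(self.w.shape)
        self.gb = gmat.sum(axis=0)
        wmat = self.w.reshape(c_out, -1)
        gcols = (gmat @ wmat).reshape(b, oh, ow, -1)
        # scatter-add column gradients back onto the input
        k = self.k
        _, c, h, w = self._x.shape
        gx = np.zeros_like(self._x)
        gcols = gcols.reshape(b, oh, ow, c, k, k)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di : di + oh, dj : dj + ow] += gcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return gx

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]


class _MaxPool2D:
    def __init__(self, p: int):
        self.p = p

    def forward(self, x):
        b, c, h, w = x.shape
        p = self.p
        oh, ow = h // p, w // p
        if oh == 0 or ow == 0:
            raise TrainingError(f"pool size {p} too large for input {h}x{w}")
        xt = x[:, :, : oh * p, : ow * p].reshape(b, c, oh, p, ow, p)
        self._xt_shape = xt.shape
        self._x_shape = x.shape
        flat = xt.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, oh, ow, p * p)
        self._argmax = flat.argmax(axis=-1)
        self._flat_shape = flat.shape
        return flat.max(axis=-1)

    def backward(self, g):
        b, c, oh, ow, pp = self._flat_shape
        gflat = np.zeros(self._flat_shape)
        idx = np.indices((b, c, oh, ow))
        gflat[idx[0], idx[1], idx[2], idx[3], self._argmax] = g
        p = self.p
        gx = np.zeros(self._x_shape)
        gxt = gflat.reshape(b, c, oh, ow, p, p).transpose(0, 1, 2, 4, 3, 5)
        gx[:, :, : oh * p, : ow * p] = gxt.reshape(b, c, oh * p, ow * p)
        return gx

    def params(self):
        return []


class _Network:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, training: bool) -> np.ndarray:
        for layer in self.layers:
            if isinstance(layer, _Dropout):
                layer.training = training
            x = layer.forward(x)
        return x.reshape(-1)  # logits

    def backward(self, gout: np.ndarray) -> None:
        g = gout.reshape(-1, 1) if self.layers and isinstance(
            self.layers[-1], _Dense
        ) else gout
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def param_triples(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, value, grad in layer.params():
                out.append((f"layer{i}.{name}", value, grad))
        return out

    def get_state(self) -> dict:
        return {name: value.copy() for name, value, _ in self.param_triples()}

    def set_state(self, state: dict) -> None:
        for name, value, _ in self.param_triples():
            value[...] = state[name]


class _Optimizer:
    def __init__(self, kind: str, lr: float, weight_decay: float = 0.01):
        self.kind = kind
        self.lr = lr
        self.wd = weight_decay
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, triples) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for name, value, grad in triples:
            if self.kind == "sgd":
                value -= self.lr * grad
                continue
            if name not in self.m:
                self.m[name] = np.zeros_like(value)
                self.v[name] = np.zeros_like(value)
            self.m[name] = b1 * self.m[name] + (1 - b1) * grad
            self.v[name] = b2 * self.v[name] + (1 - b2) * grad**2
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            if self.kind == "adamw" and not name.endswith(".b"):
                value -= self.lr * self.wd * value
            value -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _build_network(hp: HyperParams, n_rows: int, n_features: int, rng) -> _Network:
    layers: list = []
    if hp.model_kind == "cnn":
        h, w = n_rows, n_features
        c = 1
        for _ in range(hp.n_conv_layers):
            layers.append(_Conv2D(c, hp.n_filters, hp.filter_size, rng))
            layers.append(_ReLU())
            layers.append(_MaxPool2D(hp.pool_size))
            c = hp.n_filters
            h = (h - hp.filter_size + 1) // hp.pool_size
            w = (w - hp.filter_size + 1) // hp.pool_size
            if h < 1 or w < 1:
                raise TrainingError("conv/pool stack collapses the input")
        layers.append(_Flatten())
        dim = c * h * w
    else:
        layers.append(_Flatten())
        dim = n_rows * n_features
    for _ in range(hp.n_dense_layers):
        layers.append(_Dense(dim, hp.hidden_width, rng))
        layers.append(_ReLU())
        layers.append(_Dropout(hp.dropout, rng))
        dim = hp.hidden_width
    layers.append(_Dense(dim, 1, rng))
    return _Network(layers)


# -- training ---------------------------------------------------------------


def _stack(matrices: Sequence[FeatureMatrix]):
    x = np.stack([m.values for m in matrices])
    labels = [m.label for m in matrices]
    if any(l is None for l in labels):
        raise TrainingError("all matrices must carry labels for training")
    y = np.array(labels, dtype=float)
    return x, y


def _check_shapes(train, val):
    shapes = {m.values.shape for m in train} | {m.values.shape for m in val}
    fsets = {m.feature_set for m in train} | {m.feature_set for m in val}
    if len(shapes) != 1:
        raise TrainingError(f"inconsistent matrix shapes: {shapes}")
    if len(fsets) != 1:
        raise TrainingError(f"inconsistent feature sets: {fsets}")
    return shapes.pop(), fsets.pop()


def _network_scores(net: _Network, x: np.ndarray, hp: HyperParams,
                    batch: int = 1024) -> np.ndarray:
    out = []
    for i in range(0, len(x), batch):
        xb = x[i : i + batch]
        if hp.model_kind == "cnn":
            xb = xb[:, None, :, :]
        out.append(_sigmoid(net.forward(xb, training=False)))
    return np.concatenate(out)


def train_scorer(
    train_matrices: Sequence[FeatureMatrix],
    val_matrices: Sequence[FeatureMatrix],
    hyperparams: HyperParams,
    epochs: int = 50,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[TrainedScorer, TrainingHistory]:
    """Train one scorer; return the best-validation-AUROC parameters.

    Logistic regression ignores `epochs` and trains to convergence or
    `max_iter` iterations.  Networks train `epochs` epochs of minibatch
    gradient descent on binary cross-entropy.
    """
    if not train_matrices or not val_matrices:
        raise TrainingError("train and validation sets must be non-empty")
    (n_rows, n_features), feature_set = _check_shapes(train_matrices, val_matrices)
    xtr, ytr = _stack(train_matrices)
    xva, yva = _stack(val_matrices)
    hp = hyperparams

    if hp.model_kind == "lr":
        flat_tr = xtr.reshape(len(xtr), -1)
        kwargs: dict = {"max_iter": max_iter, "random_state": seed}
        if hp.penalty == "none":
            kwargs["penalty"] = None
        elif hp.penalty == "elasticnet":
            kwargs.update(penalty="elasticnet", solver="saga", l1_ratio=0.5,
                          C=1.0 / hp.reg_weight)
        elif hp.penalty == "l1":
            kwargs.update(penalty="l1", solver="saga", C=1.0 / hp.reg_weight)
        else:
            kwargs.update(penalty="l2", C=1.0 / hp.reg_weight)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings expected at 500
            clf = LogisticRegression(**kwargs).fit(flat_tr, ytr)
        params = {"w": clf.coef_.reshape(-1), "b": clf.intercept_}
        scorer = TrainedScorer(
            model_kind="lr", hyperparams=hp, params=params,
            feature_set=feature_set, n_rows=n_rows, n_features=n_features,
            training_seed=seed,
        )
        str_scores = _sigmoid(flat_tr @ params["w"] + params["b"][0])
        sva_scores = _sigmoid(xva.reshape(len(xva), -1) @ params["w"] + params["b"][0])
        history = TrainingHistory(
            train_auroc=[float(roc_auc_score(ytr, str_scores))],
            val_auroc=[float(roc_auc_score(yva, sva_scores))],
            train_loss=[float(_bce(ytr, str_scores))],
            best_epoch=0,
            seed=seed,
        )
        return scorer, history

    rng = np.random.default_rng(seed)
    net = _build_network(hp, n_rows, n_features, rng)
    opt = _Optimizer(hp.optimizer, hp.learning_rate)
    history = TrainingHistory(seed=seed)
    best_auc, best_state = -np.inf, net.get_state()
    n = len(xtr)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            if hp.model_kind == "cnn":
                xb = xb[:, None, :, :]
            logits = net.forward(xb, training=True)
            p = _sigmoid(logits)
            losses.append(_bce(yb, p))
            # d BCE / d logits = (p - y) / batch
            net.backward((p - yb) / len(yb))
            opt.step(net.param_triples())
        if not np.isfinite(losses[-1]):
            raise TrainingError("training diverged (non-finite loss)")
        tr_scores = _network_scores(net, xtr, hp)
        va_scores = _network_scores(net, xva, hp)
        tr_auc = float(roc_auc_score(ytr, tr_scores))
        va_auc = float(roc_auc_score(yva, va_scores))
        history.train_auroc.append(tr_auc)
        history.val_auroc.append(va_auc)
        history.train_loss.append(float(np.mean(losses)))
        if va_auc > best_auc:
            best_auc = va_auc
            best_state = net.get_state()
            history.best_epoch = epoch
    net.set_state(best_state)
    scorer = TrainedScorer(
        model_kind=hp.model_kind, hyperparams=hp, params=net.get_state(),
        feature_set=feature_set, n_rows=n_rows, n_features=n_features,
        training_seed=seed,
    )
    return scorer, history


def _bce(y: np.ndarray, p: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def grid_search(
    train_matrices: Sequence[FeatureMatrix],
    val_matrices: Sequence[FeatureMatrix],
    grid: Sequence[HyperParams],
    seeds: Sequence[int] = (0, 1, 2),
    epochs: int = 50,
):
    """Train every config once per seed; rank by mean best validation AUROC.

    Returns (best HyperParams, report rows).  Each report row holds the
    config index, mean and sd of the best validation AUROC over the seeds.
    Ties go to the earlier config in grid order.
    """
    if not grid:
        raise ParameterError("empty hyperparameter grid")
    report = []
    for i, hp in enumerate(grid):
        aucs = []
        for seed in seeds:
            _, hist = train_scorer(
                train_matrices, val_matrices, hp, epochs=epochs, seed=seed
            )
            aucs.append(max(hist.val_auroc))
        report.append(
            {"config": i, "mean_val_auroc": float(np.mean(aucs)),
             "sd_val_auroc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0}
        )
    # ties to the first config in grid order
    best_mean = max(r["mean_val_auroc"] for r in report)
    best_i = next(i for i, r in enumerate(report)
                  if r["mean_val_auroc"] == best_mean)
    return grid[best_i], report


# -- scoring ----------------------------------------------------------------


def _rebuild_network(scorer: TrainedScorer) -> _Network:
    rng = np.random.default_rng(0)  # weights overwritten from stored params
    net = _build_network(scorer.hyperparams, scorer.n_rows, scorer.n_features, rng)
    net.set_state(scorer.params)
    return net


def score_pockets(
    scorer: TrainedScorer, matrices: Sequence[FeatureMatrix]
) -> np.ndarray:
    """Batched scoring; deterministic (dropout off)."""
    if not len(matrices):
        return np.array([])
    for m in matrices:
        if m.values.shape != (scorer.n_rows, scorer.n_features):
            raise ParameterError(
                f"matrix shape {m.values.shape} does not match scorer "
                f"({scorer.n_rows}, {scorer.n_features})"
            )
    x = np.stack([m.values for m in matrices])
    if scorer.model_kind == "lr":
        return _sigmoid(x.reshape(len(x), -1) @ scorer.params["w"]
                        + scorer.params["b"][0])
    return _network_scores(_rebuild_network(scorer), x, scorer.hyperparams)


def score_pocket(scorer: TrainedScorer, matrix: FeatureMatrix) -> float:
    return float(score_pockets(scorer, [matrix])[0])


def select_threshold(
    scorer: TrainedScorer, val_matrices: Sequence[FeatureMatrix]
) -> float:
    """Decision threshold maximizing TPR − FPR on validation scores.

    Candidates are the sorted unique validation scores; predictions at a
    candidate t are ``score >= t``.  Ties resolve to the smallest t.  The
    chosen value is stored on the scorer and returned.
    """
    _, y = _stack(val_matrices)
    if len(set(y)) < 2:
        raise ParameterError("validation set must contain both classes")
    scores = score_pockets(scorer, val_matrices)
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    best_t, best_j = None, -np.inf
    for t in np.sort(np.unique(scores)):
        pred = scores >= t
        tpr = (pred & (y == 1)).sum() / n_pos
        fpr = (pred & (y == 0)).sum() / n_neg
        j = tpr - fpr
        if j > best_j:  # strict: ties keep the earlier (smaller) t
            best_j, best_t = j, float(t)
    if best_j <= 0:
        warnings.warn(
            f"best TPR-FPR is {best_j:.3f} <= 0; scorer is uninformative or "
            "anti-correlated", stacklevel=2,
        )
    scorer.threshold_t = best_t
    return best_t


# -- serialization ----------------------------------------------------------


def save_scorer(scorer: TrainedScorer, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "params.npz", **scorer.params)
    meta = {
        "format_version": 1,
        "model_kind": scorer.model_kind,
        "hyperparams": asdict(scorer.hyperparams),
        "feature_set": scorer.feature_set,
        "n_rows": scorer.n_rows,
        "n_features": scorer.n_features,
        "method_order": scorer.method_order,
        "threshold_t": scorer.threshold_t,
        "training_seed": scorer.training_seed,
    }
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_scorer(directory: str | Path) -> TrainedScorer:
    directory = Path(directory)
    with open(directory / "meta.json") as fh:
        meta = json.load(fh)
    with np.load(directory / "params.npz") as npz:
        params = {k: npz[k].copy() for k in npz.files}
    return TrainedScorer(
        model_kind=meta["model_kind"],
        hyperparams=HyperParams(**meta["hyperparams"]),
        params=params,
        feature_set=meta["feature_set"],
        n_rows=meta["n_rows"],
        n_features=meta["n_features"],
        method_order=meta["method_order"],
        threshold_t=meta["threshold_t"],
        training_seed=meta["training_seed"],
    )
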