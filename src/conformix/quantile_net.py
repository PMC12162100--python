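"""Two-output quantile-regression network trained with pinball loss.

A single feed-forward network with four fully connected hidden layers (ReLU
activations, dropout between layers) and a two-unit linear head emits the
lower and upper conditional quantile estimates (q_lo, q_hi) of the malignant
fraction for a preprocessed expression vector. Sharing the trunk between the
two quantile heads halves the cost relative to fitting two separate
networks. Training minimises the summed pinball losses at levels alpha/2 and
1 - alpha/2 with Adam; dropout is the regulariser.

The pinball (quantile) loss at level a is

    rho_a(y, yhat) = a * (y - yhat)        if y - yhat > 0
                     (1 - a) * (yhat - y)  otherwise,

whose expected-loss minimiser is the a-quantile of y. The head is linear
(unbounded); prediction intervals are clipped to [0, 1] later, at the
conformalisation step. If a row's raw outputs cross (lower > upper) they are
swapped before being returned -- the minimal monotonicity repair.

Implemented directly on numpy: forward/backward passes, inverted dropout and
the Adam update are a few dozen lines for a network this size, and keeping
them explicit makes the training loop exactly reproducible from a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocess import TransformSpec


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def pinball_loss(y, y_hat, alpha: float):
    """Pinball loss rho_alpha, elementwise (scalar in, scalar out)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    diff = y - y_hat
    out = np.where(diff > 0, alpha * diff, (1.0 - alpha) * (-diff))
    if out.ndim == 0:
        return float(out)
    return out


def _pinball_grad(y: np.ndarray, y_hat: np.ndarray, alpha: float) -> np.ndarray:
    # d rho / d y_hat; the y == y_hat tie takes the "otherwise" branch
    return np.where(y - y_hat > 0, -alpha, 1.0 - alpha)


@dataclass
class QuantileModelConfig:
    """Architecture and optimisation settings.

    Four hidden layers is the fixed architecture; widths, dropout, learning
    rate, batch size and epochs are tunable. ``alpha`` is the significance
    level: the two heads estimate the alpha/2 and 1 - alpha/2 quantiles.
    """

    hidden_sizes: tuple = (512, 256, 128, 64)
    dropout_rate: float = 0.2
    learning_rate: float = 1e-4
    batch_size: int = 128
    epochs: int = 100
    alpha: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if len(self.hidden_sizes) != 4 or any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be four positive integers")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def alpha_lo(self) -> float:
        return self.alpha / 2.0

    @property
    def alpha_hi(self) -> float:
        return 1.0 - self.alpha / 2.0


@dataclass
class QuantileModel:
    """Network parameters plus the preprocessing spec they were trained with."""

    weights: list
    biases: list
    config: QuantileModelConfig
    transform_spec: TransformSpec | None = None
    loss_history: list = field(default_factory=list)

    @property
    def alpha(self) -> float:
        return self.config.alpha

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[0]

    # ---- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool = False,
                 rng: np.random.Generator | None = None):
        """Returns (output, cache). Dropout (inverted) is applied after each
        hidden ReLU only in training mode."""
        p = self.config.dropout_rate
        a = X
        cache = []
        n_hidden = len(self.weights) - 1
        for layer in range(n_hidden):
            z = a @ self.weights[layer] + self.biases[layer]
            h = np.maximum(z, 0.0)
            if training and p > 0:
                mask = (rng.random(h.shape) >= p) / (1.0 - p)
                h_drop = h * mask
            else:
                mask = None
                h_drop = h
            cache.append((a, z, mask))
            a = h_drop
        out = a @ self.weights[-1] + self.biases[-1]
        cache.append((a, None, None))
        return out, cache

    def _backward(self, dout: np.ndarray, cache) -> tuple[list, list]:
        grads_W = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        a_last = cache[-1][0]
        grads_W[-1] = a_last.T @ dout
        grads_b[-1] = dout.sum(axis=0)
        da = dout @ self.weights[-1].T
        for layer in range(len(self.weights) - 2, -1, -1):
            a_in, z, mask = cache[layer]
            if mask is not None:
                da = da * mask
            dz = da * (z > 0)
            grads_W[layer] = a_in.T @ dz
            grads_b[layer] = dz.sum(axis=0)
            if layer > 0:
                da = dz @ self.weights[layer].T
        return grads_W, grads_b


def build_network(config: QuantileModelConfig, n_features: int) -> QuantileModel:
    """Initialise an untrained network (He-normal weights, zero biases),
    deterministically from ``config.seed``."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(config.seed)
    sizes = [n_features, *config.hidden_sizes, 2]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / fan_in)
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return QuantileModel(weights=weights, biases=biases, config=config)


def train(model: QuantileModel, X: np.ndarray, y: np.ndarray,
          config: QuantileModelConfig | None = None) -> QuantileModel:
    """Train in place with Adam on the summed two-level pinball loss.

    Minibatches are reshuffled every epoch from a seeded stream; the mean
    per-epoch loss is appended to ``model.loss_history``. Raises
    :class:`TrainingDivergedError` if the loss becomes non-finite.
    """
    cfg = config or model.config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise ValueError("X rows must match y")
    if X.shape[1] != model.n_features:
        raise ValueError(f"X has {X.shape[1]} features, model expects {model.n_features}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = X.shape[0]
    a_lo, a_hi = cfg.alpha_lo, cfg.alpha_hi
    params = model.weights + model.biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            out, cache = model._forward(xb, training=True, rng=rng)
            loss = float(np.mean(pinball_loss(yb, out[:, 0], a_lo)
                                 + pinball_loss(yb, out[:, 1], a_hi)))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {step}: {loss}")
            dout = np.column_stack([
                _pinball_grad(yb, out[:, 0], a_lo),
                _pinball_grad(yb, out[:, 1], a_hi),
            ]) / len(yb)
            gW, gb = model._backward(dout, cache)
            grads = gW + gb
            step += 1
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                m_hat = m[i] / (1 - beta1 ** step)
                v_hat = v[i] / (1 - beta2 ** step)
                p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            epoch_loss += loss
            n_batches += 1
        model.loss_history.append(epoch_loss / n_batches)
    return model


def predict_quantiles(model: QuantileModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation-mode quantile predictions (dropout off); crossed pairs are
    swapped so q_lo <= q_hi elementwise."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(f"X must be 2-D with {model.n_features} features")
    out, _ = model._forward(X, training=False)
    q_lo = np.minimum(out[:, 0], out[:, 1])
    q_hi = np.maximum(out[:, 0], out[:, 1])
    return q_lo, q_hi


# ---- serialization ---------------------------------------------------------

def save_model(model: QuantileModel, path: str) -> None:
    """Serialize parameters + config + transform spec to one .npz file."""
    arrays = {}
    for i, W in enumerate(model.weights):
        arrays[f"W{i}"] = W
    for i, b in enumerate(model.biases):
        arrays[f"b{i}"] = b
    meta = {"config": asdict(model.config), "n_layers": len(model.weights)}
    if model.transform_spec is not None:
        meta["transform"] = {
            "variance_threshold": model.transform_spec.variance_threshold,
            "apply_tfidf": model.transform_spec.apply_tfidf,
        }
        arrays["retained_genes"] = np.asarray(
            [str(g) for g in model.transform_spec.retained_genes])
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_model(path: str) -> QuantileModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta_json"]))
        cfg_d = meta["config"]
        cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
        config = QuantileModelConfig(**cfg_d)
        n_layers = meta["n_layers"]
        weights = [data[f"W{i}"] for i in range(n_layers)]
        biases = [data[f"b{i}"] for i in range(n_layers)]
        spec = None
        if "transform" in meta:
            spec = TransformSpec(
                retained_genes=data["retained_genes"].astype(object),
                variance_threshold=meta["transform"]["variance_threshold"],
                apply_tfidf=meta["transform"]["apply_tfidf"],
            )
    return QuantileModel(weights=weights, biases=biases, config=config,
                         transform_spec=spec)
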