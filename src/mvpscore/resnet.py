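"""The MVP network: a 1D convolutional residual classifier over ordered features.

Architecture (lengths shown for the 38-feature constrained-gene model):

    input (1 x L) -> conv(1->32, k=3, stride 1, same padding)
    -> [ residual unit: conv(32->32, k=3) -> ReLU -> conv(32->32, k=3);
         sum with unit input; ReLU; max-pool(size 2, ceil) ] x 2
    -> flatten (L=38 -> 19 -> 10, x32 channels = 320)
    -> FC(320 -> 512) -> ReLU -> FC(512 -> 1) -> sigmoid

The convolutional stack holds 32*(3+1) + 2*2*(32*3*32 + 32) = 12,544
parameters. Training uses Adam on binary cross-entropy with an 80/20
train/validation split and early stopping: after each full pass over the
training data the validation loss is computed, and training stops once it
has not decreased for ``patience`` further cycles; the weights from the
cycle with the lowest validation loss are restored.

Everything — forward, backward, the optimizer — is implemented on NumPy
arrays, which keeps training bit-for-bit reproducible under a fixed seed on
any platform.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .features import FeatureOrder
from .variants import FeatureMatrix


@dataclass
class ModelConfig:
    """Hyperparameters of the network and its training loop."""

    n_features: int
    n_kernels: int = 32
    kernel_size: int = 3
    stride: int = 1
    n_residual_units: int = 2
    pool_size: int = 2
    fc_hidden: int = 512
    batch_size: int = 64
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.99
    eps: float = 1e-8
    patience: int = 5
    max_cycles: int = 100
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residual_units < 1:
            raise ValueError("n_residual_units must be >= 1")
        if self.n_features < self.kernel_size:
            raise ValueError(
                f"n_features ({self.n_features}) must be >= kernel_size "
                f"({self.kernel_size})"
            )
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.stride != 1:
            raise ValueError("only stride 1 is supported")


def conv_stack_param_count(config: ModelConfig) -> int:
    """Closed-form parameter count of the convolutional stack.

    input conv: n_kernels * (kernel_size * 1 + 1); each residual unit adds two
    conv layers of n_kernels * kernel_size * n_kernels weights + n_kernels
    biases.
    """
    nk, k = config.n_kernels, config.kernel_size
    return nk * (k * 1 + 1) + config.n_residual_units * 2 * (nk * k * nk + nk)


def flattened_length(config: ModelConfig) -> int:
    """Length x channels entering the first FC layer (ceil-mode pooling)."""
    length = config.n_features
    for _ in range(config.n_residual_units):
        length = math.ceil(length / config.pool_size)
    return length * config.n_kernels


# ---------------------------------------------------------------------------
# layer primitives (B = batch, C = channels, L = length)


def _conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded 1D convolution. x: (B, Cin, L); w: (Cout, Cin, k)."""
    k = w.shape[2]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, k - 1 - pad)))
    win = sliding_window_view(xp, k, axis=2)  # (B, Cin, L, k)
    y = np.einsum("bcik,ock->boi", win, w, optimize=True) + b[None, :, None]
    return y, (x.shape, win, w)


def _conv1d_backward(dy: np.ndarray, cache):
    (bsz, cin, length), win, w = cache
    k = w.shape[2]
    pad = k // 2
    db = dy.sum(axis=(0, 2))
    dw = np.einsum("boi,bcik->ock", dy, win, optimize=True)
    dxp = np.zeros((bsz, cin, length + k - 1), dtype=dy.dtype)
    for j in range(k):
        dxp[:, :, j : j + length] += np.einsum(
            "boi,oc->bci", dy, w[:, :, j], optimize=True
        )
    return dxp[:, :, pad : pad + length], dw, db


def _maxpool_forward(x: np.ndarray, size: int):
    """Ceil-mode max pooling: trailing partial window is kept."""
    bsz, ch, length = x.shape
    out_len = math.ceil(length / size)
    padded = out_len * size
    xp = np.pad(
        x, ((0, 0), (0, 0), (0, padded - length)), constant_values=-np.inf
    )
    xr = xp.reshape(bsz, ch, out_len, size)
    arg = xr.argmax(axis=3)
    y = np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]
    return y, (x.shape, arg, size, padded)


def _maxpool_backward(dy: np.ndarray, cache):
    (bsz, ch, length), arg, size, padded = cache
    dxp = np.zeros((bsz, ch, padded // size, size), dtype=dy.dtype)
    np.put_along_axis(dxp, arg[..., None], dy[..., None], axis=3)
    return dxp.reshape(bsz, ch, padded)[:, :, :length]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------


@dataclass
class ResNetModel:
    """Architecture config, weight tensors, and the fit context they belong to.

    ``feature_order`` and ``partition`` tie the weights to the exact column
    permutation and gene class they were trained on; scoring refuses input
    whose features do not match.
    """

    config: ModelConfig
    params: dict[str, np.ndarray]
    feature_order: FeatureOrder | None = None
    partition: str | None = None
    history: list[dict] = field(default_factory=list)

    # -- persistence --------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"config": asdict(self.config), "partition": self.partition}
        (outdir / "model.json").write_text(json.dumps(meta, indent=1))
        (outdir / "history.json").write_text(json.dumps(self.history, indent=1))
        np.savez(outdir / "weights.npz", **self.params)
        if self.feature_order is not None:
            self.feature_order.to_json(outdir / "feature_order.json")

    @classmethod
    def load(cls, outdir: str | Path) -> "ResNetModel":
        outdir = Path(outdir)
        meta = json.loads((outdir / "model.json").read_text())
        with np.load(outdir / "weights.npz") as npz:
            params = {k: npz[k].copy() for k in npz.files}
        fo_path = outdir / "feature_order.json"
        feature_order = FeatureOrder.from_json(fo_path) if fo_path.exists() else None
        hist_path = outdir / "history.json"
        history = json.loads(hist_path.read_text()) if hist_path.exists() else []
        return cls(
            config=ModelConfig(**meta["config"]),
            params=params,
            feature_order=feature_order,
            partition=meta.get("partition"),
            history=history,
        )

    # -- forward / backward --------------------------------------------------

    def _forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (B, n_features) -> logits (B,). Cache retained for backprop."""
        cfg = self.config
        p = self.params
        h = x[:, None, :]  # (B, 1, L)
        caches: list = []
        h, c = _conv1d_forward(h, p["conv0_w"], p["conv0_b"])
        caches.append(("conv0", c))
        for i in range(cfg.n_residual_units):
            unit_in = h
            h1, c1 = _conv1d_forward(unit_in, p[f"ru{i}_c1_w"], p[f"ru{i}_c1_b"])
            a1 = _relu(h1)
            h2, c2 = _conv1d_forward(a1, p[f"ru{i}_c2_w"], p[f"ru{i}_c2_b"])
            s = h2 + unit_in
            r = _relu(s)
            h, cp = _maxpool_forward(r, cfg.pool_size)
            caches.append((f"ru{i}", (c1, h1, c2, s, cp)))
        bsz = h.shape[0]
        flat = h.reshape(bsz, -1)
        z1 = flat @ p["fc1_w"] + p["fc1_b"]
        a2 = _relu(z1)
        logits = (a2 @ p["fc2_w"] + p["fc2_b"])[:, 0]
        caches.append(("fc", (h.shape, flat, z1, a2)))
        return (logits, caches) if want_cache else logits

    def _backward(self, dlogits: np.ndarray, caches) -> dict[str, np.ndarray]:
        cfg = self.config
        p = self.params
        grads: dict[str, np.ndarray] = {}
        name, (h_shape, flat, z1, a2) = caches[-1]
        dl = dlogits[:, None]
        grads["fc2_w"] = a2.T @ dl
        grads["fc2_b"] = dl.sum(axis=0)
        da2 = dl @ p["fc2_w"].T
        dz1 = da2 * (z1 > 0)
        grads["fc1_w"] = flat.T @ dz1
        grads["fc1_b"] = dz1.sum(axis=0)
        dh = (dz1 @ p["fc1_w"].T).reshape(h_shape)
        for i in range(cfg.n_residual_units - 1, -1, -1):
            _, (c1, h1, c2, s, cp) = caches[1 + i]
            dr = _maxpool_backward(dh, cp)
            ds = dr * (s > 0)
            dh2 = ds  # residual sum: gradient flows to conv branch ...
            da1, dw2, db2 = _conv1d_backward(dh2, c2)
            grads[f"ru{i}_c2_w"] = dw2
            grads[f"ru{i}_c2_b"] = db2
            dh1 = da1 * (h1 > 0)
            dunit, dw1, db1 = _conv1d_backward(dh1, c1)
            grads[f"ru{i}_c1_w"] = dw1
            grads[f"ru{i}_c1_b"] = db1
            dh = dunit + ds  # ... and through the identity shortcut
        _, c0 = caches[0]
        _, dw0, db0 = _conv1d_backward(dh, c0)
        grads["conv0_w"] = dw0
        grads["conv0_b"] = db0
        return grads

    # -- inference -----------------------------------------------------------

    def predict_logits(self, X: np.ndarray, chunk: int = 512) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.n_features:
            raise ValueError(
                f"expected (n, {self.config.n_features}) input, got {X.shape}"
            )
        return np.concatenate(
            [self._forward(X[i : i + chunk]) for i in range(0, len(X), chunk)]
        ) if len(X) else np.empty(0)


def build_model(config: ModelConfig) -> ResNetModel:
    """Initialize an untrained network (He-uniform weights, zero biases)."""
    rng = np.random.default_rng(config.seed)
    nk, k = config.n_kernels, config.kernel_size

    def he_uniform(shape, fan_in):
        limit = math.sqrt(6.0 / fan_in)
        return rng.uniform(-limit, limit, size=shape)

    params: dict[str, np.ndarray] = {
        "conv0_w": he_uniform((nk, 1, k), fan_in=1 * k),
        "conv0_b": np.zeros(nk),
    }
    for i in range(config.n_residual_units):
        for j in (1, 2):
            params[f"ru{i}_c{j}_w"] = he_uniform((nk, nk, k), fan_in=nk * k)
            params[f"ru{i}_c{j}_b"] = np.zeros(nk)
    flat = flattened_length(config)
    params["fc1_w"] = he_uniform((flat, config.fc_hidden), fan_in=flat)
    params["fc1_b"] = np.zeros(config.fc_hidden)
    params["fc2_w"] = he_uniform((config.fc_hidden, 1), fan_in=config.fc_hidden)
    params["fc2_b"] = np.zeros(1)
    return ResNetModel(config=config, params=params)


def _bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
    # softplus(z) - y*z, computed stably
    return float(np.mean(np.logaddexp(0.0, logits) - y * logits))


def train(
    model: ResNetModel,
    X: FeatureMatrix | np.ndarray,
    y: Sequence[int] | np.ndarray,
    *,
    feature_order: FeatureOrder | None = None,
    partition: str | None = None,
) -> ResNetModel:
    """Fit the network in place and return it.

    ``X`` must already be ordered by the feature order the model will be
    tagged with (pass ``feature_order`` to record it on the artifact).
    Training runs Adam over shuffled mini-batches; after each cycle the
    validation loss on a held-out 20% split is recorded, and the weights from
    the best cycle are restored at the end.
    """
    cfg = model.config
    if isinstance(X, FeatureMatrix):
        if feature_order is not None:
            X = feature_order.apply(X)
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if len(X) < 2 * cfg.batch_size:
        raise ValueError(
            f"need at least {2 * cfg.batch_size} samples, got {len(X)}"
        )

    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(len(X))
    n_val = max(1, int(round(cfg.validation_fraction * len(X))))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    # Adam state
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    t = 0

    best_val = math.inf
    best_params: dict[str, np.ndarray] | None = None
    stall = 0
    model.history = []

    for cycle in range(cfg.max_cycles):
        order = rng.permutation(len(Xtr))
        train_loss_accum = 0.0
        n_batches = 0
        for start in range(0, len(Xtr), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            logits, caches = model._forward(xb, want_cache=True)
            train_loss_accum += _bce_from_logits(logits, yb)
            n_batches += 1
            dlogits = (_sigmoid(logits) - yb) / len(yb)
            grads = model._backward(dlogits, caches)
            t += 1
            bc1 = 1.0 - cfg.beta1**t
            bc2 = 1.0 - cfg.beta2**t
            for k, g in grads.items():
                m[k] = cfg.beta1 * m[k] + (1 - cfg.beta1) * g
                v[k] = cfg.beta2 * v[k] + (1 - cfg.beta2) * g * g
                model.params[k] -= (
                    cfg.learning_rate * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + cfg.eps)
                )
        val_loss = _bce_from_logits(model.predict_logits(Xval), yval)
        model.history.append(
            {
                "cycle": cycle,
                "train_loss": train_loss_accum / n_batches,
                "val_loss": val_loss,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: p.copy() for k, p in model.params.items()}
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    if best_params is not None:
        model.params = best_params
    model.feature_order = feature_order
    model.partition = partition
    return model


def predict_raw(model: ResNetModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Raw sigmoid outputs in (0, 1), one per row.

    A :class:`FeatureMatrix` input is checked (and reordered) against the
    model's fitted feature order; a name mismatch raises.
    """
    if isinstance(X, FeatureMatrix):
        if model.feature_order is not None:
            if sorted(X.feature_names) != sorted(model.feature_order.names):
                raise ValueError(
                    "feature names do not match the model's fitted feature order"
                )
            X = model.feature_order.apply(X)
        X = X.values
    p = _sigmoid(model.predict_logits(np.asarray(X, dtype=float)))
    # keep the open-interval contract where float rounding would saturate
    return np.clip(p, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


def crossvalidate(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[int] | np.ndarray,
    k: int = 6,
    config: ModelConfig | None = None,
) -> dict:
    """Stratified k-fold cross-validation; returns per-fold and mean AUC."""
    from sklearn.model_selection import StratifiedKFold

    from .evaluation import roc_auc

    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the size of the smallest class ({counts.min()})")
    if config is None:
        config = ModelConfig(n_features=X.shape[1])

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    aucs = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_cfg = ModelConfig(**{**asdict(config), "seed": config.seed + fold})
        mdl = build_model(fold_cfg)
        train(mdl, X[tr], y[tr])
        scores = predict_raw(mdl, X[te])
        aucs.append(roc_auc(y[te], scores).auc)
    return {"fold_aucs": aucs, "mean_auc": float(np.mean(aucs))}
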