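"""Training: Adam with staircase-decayed learning rate, backprop through
the layer graph, five-fold cross-validation, and a scikit-learn style
estimator wrapping the whole pipeline.

The optimizer follows the published recipe: Adam with beta1=0.9,
beta2=0.999, epsilon=1e-7; learning rate 1e-3 decayed by 4% every 800
optimizer steps (staircase); weighted binary cross-entropy loss; a
pixel is predicted foreground when its sigmoid output exceeds 0.5.

Gradients are computed by reverse-mode differentiation over the same
explicit node graph the forward pass executes; convolutions in both
directions are per-kernel-tap BLAS matrix products.  The loss gradient
is taken with respect to the output logits, fusing the final sigmoid
with the cross-entropy for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import graph as G
from .data import AugmentConfig, augment, kfold_split
from .loss_metrics import (ConfusionCounts, SegMetrics, _weight_mat,
                           binarize, confusion_counts, metric_suite)

__all__ = [
    "TrainConfig", "TrainedModel", "lr_schedule", "train", "predict_mask",
    "cross_validate", "TinyObjectSegmenter",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 150
    batch_size: int = 8
    initial_lr: float = 1e-3
    decay_rate: float = 0.96  # 4% decay ...
    decay_steps: int = 800  # ... every 800 optimizer steps (staircase)
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    threshold: float = 0.5
    seed: int = 0
    augment_config: AugmentConfig | None = None
    patience: int | None = None  # early stop on stalled validation rw_f1
    min_delta: float = 1e-3

    def __post_init__(self) -> None:
        if self.initial_lr <= 0:
            raise ValueError("learning rate must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("betas must lie in [0, 1)")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class TrainedModel:
    model: G.ModelSpec
    config: TrainConfig
    history: pd.DataFrame  # per-epoch loss and validation metrics


def lr_schedule(step: int, cfg: TrainConfig) -> float:
    """Staircase exponential decay: constant within each decay window."""
    if step < 0:
        raise ValueError("step must be non-negative")
    return cfg.initial_lr * cfg.decay_rate ** (step // cfg.decay_steps)


# ---------------------------------------------------------------------------
# reverse-mode pass over the node graph
# ---------------------------------------------------------------------------

def _forward_tape(model: G.ModelSpec, x: np.ndarray):
    """Forward pass keeping what backward needs.

    Returns (logits of the final conv, tape).  The final activation is
    NOT applied: the loss is evaluated on logits.
    """
    tape: dict[str, dict] = {}
    acts: dict[str, np.ndarray] = {"": x}
    for node in model.nodes:
        ins = [acts[s] for s in node.inputs]
        rec: dict = {}
        if node.op == "input":
            val = x
        elif node.op == "conv":
            spec = node.conv
            rec["x"] = ins[0]
            z = G.conv2d_same(ins[0], spec.kernel, spec.bias, spec.stride)
            if node is model.nodes[-1]:
                val = z  # logits; sigmoid fused into the loss
            else:
                val = G.apply_activation(z, spec.activation)
                if spec.activation == "relu":
                    rec["mask"] = val > 0
        elif node.op == "maxpool2":
            rec["x"] = ins[0]
            val = G.maxpool2(ins[0])
        elif node.op == "upsample2":
            val = G.upsample2(ins[0])
        elif node.op == "concat":
            rec["splits"] = np.cumsum([a.shape[-1] for a in ins])[:-1]
            val = np.concatenate(ins, axis=-1)
        elif node.op == "add":
            val = ins[0] + ins[1]
        elif node.op == "relu":
            val = np.maximum(ins[0], 0.0)
            rec["mask"] = val > 0
        else:  # pragma: no cover
            raise G.GraphError(node.op)
        acts[node.id] = val
        tape[node.id] = rec
    return acts[model.output_id], tape, acts


def _conv_backward(spec: G.ConvSpec, x: np.ndarray, g: np.ndarray):
    """Gradients of a same-padded stride-1 convolution (per-tap GEMMs)."""
    k = spec.kernel_size
    cin, cout = spec.in_channels, spec.out_channels
    n, h, w, _ = x.shape
    xm = x.reshape(n * h * w, cin)
    gm = g.reshape(n * h * w, cout)
    db = gm.sum(axis=0)
    kernel = spec.kernel
    if k == 1:
        dW = (xm.T @ gm).reshape(1, 1, cin, cout)
        dx = (gm @ kernel.reshape(cin, cout).T).reshape(n, h, w, cin)
        return dW, db, dx
    pad = (k - 1) // 2
    gp = np.pad(g, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    dW = np.empty((k, k, cin, cout), dtype=np.float32)
    dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, cin), dtype=np.float32)
    for u in range(k):
        du = u - pad
        for v in range(k):
            dv = v - pad
            gs = np.ascontiguousarray(
                gp[:, pad - du:pad - du + h, pad - dv:pad - dv + w])
            dW[u, v] = xm.T @ gs.reshape(n * h * w, cout)
            t = (gm @ kernel[u, v].T).reshape(n, h, w, cin)
            dxp[:, pad + du:pad + du + h, pad + dv:pad + dv + w] += t
    dx = dxp[:, pad:pad + h, pad:pad + w]
    return dW, db, dx


def _maxpool_backward(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    blocks = x.reshape(n, h // 2, 2, w // 2, 2, c)
    flat = blocks.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
    idx = flat.argmax(axis=-1)
    out = np.zeros_like(flat)
    np.put_along_axis(out, idx[..., None], g[..., None], axis=-1)
    return (out.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c))


def _backward(model: G.ModelSpec, tape: dict, dlogits: np.ndarray
              ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Parameter gradients for every conv node, from d(loss)/d(logits)."""
    grads: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    gacc: dict[str, np.ndarray] = {model.output_id: dlogits}
    for node in reversed(model.nodes):
        g = gacc.pop(node.id, None)
        if g is None or node.op == "input":
            continue
        rec = tape[node.id]
        if node.op == "conv":
            if "mask" in rec:
                g = g * rec["mask"]
            dW, db, dx = _conv_backward(node.conv, rec["x"], g)
            grads[node.id] = (dW, db)
            outs = [dx]
        elif node.op == "maxpool2":
            outs = [_maxpool_backward(rec["x"], g)]
        elif node.op == "upsample2":
            n, h, w, c = g.shape
            outs = [g.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))]
        elif node.op == "concat":
            outs = np.split(g, rec["splits"], axis=-1)
        elif node.op == "add":
            outs = [g, g]
        elif node.op == "relu":
            outs = [g * rec["mask"]]
        else:  # pragma: no cover
            raise G.GraphError(node.op)
        for src, dg in zip(node.inputs, outs):
            if src in gacc:
                gacc[src] = gacc[src] + dg
            else:
                gacc[src] = dg
    return grads


def _loss_and_grad(y: np.ndarray, logits: np.ndarray):
    """Weighted BCE on logits; returns (loss, d loss / d logits).

    Per-image pixel sums averaged over the batch; the per-pixel weight
    map uses each image's own class frequencies (unit background weight
    for particle-free crops).
    """
    n = y.shape[0]
    z = logits[..., 0].astype(np.float64)
    w = _weight_mat(y.astype(np.float64), safe=True)
    # CE on logits: softplus(z) - y*z, numerically stable for |z| large
    ce = np.logaddexp(0.0, z) - y * z
    loss = float((ce * w).reshape(n, -1).sum(axis=1).mean())
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    dz = (w * (sig - y) / n)[..., None].astype(np.float32)
    return loss, dz


class _Adam:
    def __init__(self, params: dict[str, tuple[np.ndarray, np.ndarray]],
                 cfg: TrainConfig):
        self.cfg = cfg
        self.t = 0
        self.m = {k: (np.zeros_like(v[0]), np.zeros_like(v[1]))
                  for k, v in params.items()}
        self.v = {k: (np.zeros_like(v[0]), np.zeros_like(v[1]))
                  for k, v in params.items()}

    def step(self, params, grads, lr: float) -> None:
        cfg = self.cfg
        self.t += 1
        b1t = 1 - cfg.beta1 ** self.t
        b2t = 1 - cfg.beta2 ** self.t
        for key, (kernel, bias) in params.items():
            for i, (p, g) in enumerate(zip((kernel, bias), grads[key])):
                m = self.m[key][i]
                v = self.v[key][i]
                m *= cfg.beta1
                m += (1 - cfg.beta1) * g
                v *= cfg.beta2
                v += (1 - cfg.beta2) * g * g
                p -= lr * (m / b1t) / (np.sqrt(v / b2t) + cfg.epsilon)


def _as_batch(x: np.ndarray, channels: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:  # (n, H, W) grayscale
        x = x[..., None]
    if x.shape[-1] != channels:
        raise ValueError(f"expected {channels} channels, got {x.shape[-1]}")
    return x


def train(model: G.ModelSpec, images: np.ndarray, masks: np.ndarray,
          cfg: TrainConfig = TrainConfig(),
          validation: tuple[np.ndarray, np.ndarray] | None = None,
          initialize: bool = True) -> TrainedModel:
    """Fit *model* on (images, masks) with the published recipe.

    ``images``: (n, H, W) or (n, H, W, C) floats; ``masks``: (n, H, W)
    binary.  All randomness (initialization, data order, augmentation)
    flows from ``cfg.seed``.  Raises ``RuntimeError`` on divergence
    (non-finite loss).  With ``patience`` set, training stops once the
    validation rw-F1 has not improved for that many epochs.
    """
    if len(images) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    if initialize:
        model.initialize(rng)
    x_all = _as_batch(images, model.input_shape[2])
    y_all = np.asarray(masks, dtype=np.float32)
    params = model.parameters()
    opt = _Adam(params, cfg)
    history: list[dict] = []
    step = 0
    best_metric, since_best = -np.inf, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_all))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            sel = order[lo:lo + cfg.batch_size]
            xb, yb = x_all[sel], y_all[sel]
            if cfg.augment_config is not None:
                pairs = [augment(xi, yi, cfg.augment_config, rng)
                         for xi, yi in zip(xb, yb)]
                xb = np.stack([p[0] for p in pairs])
                yb = np.stack([p[1] for p in pairs]).astype(np.float32)
            logits, tape, _ = _forward_tape(model, xb)
            loss, dz = _loss_and_grad(yb, logits)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, step {step}: "
                    f"loss={loss}")
            grads = _backward(model, tape, dz)
            opt.step(params, grads, lr_schedule(step, cfg))
            step += 1
            losses.append(loss)
        row = {"epoch": epoch, "loss": float(np.mean(losses)),
               "lr": lr_schedule(step - 1, cfg)}
        if validation is not None:
            vm = _evaluate(model, *validation, cfg)
            row.update({f"val_{k}": v for k, v in vars(vm).items()})
            metric = vm.rw_f1
            if metric > best_metric + cfg.min_delta:
                best_metric, since_best = metric, 0
            else:
                since_best += 1
        history.append(row)
        if (cfg.patience is not None and validation is not None
                and since_best >= cfg.patience):
            break
    return TrainedModel(model=model, config=cfg,
                        history=pd.DataFrame(history))


def _evaluate(model: G.ModelSpec, images, masks, cfg: TrainConfig,
              batch: int = 8) -> SegMetrics:
    """Pooled-confusion metrics of a model over an image stack."""
    x = _as_batch(images, model.input_shape[2])
    y = np.asarray(masks) > 0
    tp = fp = fn = tn = 0
    for lo in range(0, len(x), batch):
        prob = G.forward(model, x[lo:lo + batch])
        pred = binarize(prob, cfg.threshold)
        c = confusion_counts(y[lo:lo + batch], pred)
        tp += c.tp; fp += c.fp; fn += c.fn; tn += c.tn
    return metric_suite(ConfusionCounts(tp, fp, fn, tn))


def predict_mask(tm: TrainedModel | G.ModelSpec, image: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Binary mask: sigmoid output strictly greater than *threshold*."""
    model = tm.model if isinstance(tm, TrainedModel) else tm
    return binarize(G.forward(model, image), threshold)


def cross_validate(arch_names, images, masks, cfg: TrainConfig = TrainConfig(),
                   k: int = 5, configs: dict | None = None,
                   predictor_factory=None) -> pd.DataFrame:
    """K-fold cross-validation of several architectures.

    Returns one row per (architecture, fold) with the six metrics from
    pooled test-set confusion counts, plus per-architecture average
    rows (fold = "avg"), mirroring the published result tables.

    ``predictor_factory(arch, fold_split) -> callable`` may replace
    training entirely (used for plumbing tests); the callable maps an
    image stack to binary masks.
    """
    if isinstance(arch_names, str):
        arch_names = [arch_names]
    n = len(images)
    folds = kfold_split(n, k, rng=cfg.seed)
    rows = []
    for arch in arch_names:
        for fs in folds:
            if predictor_factory is not None:
                predict = predictor_factory(arch, fs)
            else:
                shape = images.shape[1:3] + (1 if images.ndim == 3
                                             else images.shape[3],)
                model = G.build_model(
                    arch, config=(configs or {}).get(arch),
                    input_shape=shape)
                tm = train(model, images[fs.train], masks[fs.train], cfg,
                           validation=(images[fs.validation],
                                       masks[fs.validation]))
                predict = lambda xs, m=tm.model: predict_mask(
                    m, _as_batch(xs, m.input_shape[2]), cfg.threshold)
            pred = predict(images[fs.test])
            met = metric_suite(confusion_counts(
                np.asarray(masks[fs.test]) > 0, pred))
            rows.append({"model": arch, "fold": fs.fold, **vars(met)})
        avg = pd.DataFrame([r for r in rows if r["model"] == arch]
                           ).drop(columns=["model", "fold"]).mean()
        rows.append({"model": arch, "fold": "avg", **avg.to_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class TinyObjectSegmenter(BaseEstimator):
    """Segmentation model with the scikit-learn fit/predict contract.

    Parameters mirror :class:`TrainConfig`; ``X`` is an image stack
    (n, H, W) or (n, H, W, C) and ``y`` the matching binary mask stack
    (n, H, W).  After :meth:`fit`, ``model_`` holds the trained layer
    graph and ``history_`` the per-epoch training record.

    >>> seg = TinyObjectSegmenter(arch="quarter_multiresunet", epochs=5)
    >>> seg.fit(images, masks).predict(images).shape == masks.shape
    """

    def __init__(self, arch: str = "quarter_multiresunet",
                 epochs: int = 50, batch_size: int = 8,
                 learning_rate: float = 1e-3, threshold: float = 0.5,
                 patience: int | None = None, validation_fraction: float = 0.1,
                 augment: bool = False, seed: int = 0):
        self.arch = arch
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.threshold = threshold
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.augment = augment
        self.seed = seed

    def _config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size,
            initial_lr=self.learning_rate, threshold=self.threshold,
            seed=self.seed, patience=self.patience,
            augment_config=AugmentConfig() if self.augment else None)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim not in (3, 4) or y.ndim != 3 or X.shape[:3] != y.shape:
            raise ValueError(
                f"X must be (n, H, W[, C]) and y (n, H, W); got {X.shape} "
                f"and {y.shape}")
        channels = 1 if X.ndim == 3 else X.shape[3]
        shape = (X.shape[1], X.shape[2], channels)
        cfg = self._config()
        model = G.build_model(self.arch, input_shape=shape)
        validation = None
        train_idx = np.arange(len(X))
        if self.validation_fraction and len(X) >= 10:
            rng = np.random.default_rng(cfg.seed)
            perm = rng.permutation(len(X))
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            validation = (X[val_idx], y[val_idx])
        tm = train(model, X[train_idx], y[train_idx], cfg,
                   validation=validation)
        self.model_ = tm.model
        self.history_ = tm.history
        self.n_features_in_ = int(np.prod(shape))
        return self

    def predict_proba(self, X):
        X = _as_batch(np.asarray(X), self.model_.input_shape[2])
        return G.forward(self.model_, X)

    def predict(self, X):
        return binarize(self.predict_proba(X), self.threshold)

    def score(self, X, y):
        """Recall-weighted F1 over pooled confusion counts."""
        met = metric_suite(confusion_counts(np.asarray(y) > 0,
                                            self.predict(X)))
        return met.rw_f1
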