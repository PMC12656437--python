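"""Training: cost-sensitive label-smoothed cross-entropy, AdamW, poly schedule.

False alarms dominate the operational cost of an inline inspector: every
contaminant prediction on clean product triggers manual checking.  The loss
therefore scales the per-pixel smoothed cross-entropy by a penalty factor
W[t, yhat] read from a 13x13 matrix indexed by (true class, predicted class):
misclassifying meat or fat *as a contaminant* costs extra (default 2.0),
misclassifying conveyor belt as a contaminant costs less (default 0.5, a
belt-only alarm is cheap to dismiss), everything else costs 1.  The factor is
gated by the hard argmax and treated as a constant w.r.t. the gradient.

Label smoothing (rate 0.3) softens the one-hot targets to
q_c = (1 - eps) * [c = t] + eps / K, tolerating imprecise annotation at
contaminant borders.  Optimisation is AdamW (lr 1e-3, weight decay 2e-4)
under a polynomial decay schedule with a linear warm-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .taxonomy import UNANNOTATED, ClassTaxonomy, default_taxonomy
from .vitseg import SegModelConfig, backward, forward, init_params


def default_penalty_matrix(
    taxonomy: ClassTaxonomy | None = None, w_high: float = 2.0, w_low: float = 0.5
) -> np.ndarray:
    """W[t, p]: ``w_high`` for meat/fat -> contaminant, ``w_low`` for
    belt -> contaminant, 1 elsewhere.  The penalty *structure* is principled;
    the numeric defaults are package choices exposed in configuration."""
    if not w_high >= 1 >= w_low > 0:
        raise ValueError(f"require w_high >= 1 >= w_low > 0, got {w_high}, {w_low}")
    taxonomy = taxonomy or default_taxonomy()
    k = taxonomy.n_classes
    w = np.ones((k, k), dtype=np.float64)
    contaminants = list(taxonomy.contaminant_indices)
    for name, value in (("meat", w_high), ("fat", w_high)):
        w[taxonomy.index_of(name), contaminants] = value
    w[taxonomy.index_of("conveyor_belt"), contaminants] = w_low
    np.fill_diagonal(w, 1.0)
    return w


@dataclass
class TrainConfig:
    """Training recipe; defaults follow the reference recipe except where a
    value was never published (penalty weights, polynomial power)."""

    epochs: int = 24
    batch_size: int = 520
    lr: float = 1e-3
    weight_decay: float = 2e-4
    warmup_epochs: int = 3
    poly_power: float = 1.0
    label_smoothing: float = 0.3
    seed: int = 0
    penalty_matrix: np.ndarray = field(default_factory=default_penalty_matrix)

    def __post_init__(self) -> None:
        if not 0 <= self.label_smoothing < 1:
            raise ValueError("label smoothing rate must lie in [0, 1)")
        if not self.warmup_epochs < self.epochs:
            raise ValueError("warmup_epochs must be smaller than epochs")
        self.penalty_matrix = np.asarray(self.penalty_matrix, dtype=np.float64)
        if np.any(self.penalty_matrix <= 0) or np.any(np.diag(self.penalty_matrix) != 1):
            raise ValueError("penalty matrix must be positive with unit diagonal")


def smoothed_targets(t: int, eps: float, n_classes: int = 13) -> np.ndarray:
    """q_c = (1 - eps) * [c = t] + eps / K; sums to one."""
    if not 0 <= eps < 1:
        raise ValueError("smoothing rate must lie in [0, 1)")
    q = np.full(n_classes, eps / n_classes, dtype=np.float64)
    q[t] += 1.0 - eps
    return q


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def pixel_loss(logits: np.ndarray, t: int, cfg: TrainConfig) -> float:
    """L = W[t, argmax logits] * ( -sum_c q_c log softmax(logits)_c )."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.isfinite(logits).all():
        raise FloatingPointError("non-finite logits")
    k = logits.shape[-1]
    q = smoothed_targets(t, cfg.label_smoothing, k)
    w = cfg.penalty_matrix[t, int(np.argmax(logits))]
    return float(w * -(q * _log_softmax(logits)).sum())


def batch_loss_and_grad(
    logits: np.ndarray, labels: np.ndarray, cfg: TrainConfig
) -> tuple[float, np.ndarray, float]:
    """Mean weighted smoothed CE over labelled pixels, its logits-gradient,
    and the pixel accuracy.  Pixels labelled 255 contribute nothing.

    For one pixel with weight w the gradient is w * (softmax - q) / N.
    """
    k = logits.shape[-1]
    flat_logits = logits.reshape(-1, k).astype(np.float64)
    flat_labels = labels.reshape(-1)
    valid = flat_labels != UNANNOTATED
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no labelled pixels in batch")
    lv = flat_logits[valid]
    tv = flat_labels[valid].astype(np.int64)
    logp = _log_softmax(lv)
    p = np.exp(logp)
    eps = cfg.label_smoothing
    q = np.full((n_valid, k), eps / k)
    q[np.arange(n_valid), tv] += 1.0 - eps
    pred = np.argmax(lv, axis=1)
    w = cfg.penalty_matrix[tv, pred]
    loss = float((w * -(q * logp).sum(axis=1)).mean())
    dflat = np.zeros_like(flat_logits)
    dflat[valid] = (w[:, None] * (p - q)) / n_valid
    acc = float((pred == tv).mean())
    return loss, dflat.reshape(logits.shape).astype(np.float32), acc


def lr_at(step: int, cfg: TrainConfig, steps_per_epoch: int) -> float:
    """Linear warm-up from 0 over ``warmup_epochs``, then polynomial decay
    lr * (1 - s/S)^power down to 0 at the final step."""
    if step < 0:
        raise ValueError("step must be non-negative")
    warmup = cfg.warmup_epochs * steps_per_epoch
    total = cfg.epochs * steps_per_epoch
    if warmup > 0 and step < warmup:
        return cfg.lr * step / warmup
    s = step - warmup
    span = max(total - warmup, 1)
    frac = min(s / span, 1.0)
    return cfg.lr * (1.0 - frac) ** cfg.poly_power


class AdamW:
    """Decoupled-weight-decay Adam.  Decay applies to weight matrices only
    (ndim >= 2); biases and LayerNorm parameters are not decayed."""

    def __init__(self, params: dict[str, np.ndarray], weight_decay: float, betas=(0.9, 0.999), eps=1e-8):
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for key, p in params.items():
            g = grads[key].astype(np.float64)
            m = self.m[key]
            v = self.v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if p.ndim >= 2:
                update = update + self.weight_decay * p
            params[key] = (p - lr * update).astype(np.float32)


@dataclass
class EpochLog:
    epoch: int
    loss: float
    accuracy: float
    lr: float
    val_miou: float | None = None


def train(
    tiles: np.ndarray,
    labels: np.ndarray,
    model_cfg: SegModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[dict[str, np.ndarray], list[EpochLog]]:
    """Run the recipe on (N, 20, 16, 184) tiles with (N, 20, 16) labels.

    Shuffling is seeded and epochs are fixed (no early stopping).  Pixels
    labelled 255 are kept in the input for spatial context but excluded from
    the loss.  With a validation split the parameters with the best
    validation mIoU are returned, otherwise the final parameters.
    """
    from .evaluate import confusion_and_miou  # local import to avoid a cycle

    model_cfg = model_cfg or SegModelConfig()
    train_cfg = train_cfg or TrainConfig()
    tiles = np.asarray(tiles, dtype=np.float32)
    labels = np.asarray(labels)
    n = tiles.shape[0]
    if np.all(labels == UNANNOTATED):
        raise ValueError("training set has no labelled pixels")
    present = np.unique(labels[labels != UNANNOTATED])
    if present.size < 2:
        raise ValueError(f"training set must contain at least 2 classes, found {present.tolist()}")

    rng = np.random.default_rng(train_cfg.seed)
    params = init_params(model_cfg, seed=train_cfg.seed)
    optimizer = AdamW(params, weight_decay=train_cfg.weight_decay)
    batch = min(train_cfg.batch_size, n)
    steps_per_epoch = max(n // batch, 1)
    drop_rng = np.random.default_rng(train_cfg.seed + 1) if model_cfg.dropout > 0 else None

    logs: list[EpochLog] = []
    best_params = None
    best_miou = -1.0
    step = 0
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses, accs = [], []
        lr = 0.0
        for b in range(steps_per_epoch):
            idx = order[b * batch : (b + 1) * batch]
            lr = lr_at(step, train_cfg, steps_per_epoch)
            logits, cache = forward(params, tiles[idx], model_cfg, need_cache=True, drop_rng=drop_rng)
            loss, dlogits, acc = batch_loss_and_grad(logits, labels[idx], train_cfg)
            grads = backward(params, cache, dlogits, model_cfg)
            optimizer.step(params, grads, lr)
            losses.append(loss)
            accs.append(acc)
            step += 1
        entry = EpochLog(epoch=epoch, loss=float(np.mean(losses)), accuracy=float(np.mean(accs)), lr=lr)
        if validation is not None:
            val_x, val_y = validation
            pred = _predict_in_batches(params, val_x, model_cfg)
            _, miou = confusion_and_miou(pred.reshape(-1), val_y.reshape(-1), n_classes=model_cfg.n_classes)
            entry.val_miou = miou
            if miou > best_miou:
                best_miou = miou
                best_params = {k: v.copy() for k, v in params.items()}
        logs.append(entry)
    if validation is not None and best_params is not None:
        params = best_params
    return params, logs


def _predict_in_batches(params, tiles, model_cfg, batch: int = 64) -> np.ndarray:
    out = []
    for start in range(0, tiles.shape[0], batch):
        logits, _ = forward(params, tiles[start : start + batch], model_cfg)
        out.append(np.argmax(logits, axis=-1).astype(np.uint8))
    return np.concatenate(out, axis=0)


def logs_to_csv(logs: list[EpochLog], path) -> None:
    import pandas as pd

    pd.DataFrame([vars(e) for e in logs]).to_csv(path, index=False)
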