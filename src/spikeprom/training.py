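"""Surrogate-gradient training, evaluation metrics, and cross-validation.

Training minimizes the mean-square error between the readout firing rates and
one-hot class targets with Adam.  The forward pass uses hard threshold
spikes; the backward pass substitutes the surrogate derivative at every
neuron (see :mod:`spikeprom.neurons`), so a plain gradient step applies.

Threshold metrics follow the standard confusion-matrix definitions

    Sn  = TP / (TP + FN)            Sp  = TN / (TN + FP)
    Pre = TP / (TP + FP)            Acc = (TP + TN) / n
    F1  = 2 Pre Sn / (Pre + Sn)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with any zero-denominator case reported as 0.  Ranking metrics (AUC, AUPRC)
score samples by the positive-class firing rate.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import PromoterNet
from .seqdata import SequenceRecord, ValidationError, encode_batch, kfold_split


@dataclasses.dataclass
class TrainConfig:
    lr: float = 0.0009
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    patience: int | None = 10       # early stop when val Acc stops improving
    stop_acc: float | None = None   # optional: stop once val Acc reaches this

    def validate(self):
        if self.lr <= 0:
            raise ValidationError("learning rate must be > 0")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValidationError("epochs >= 0 and batch size >= 1 required")


class Adam:
    """Standard Adam over a named parameter dict."""

    def __init__(self, params: dict[str, tuple[np.ndarray, np.ndarray]], cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, (v, _) in params.items()}
        self.v = {k: np.zeros_like(v) for k, (v, _) in params.items()}
        self.t = 0

    def step(self, params: dict[str, tuple[np.ndarray, np.ndarray]]) -> None:
        c = self.cfg
        self.t += 1
        b1t = 1 - c.beta1 ** self.t
        b2t = 1 - c.beta2 ** self.t
        for k, (val, grad) in params.items():
            m = self.m[k]
            v = self.v[k]
            m *= c.beta1
            m += (1 - c.beta1) * grad
            v *= c.beta2
            v += (1 - c.beta2) * grad * grad
            val -= c.lr * (m / b1t) / (np.sqrt(v / b2t) + c.eps)


def one_hot_targets(y: np.ndarray) -> np.ndarray:
    t = np.zeros((len(y), 2), dtype=np.float32)
    t[np.arange(len(y)), y] = 1.0
    return t


def mse_loss(rates: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean over all entries of the squared difference, plus its gradient."""
    rates = np.asarray(rates)
    targets = np.asarray(targets, dtype=rates.dtype)
    if rates.shape != targets.shape:
        raise ValidationError(f"shape mismatch {rates.shape} vs {targets.shape}")
    diff = rates - targets
    return float(np.mean(diff * diff)), (2.0 / diff.size) * diff


def _forward_in_batches(net: PromoterNet, X: np.ndarray, batch: int = 128) -> np.ndarray:
    return np.concatenate([net.forward(X[i:i + batch]) for i in range(0, len(X), batch)])


def fit(net: PromoterNet, train_records: Sequence[SequenceRecord],
        val_records: Sequence[SequenceRecord] | None, cfg: TrainConfig) -> list[dict]:
    """Train in place; returns per-epoch history dicts.

    History entries carry ``epoch``, ``train_loss`` and, when a validation
    set is given, ``val_loss`` / ``val_acc``.  Fully deterministic given
    ``cfg.seed`` (batch shuffling and dropout masks both derive from it).
    """
    cfg.validate()
    if len(train_records) == 0:
        raise ValidationError("empty training set")
    X, y = encode_batch(train_records)
    targets = one_hot_targets(y)
    Xv = yv = None
    if val_records:
        Xv, yv = encode_batch(val_records)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params(), cfg)
    history: list[dict] = []
    best_acc, since_best = -1.0, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            net.zero_grads()
            rates = net.forward(X[idx], train=True, rng=rng)
            loss, grad = mse_loss(rates, targets[idx])
            net.backward(grad)
            opt.step(net.params())
            losses.append(loss)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if Xv is not None:
            rates_v = _forward_in_batches(net, Xv)
            entry["val_loss"] = mse_loss(rates_v, one_hot_targets(yv))[0]
            pred = (rates_v[:, 1] > rates_v[:, 0]).astype(int)
            entry["val_acc"] = float(np.mean(pred == yv))
        history.append(entry)
        if Xv is not None:
            acc = entry["val_acc"]
            if acc > best_acc:
                best_acc, since_best = acc, 0
            else:
                since_best += 1
            if cfg.stop_acc is not None and acc >= cfg.stop_acc:
                break
            if cfg.patience is not None and since_best > cfg.patience:
                break
    return history


@dataclasses.dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValidationError("label vectors differ in length")
    return ConfusionCounts(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        TN=int(np.sum((yt == 0) & (yp == 0))),
        FP=int(np.sum((yt == 0) & (yp == 1))),
        FN=int(np.sum((yt == 1) & (yp == 0))),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Threshold metrics from confusion counts (zero denominators -> 0)."""
    if c.n == 0:
        raise ValidationError("no samples")
    sn = _safe_div(c.TP, c.TP + c.FN)
    sp = _safe_div(c.TN, c.TN + c.FP)
    pre = _safe_div(c.TP, c.TP + c.FP)
    acc = (c.TP + c.TN) / c.n
    f1 = _safe_div(2 * pre * sn, pre + sn)
    mcc_den = math.sqrt(float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN))
    mcc = _safe_div(float(c.TP) * c.TN - float(c.FP) * c.FN, mcc_den)
    return {"Sn": sn, "Sp": sp, "Pre": pre, "Acc": acc, "F1": f1, "MCC": mcc}


def roc_pr_curves(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """(AUC, AUPRC) with positive-class firing rates as scores.

    AUC equals the pairwise rank statistic with ties counted 1/2; AUPRC is
    the step-interpolated area under the precision-recall curve.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("AUC requires both classes present")
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def evaluate(net: PromoterNet, records: Sequence[SequenceRecord]) -> dict:
    """Full metric report (threshold + ranking) on labelled records."""
    X, y = encode_batch(records)
    rates = _forward_in_batches(net, X)
    scores = rates[:, 1]
    pred = (rates[:, 1] > rates[:, 0]).astype(int)
    report = metrics(confusion(y, pred))
    try:
        auc, auprc = roc_pr_curves(scores, y)
        report["AUC"], report["AUPRC"] = auc, auprc
    except ValidationError:
        pass
    return report


def cross_validate(records: Sequence[SequenceRecord], model_builder,
                   cfg: TrainConfig, K: int = 5, seed: int = 0) -> dict:
    """K-fold cross-validation: per-fold metric reports plus arithmetic means.

    ``model_builder(fold_seed)`` must return a fresh network per fold.
    Stratified folds; the evaluation sets partition the dataset.
    """
    labels = [r.label for r in records]
    folds = kfold_split(labels, K, seed=seed, stratified=True)
    reports = []
    for k in range(K):
        held = set(folds.members(k).tolist())
        train_recs = [r for i, r in enumerate(records) if i not in held]
        val_recs = [records[i] for i in sorted(held)]
        net = model_builder(seed + k)
        fold_cfg = dataclasses.replace(cfg, seed=cfg.seed + k)
        fit(net, train_recs, val_recs, fold_cfg)
        reports.append(evaluate(net, val_recs))
    keys = reports[0].keys()
    means = {m: float(np.mean([r[m] for r in reports if m in r])) for m in keys}
    return {"folds": reports, "mean": means}
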