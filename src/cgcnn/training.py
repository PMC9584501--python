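"""Training loop (Adam, cross-entropy), 5-fold CV protocol and metrics.

The cross-validation splits on *source* trials (stratified by class) and
applies augmentation only inside each training fold, so no augmented copy
of a held-out trial ever reaches the optimizer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import autodiff as ad
from .config import AugmentParams, RunConfig, TrainParams, substream_seed
from .model import CGCNN, ModelConfig
from .montage import SpectralOperators
from .representations import (TrialSet, sliding_window_augment,
                              trialset_to_tensors, white_noise_augment)

__all__ = ["ConfusionMatrix", "CVResult", "kappa", "accuracy", "Adam",
           "fit", "train", "cross_validate", "apply_augmentation"]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """m x m count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @classmethod
    def from_labels(cls, y_true, y_pred, n_classes: int = None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        m = n_classes or int(max(y_true.max(), y_pred.max())) + 1
        counts = np.zeros((m, m), dtype=np.int64)
        np.add.at(counts, (y_true, y_pred), 1)
        return cls(counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def class_true_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def class_pred_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def accuracy(conf: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples, trace / n."""
    if conf.n == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(conf.counts)) / conf.n


def kappa(conf: ConfusionMatrix) -> float:
    """Cohen's kappa, (p_o - p_e) / (1 - p_e); returns 0 when p_e = 1."""
    n = conf.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = float(np.trace(conf.counts)) / n
    a = conf.class_true_totals.astype(float)
    b = conf.class_pred_totals.astype(float)
    p_e = float(a @ b) / (n * n)
    if p_e >= 1.0:
        warnings.warn("degenerate confusion matrix with p_e = 1; kappa set to 0")
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam on a flat parameter dict."""

    def __init__(self, params: dict, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def fit(model: CGCNN, x_st, x_ss, labels, params: TrainParams = None,
        seed: int = 0) -> list:
    """Minimize mean cross-entropy with Adam; returns per-epoch mean loss.

    Deterministic given ``seed`` (controls batch shuffling and the optional
    validation split for early stopping).
    """
    params = params or TrainParams()
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain at least two classes")
    n = len(labels)
    rng = np.random.default_rng(seed)

    val_idx = np.array([], dtype=int)
    train_idx = np.arange(n)
    if params.early_stopping and params.val_fraction > 0:
        perm = rng.permutation(n)
        n_val = max(1, int(round(params.val_fraction * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]

    def take(a, idx):
        return None if a is None else a[idx]

    opt = Adam(model.params, lr=params.lr)
    losses = []
    best_val, best_params, wait = np.inf, None, 0
    for _ in range(params.epochs):
        order = rng.permutation(train_idx)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), params.batch_size):
            idx = order[start:start + params.batch_size]
            logits = model.forward_logits(take(x_st, idx), take(x_ss, idx))
            loss = ad.softmax_cross_entropy(logits, labels[idx])
            loss.backward()
            grads = {k: t.grad for k, t in model._tensors.items()}
            opt.step(grads)
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
        if len(val_idx):
            logits = model.forward_logits(take(x_st, val_idx), take(x_ss, val_idx))
            val_loss = float(ad.softmax_cross_entropy(logits, labels[val_idx]).data)
            if val_loss < best_val - 1e-6:
                best_val, wait = val_loss, 0
                best_params = {k: v.copy() for k, v in model.params.items()}
            else:
                wait += 1
                if wait >= params.patience:
                    break
    if best_params is not None:
        model.params.update(best_params)
    return losses


def train(model: CGCNN, train_set: TrialSet, config: RunConfig,
          seed: int = None) -> list:
    """Prepare representations for ``train_set`` and fit the model."""
    seed = config.seed if seed is None else seed
    x_st, x_ss = trialset_to_tensors(train_set, config.representation)
    cfg = model.config
    return fit(model,
               x_st if cfg.use_st_branch else None,
               x_ss if cfg.use_ss_branch else None,
               train_set.labels, config.train,
               seed=substream_seed(seed, "fit"))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def apply_augmentation(trials: TrialSet, params: AugmentParams, seed: int = 0) -> TrialSet:
    if params.scheme == "none":
        return trials
    if params.scheme == "sliding_window":
        return sliding_window_augment(trials, params.window_s, params.step_s)
    return white_noise_augment(trials, params.snr_db, params.copies, seed=seed)


@dataclass
class CVResult:
    per_fold_accuracy: list
    per_fold_kappa: list
    fold_assignment: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    @property
    def mean_kappa(self) -> float:
        return float(np.mean(self.per_fold_kappa))

    def to_dict(self) -> dict:
        return {
            "per_fold_accuracy": [float(a) for a in self.per_fold_accuracy],
            "per_fold_kappa": [float(k) for k in self.per_fold_kappa],
            "mean_accuracy": self.mean_accuracy,
            "mean_kappa": self.mean_kappa,
            "fold_assignment": {str(k): int(v) for k, v in self.fold_assignment.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CVResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["per_fold_accuracy"], d["per_fold_kappa"],
                   {int(k): v for k, v in d["fold_assignment"].items()})


def make_model_config(config: RunConfig, n_nodes: int, n_classes: int,
                      seed: int = None) -> ModelConfig:
    m = config.model
    return ModelConfig(
        n_nodes=n_nodes, n_classes=n_classes,
        T=config.representation.T_target, F=config.representation.F_target,
        cheb_order=m.cheb_order, c1=m.c1, c2=m.c2, kernel_t=m.kernel_t,
        use_st_branch=m.use_st_branch, use_ss_branch=m.use_ss_branch,
        use_attention=m.use_attention,
        use_global_aggregation=m.use_global_aggregation,
        use_shortcut=m.use_shortcut, attention_norm=m.attention_norm,
        seed=config.seed if seed is None else seed,
    )


def cross_validate(dataset: TrialSet, ops: SpectralOperators, config: RunConfig,
                   seed: int = None) -> CVResult:
    """Stratified k-fold CV on source trials; augmentation train-fold only.

    Every fold trains a fresh model from scratch and is evaluated on the
    untouched held-out source trials.  Deterministic given ``seed``.
    """
    seed = config.seed if seed is None else seed
    labels = dataset.labels
    n_classes = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=n_classes)
    if counts.min() < config.n_folds:
        raise ValueError(
            f"need at least {config.n_folds} trials per class for "
            f"{config.n_folds}-fold stratified CV; class counts are {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=substream_seed(seed, "cv-split") % (2 ** 32))
    accs, kappas, assignment = [], [], {}
    for fold, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        for tid in dataset.trial_ids[te_idx]:
            assignment[int(tid)] = fold
        fold_seed = substream_seed(seed, f"fold-{fold}")
        train_set = apply_augmentation(dataset.subset(tr_idx), config.augment,
                                       seed=substream_seed(fold_seed, "augment"))
        # leakage audit: no held-out source id may reach the training fold
        held = set(dataset.trial_ids[te_idx].tolist())
        if held & set(train_set.trial_ids.tolist()):
            raise AssertionError("augmented training fold contains held-out trials")
        mcfg = make_model_config(config, dataset.n_electrodes, n_classes,
                                 seed=substream_seed(fold_seed, "init"))
        model = CGCNN(mcfg, ops)
        x_st, x_ss = trialset_to_tensors(train_set, config.representation)
        fit(model,
            x_st if mcfg.use_st_branch else None,
            x_ss if mcfg.use_ss_branch else None,
            train_set.labels, config.train,
            seed=substream_seed(fold_seed, "fit"))
        t_st, t_ss = trialset_to_tensors(dataset.subset(te_idx), config.representation)
        preds = model.predict(t_st if mcfg.use_st_branch else None,
                              t_ss if mcfg.use_ss_branch else None)
        conf = ConfusionMatrix.from_labels(labels[te_idx], preds, n_classes)
        accs.append(accuracy(conf))
        kappas.append(kappa(conf))
    return CVResult(accs, kappas, assignment)
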