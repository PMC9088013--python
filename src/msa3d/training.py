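"""Joint end-to-end training of the two-branch model.

Optimisation follows the published protocol: SGD, learning rate 0.01,
weight decay 0.02, batch size 12, early stopping on a stratified 10%
validation split with the best-validation weights restored.

The training objective is the macro-averaged cross-entropy

    L = -(1/C) * sum_c (1/N) * sum_i [y_i = c] * log p_i,c

which collapses algebraically to (standard cross-entropy) / C for every
batch — the macro form rescales but does not re-weight classes, because
the inner average is over all N samples rather than the per-class count.
Both variants are available (``loss_variant``); they differ only by that
constant factor and so share gradients up to scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .metrics import MetricsReport, evaluate as _evaluate_probs
from .model import MSA3D, FusionConfig
from .nn import SGD, Tensor, log_softmax
from .phantoms import SyntheticDataset

__all__ = ["TrainConfig", "TrainHistory", "macro_ce_loss", "standard_ce_loss",
           "train", "evaluate_model"]

_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (defaults follow the published protocol)."""

    batch_size: int = 12
    learning_rate: float = 0.01
    weight_decay: float = 0.02
    momentum: float = 0.0
    max_epochs: int = 50
    patience: int = 10          # early-stopping patience on validation loss
    val_fraction: float = 0.10  # stratified split from the training set
    seed: int = 0

    def __post_init__(self):
        for name in ("batch_size", "learning_rate", "weight_decay",
                     "max_epochs", "patience"):
            if getattr(self, name) <= 0 and name != "weight_decay":
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False


# ---------------------------------------------------------------------------
# losses (array level, float64 — exact closed forms)
# ---------------------------------------------------------------------------

def macro_ce_loss(probs: np.ndarray, labels: np.ndarray, n_classes: int) -> float:
    """Macro-averaged cross-entropy over predicted class probabilities.

    Zero exactly when every sample puts probability 1 on its true class.
    True-class probabilities of 0 are clamped at 1e-12 with a warning.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    if probs.shape != (n, n_classes):
        raise ValueError(f"probs must be ({n}, {n_classes}), got {probs.shape}")
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels out of range")
    total = 0.0
    for c in range(n_classes):
        p = probs[labels == c, c]
        if (p <= 0).any():
            warnings.warn("zero probability on a true class; clamping at 1e-12",
                          RuntimeWarning, stacklevel=2)
            p = np.clip(p, _EPS, None)
        total += np.log(p).sum() / n
    return float(-total / n_classes)


def standard_ce_loss(probs: np.ndarray, labels: np.ndarray, n_classes: int) -> float:
    """Plain mean negative log-likelihood (= macro form times n_classes)."""
    return macro_ce_loss(probs, labels, n_classes) * n_classes


def _loss_from_logits(logits: Tensor, labels: np.ndarray, n_classes: int,
                      variant: str) -> Tensor:
    """Differentiable loss used in the training loop."""
    logp = log_softmax(logits, axis=1)
    onehot = np.zeros((len(labels), n_classes), dtype=logits.dtype)
    onehot[np.arange(len(labels)), labels] = 1.0
    nll = -(logp * Tensor(onehot)).sum() * (1.0 / len(labels))
    if variant == "macro_eq5":
        nll = nll * (1.0 / n_classes)
    return nll


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _stratified_split(labels: np.ndarray, val_fraction: float,
                      rng: np.random.Generator):
    train_idx, val_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(val_fraction * len(idx))))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def _epoch_loss(model: MSA3D, x: np.ndarray, y: np.ndarray, batch: int,
                variant: str) -> float:
    """Mean per-sample loss over a dataset in inference mode."""
    from .nn import no_grad
    model.eval()
    total = 0.0
    with no_grad():
        for start in range(0, len(y), batch):
            xb = Tensor(x[start:start + batch])
            logits = model(xb)
            loss = _loss_from_logits(logits, y[start:start + batch],
                                     model.fusion_cfg.n_classes, variant)
            total += float(loss.data) * len(xb.data)
    return total / len(y)


def train(dataset: SyntheticDataset | tuple[np.ndarray, np.ndarray],
          model: MSA3D | None = None,
          fusion_cfg: FusionConfig | None = None,
          train_cfg: TrainConfig = TrainConfig(),
          verbose: bool = False) -> tuple[MSA3D, TrainHistory]:
    """Jointly optimise slice subnets, attention gates, 3D branch and head.

    ``dataset`` is a :class:`SyntheticDataset` or an ``(X, y)`` pair with X
    of shape (N, D, H, W).  A fresh model is built from ``fusion_cfg`` when
    none is passed.  Fully reproducible given ``train_cfg.seed``.
    """
    if isinstance(dataset, tuple):
        x, y = dataset
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y).astype(int)
    else:
        x, y = dataset.as_arrays()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    if any((y == c).sum() < 2 for c in classes):
        raise ValueError("need at least 2 samples per class")

    rng = np.random.default_rng(train_cfg.seed)
    if model is None:
        from .mvssn import SliceNetConfig
        from .s3dcnn import SubjectNetConfig
        model = MSA3D(x.shape[1:],
                      slice_cfg=SliceNetConfig(weight_sharing="per_view"),
                      subject_cfg=SubjectNetConfig.desk_scale(),
                      fusion_cfg=fusion_cfg or FusionConfig(),
                      seed=int(rng.integers(2**31 - 1)))
    variant = model.fusion_cfg.loss_variant
    n_classes = model.fusion_cfg.n_classes

    tr_idx, va_idx = _stratified_split(y, train_cfg.val_fraction, rng)
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_va, y_va = x[va_idx], y[va_idx]

    opt = SGD(model.parameters(), lr=train_cfg.learning_rate,
              weight_decay=train_cfg.weight_decay, momentum=train_cfg.momentum)
    history = TrainHistory()
    best_val = np.inf
    best_state: dict | None = None
    since_best = 0

    for epoch in range(train_cfg.max_epochs):
        model.train()
        order = rng.permutation(len(y_tr))
        running = 0.0
        for start in range(0, len(order), train_cfg.batch_size):
            sel = order[start:start + train_cfg.batch_size]
            if len(sel) < 2:
                continue  # batch-norm needs more than one sample
            opt.zero_grad()
            logits = model(Tensor(x_tr[sel]))
            loss = _loss_from_logits(logits, y_tr[sel], n_classes, variant)
            loss.backward()
            opt.step()
            running += float(loss.data) * len(sel)
        history.train_loss.append(running / len(y_tr))
        val = _epoch_loss(model, x_va, y_va, train_cfg.batch_size, variant)
        history.val_loss.append(val)
        if verbose:
            print(f"epoch {epoch:3d}  train {history.train_loss[-1]:.4f}  "
                  f"val {val:.4f}")
        if val < best_val - 1e-9:
            best_val = val
            best_state = model.state_dict()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= train_cfg.patience:
                history.stopped_early = True
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def evaluate_model(model: MSA3D, dataset, batch_size: int = 12) -> MetricsReport:
    """Compute ACC/SEN/SPE/AUC/F1 of a trained model on labelled volumes."""
    if isinstance(dataset, tuple):
        x, y = dataset
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y).astype(int)
    else:
        x, y = dataset.as_arrays()
    probs = np.concatenate([model.predict_proba(x[s:s + batch_size])
                            for s in range(0, len(y), batch_size)])
    return _evaluate_probs(y, probs[:, 1])
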