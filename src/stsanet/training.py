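"""Training protocols: two-phase early stopping, 10-fold CV, transfer.

The optimization recipe is fixed by design: negative-log-likelihood loss
on log-softmax outputs, Adam, Xavier initialization, batch size 32, the
training set split 80/20 into train/validation.

Two-phase early stopping:

* **Phase 1** trains on the 80% split while tracking validation accuracy.
  When the accuracy has not improved for ``patience`` epochs, training
  stops and parameters are restored to the best-validation state.  The
  training loss recorded at that best epoch becomes the phase-2 stopping
  threshold.
* **Phase 2** continues on train+validation combined and ends when the
  loss on the former validation subset drops to the phase-1 training-loss
  threshold (or at ``phase2_max_epochs``, flagged in the result).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .evaluation import accuracy
from .model import STSANet, nll_loss

logger = logging.getLogger("stsanet")

__all__ = [
    "TrainConfig",
    "FitResult",
    "Adam",
    "split_train_valid",
    "kfold_indices",
    "fit_two_phase",
    "crossval_10fold",
    "transfer_pretrain_finetune",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    ``lr`` defaults to 1e-4 (the 22-channel benchmark setting; use 1e-3
    for larger/cleaner data).  ``patience`` counts phase-1 epochs without
    a new best validation accuracy.
    """

    lr: float = 1e-4
    batch_size: int = 32
    valid_fraction: float = 0.2
    patience: int = 80
    max_epochs: int = 800
    phase2_max_epochs: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.valid_fraction < 1):
            raise ValueError("valid_fraction must lie strictly between 0 and 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class FitResult:
    """Trained parameters plus the training history and stopping bookkeeping."""

    state: dict[str, np.ndarray]
    history: list[dict[str, float]]
    phase1_end_epoch: int
    phase1_best_epoch: int
    phase1_train_loss: float
    phase2_epochs: int = 0
    phase2_hit_cap: bool = False
    best_valid_acc: float = 0.0
    pretrain: "FitResult | None" = None


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k in self.m:
            g = np.asarray(grads[k], dtype=np.float64)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            params[k] = (params[k].astype(np.float64) - update).astype(params[k].dtype)


def split_train_valid(
    X: np.ndarray,
    y: np.ndarray,
    fraction: float = 0.2,
    seed: int = 0,
):
    """Stratified random split into (train, valid) = ((Xtr, ytr), (Xva, yva)).

    Stratification keeps per-class proportions within one trial of the
    requested fraction.  Each class must contribute at least 2 trials.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie strictly between 0 and 1")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    for c, n in zip(classes, counts):
        if n < 2:
            raise ValueError(f"class {c} has fewer than 2 epochs; cannot stratify")
    idx_tr, idx_va = train_test_split(
        np.arange(len(y)), test_size=fraction, random_state=seed, stratify=y
    )
    return (X[idx_tr], y[idx_tr]), (X[idx_va], y[idx_va])


def kfold_indices(n: int, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Seeded shuffle split into k near-equal folds, larger folds first.

    For n = 576 and k = 10 this yields six folds of 58 and four of 57,
    so each run trains on 518 trials and tests on 58 (or 57).
    """
    if n < k:
        raise ValueError(f"need at least {k} trials for {k}-fold CV, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    sizes = [base + 1] * extra + [base] * (k - extra)
    folds, start = [], 0
    for s in sizes:
        folds.append(np.sort(perm[start : start + s]))
        start += s
    return folds


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _run_epoch(model: STSANet, opt: Adam, X, y, batch_size, rng) -> float:
    """One pass of minibatch SGD; returns the mean training loss."""
    n = X.shape[0]
    order = rng.permutation(n)
    total, seen = 0.0, 0
    for i in range(0, n, batch_size):
        idx = order[i : i + batch_size]
        logp, cache = model.forward(X[idx], train=True, rng=rng, want_cache=True)
        loss, dlogp = nll_loss(logp, y[idx])
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss {loss} at step {opt.t}; aborting"
            )
        grads = model.backward(dlogp, cache)
        opt.step(model.params, {k: grads[k] for k in model.params})
        total += loss * len(idx)
        seen += len(idx)
    return total / seen


def _eval_loss_acc(model: STSANet, X, y, batch_size=64) -> tuple[float, float]:
    logp = model.predict_logp(X, batch_size=batch_size)
    loss, _ = nll_loss(logp, y)
    acc = accuracy(y, np.argmax(logp, axis=1))
    return loss, acc


def fit_two_phase(
    model: STSANet,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    eval_set: tuple[np.ndarray, np.ndarray] | None = None,
) -> FitResult:
    """Train with the two-phase early-stopping schedule.

    ``eval_set`` is an optional held-out set whose accuracy is logged per
    epoch (never used for any training decision).
    """
    rng = np.random.default_rng(config.seed)
    if not model.params:
        model.init_parameters(config.seed)
    (Xtr, ytr), (Xva, yva) = split_train_valid(
        X, y, config.valid_fraction, config.seed
    )
    opt = Adam(model.params, config.lr)
    history: list[dict[str, float]] = []

    best_acc = -np.inf
    best_state = model.state_copy()
    best_epoch = 0
    best_train_loss = np.inf
    since_improve = 0

    for epoch in range(1, config.max_epochs + 1):
        train_loss = _run_epoch(model, opt, Xtr, ytr, config.batch_size, rng)
        valid_loss, valid_acc = _eval_loss_acc(model, Xva, yva)
        rec = {
            "phase": 1, "epoch": epoch, "train_loss": train_loss,
            "valid_loss": valid_loss, "valid_acc": valid_acc,
        }
        if eval_set is not None:
            _, test_acc = _eval_loss_acc(model, *eval_set)
            rec["test_acc"] = test_acc
        history.append(rec)
        if valid_acc > best_acc:
            best_acc = valid_acc
            best_state = model.state_copy()
            best_epoch = epoch
            best_train_loss = train_loss
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break
        logger.debug("phase1 epoch %d: train %.4f valid %.4f acc %.2f",
                     epoch, train_loss, valid_loss, valid_acc)

    model.load_state(best_state)
    phase1_end = len(history)

    # phase 2: train on everything, stop when former-validation loss
    # reaches the phase-1 training loss of the restored state
    opt = Adam(model.params, config.lr)
    hit_cap = False
    phase2_epochs = 0
    for epoch in range(1, config.phase2_max_epochs + 1):
        train_loss = _run_epoch(model, opt, X, y, config.batch_size, rng)
        valid_loss, valid_acc = _eval_loss_acc(model, Xva, yva)
        rec = {
            "phase": 2, "epoch": epoch, "train_loss": train_loss,
            "valid_loss": valid_loss, "valid_acc": valid_acc,
        }
        if eval_set is not None:
            _, test_acc = _eval_loss_acc(model, *eval_set)
            rec["test_acc"] = test_acc
        history.append(rec)
        phase2_epochs = epoch
        if valid_loss <= best_train_loss:
            break
    else:
        hit_cap = config.phase2_max_epochs > 0
    if hit_cap:
        logger.warning("phase 2 hit the %d-epoch cap without reaching the "
                       "phase-1 loss threshold", config.phase2_max_epochs)

    model.fitted = True
    return FitResult(
        state=model.state_copy(),
        history=history,
        phase1_end_epoch=phase1_end,
        phase1_best_epoch=best_epoch,
        phase1_train_loss=float(best_train_loss),
        phase2_epochs=phase2_epochs,
        phase2_hit_cap=hit_cap,
        best_valid_acc=float(best_acc),
    )


def crossval_10fold(
    X: np.ndarray,
    y: np.ndarray,
    model_factory,
    config: TrainConfig,
    k: int = 10,
) -> dict:
    """k-fold cross-validation over a pooled trial set.

    Each run trains (two-phase schedule) on k-1 folds and tests on the
    held-out fold.  Both the best per-epoch test accuracy and the final
    restored-model accuracy are reported; the headline mean follows the
    best-value convention, with the final-model mean alongside.
    """
    folds = kfold_indices(len(y), k, config.seed)
    best_accs, final_accs = [], []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        model = model_factory()
        model.init_parameters(config.seed + i)
        res = fit_two_phase(
            model, X[train_idx], y[train_idx], config,
            eval_set=(X[test_idx], y[test_idx]),
        )
        final_acc = accuracy(y[test_idx], model.predict(X[test_idx]))
        epoch_accs = [r["test_acc"] for r in res.history if "test_acc" in r]
        best_acc = max(epoch_accs + [final_acc])
        best_accs.append(best_acc)
        final_accs.append(final_acc)
        logger.info("fold %d/%d: best %.2f%% final %.2f%%", i + 1, k, best_acc, final_acc)
    return {
        "fold_best_acc": best_accs,
        "fold_final_acc": final_accs,
        "mean_best_acc": float(np.mean(best_accs)),
        "mean_final_acc": float(np.mean(final_accs)),
        "fold_sizes": [len(f) for f in folds],
    }


def transfer_pretrain_finetune(
    target_subject: str,
    subjects: dict[str, tuple[np.ndarray, np.ndarray]],
    model_factory,
    config: TrainConfig,
) -> FitResult:
    """Inter-subject transfer: pretrain on everyone else, fine-tune on target.

    Phase A trains one model on the concatenated training data of all
    non-target subjects; phase B starts from those weights (no layers
    frozen) and runs the two-phase schedule on the target's data.  The
    returned result is the fine-tuning fit, with the pretraining fit
    attached as ``.pretrain``.
    """
    if target_subject not in subjects:
        raise KeyError(f"target subject {target_subject!r} not in the pool")
    if len(subjects) < 2:
        raise ValueError("transfer needs at least 2 subjects")
    Xp = np.concatenate(
        [subjects[s][0] for s in subjects if s != target_subject], axis=0
    )
    yp = np.concatenate(
        [subjects[s][1] for s in subjects if s != target_subject], axis=0
    )
    model = model_factory()
    model.init_parameters(config.seed)
    pre = fit_two_phase(model, Xp, yp, config)

    Xt, yt = subjects[target_subject]
    fine = fit_two_phase(model, Xt, yt, config)  # starts from pretrained weights
    fine.pretrain = pre
    return fine
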