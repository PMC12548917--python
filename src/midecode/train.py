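"""Loss, optimization loop with early stopping, and experiment drivers.

The loss is the mean cross-entropy of the fused pre-softmax logits. The
optimizer is Adam (lr 1e-3, beta1 0.9, beta2 0.99, weight decay 1e-3) with
max-norm constraints re-projected after every step. Early stopping halts
training once validation loss has not improved by more than `min_delta`
for `patience` consecutive evaluations (one per epoch) and restores the
best-validation weights.
"""

from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

from . import nn
from .data import (
    EEGEpochSet,
    concat_epochs,
    make_loso_folds,
    make_within_subject_folds,
    zscore_apply,
    zscore_fit,
)
from .errors import ConfigurationError, InsufficientDataError, LabelError
from .metrics import EvalReport, confusion_matrix
from .model import ABLATABLE_BLOCKS, ModelConfig, MultiScaleAttentionTCN
from .nn import Tensor


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.99
    weight_decay: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 300  # validation evaluations without improvement
    min_delta: float = 1e-4
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ConfigurationError("beta1/beta2 must lie in [0, 1)")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")


@dataclass
class TrainHistory:
    step_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    val_accuracies: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    stopped_epoch: int = -1


def cross_entropy_loss(logits, labels) -> Tensor:
    """Mean cross-entropy of pre-softmax logits: (1/M) sum_m -log softmax_m[y_m]."""
    if not isinstance(logits, Tensor):
        logits = Tensor(np.asarray(logits, dtype=np.float64))
    labels = np.asarray(labels, dtype=np.int64)
    m, nc = logits.shape
    if labels.size and (labels.min() < 0 or labels.max() >= nc):
        raise LabelError(f"labels outside [0, {nc})")
    onehot = np.zeros((m, nc), dtype=logits.data.dtype)
    onehot[np.arange(m), labels] = 1.0
    lse = nn.logsumexp(logits, axis=1).reshape(m)
    chosen = (logits * Tensor(onehot)).sum(axis=1)
    return (lse - chosen).mean()


def _batched_logits(model, data: np.ndarray, batch: int = 256) -> np.ndarray:
    outs = []
    with nn.no_grad():
        for i in range(0, len(data), batch):
            outs.append(model(data[i : i + batch]).data)
    return np.concatenate(outs, axis=0)


def evaluate(model, epochs: EEGEpochSet):
    """Eval-mode predictions and mean loss on an epoch set."""
    was_training = model.training
    model.eval()
    try:
        logits = _batched_logits(model, epochs.data)
    finally:
        model.train(was_training)
    loss = float(cross_entropy_loss(logits, epochs.labels).data)
    preds = logits.argmax(axis=1)
    acc = float((preds == epochs.labels).mean())
    return preds, loss, acc


def train_model(
    model: MultiScaleAttentionTCN,
    train: EEGEpochSet,
    val: EEGEpochSet,
    tcfg: TrainConfig,
):
    """Adam training with per-epoch validation and early stopping.

    Returns (model restored to its best-validation weights, TrainHistory).
    """
    if train.n_trials == 0 or val.n_trials == 0:
        raise InsufficientDataError("empty training or validation set")
    constraints = model.max_norm_constraints()
    opt = nn.Adam(
        model.parameters(),
        lr=tcfg.learning_rate,
        beta1=tcfg.beta1,
        beta2=tcfg.beta2,
        weight_decay=tcfg.weight_decay,
        constraints=constraints,
    )
    rng = np.random.default_rng(tcfg.seed)
    hist = TrainHistory()
    best_state = None
    since_improve = 0

    for epoch in range(tcfg.max_epochs):
        model.train()
        order = rng.permutation(train.n_trials)
        for start in range(0, train.n_trials, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            logits = model(train.data[idx])
            loss = cross_entropy_loss(logits, train.labels[idx])
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"non-finite training loss at step {len(hist.step_losses)}"
                )
            hist.step_losses.append(loss_val)
            opt.zero_grad()
            loss.backward()
            opt.step()

        _, val_loss, val_acc = evaluate(model, val)
        hist.val_losses.append(val_loss)
        hist.val_accuracies.append(val_acc)
        if hist.best_val_loss - val_loss > tcfg.min_delta:
            hist.best_val_loss = val_loss
            hist.best_epoch = epoch
            best_state = copy.deepcopy(model.state_dict())
            since_improve = 0
        else:
            since_improve += 1
        if since_improve >= tcfg.patience:
            break
    hist.stopped_epoch = len(hist.val_losses) - 1

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, hist


def _stratified_split(labels: np.ndarray, fraction: float, seed: int):
    sss = StratifiedShuffleSplit(n_splits=1, test_size=fraction, random_state=seed)
    idx = np.arange(len(labels))
    keep, held = next(sss.split(idx, labels))
    return idx[keep], idx[held]


def _fit_fold(mcfg, tcfg, train_set, val_set, test_set, seed, removed_block=None,
              denominator="sd"):
    stats = zscore_fit(train_set)
    train_n = zscore_apply(train_set, stats, denominator)
    val_n = zscore_apply(val_set, stats, denominator)
    test_n = zscore_apply(test_set, stats, denominator)
    model = MultiScaleAttentionTCN(mcfg, seed=seed, removed_block=removed_block)
    fold_tcfg = replace(tcfg, seed=seed)
    model, hist = train_model(model, train_n, val_n, fold_tcfg)
    preds, _, acc = evaluate(model, test_n)
    cm = confusion_matrix(test_n.labels, preds, mcfg.Nc)
    return acc, cm, model, hist


def run_within_subject(
    cohort: list[EEGEpochSet],
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    k: int = 5,
    removed_block: str | None = None,
    denominator: str = "sd",
) -> EvalReport:
    """Per-subject stratified k-fold protocol: train/early-stop/test each fold,
    per-subject accuracy = unweighted mean over folds."""
    subject_ids, accuracies, confusions, seeds = [], [], [], []
    for subject in cohort:
        # seed depends on the subject's identity, not its position in the
        # cohort list, so per-subject results are order-independent
        sid_hash = zlib.crc32(str(subject.subject_id).encode()) % 9973
        plan = make_within_subject_folds(subject, k=k, seed=tcfg.seed)
        fold_accs, cm_total = [], np.zeros((mcfg.Nc, mcfg.Nc), dtype=np.int64)
        for f, fold in enumerate(plan.folds):
            seed = (tcfg.seed * 10007 + sid_hash * 101 + f) % (2**31)
            acc, cm, _, _ = _fit_fold(
                mcfg, tcfg,
                subject.subset(fold.train), subject.subset(fold.val),
                subject.subset(fold.test), seed, removed_block, denominator,
            )
            fold_accs.append(acc)
            cm_total += cm
            seeds.append(seed)
        subject_ids.append(subject.subject_id)
        accuracies.append(float(np.mean(fold_accs)))
        confusions.append(cm_total)
    return EvalReport(
        protocol="within_subject", subject_ids=subject_ids, accuracies=accuracies,
        confusions=confusions, seeds=seeds, removed_block=removed_block,
    )


def run_cross_subject(
    cohort: list[EEGEpochSet],
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    val_fraction: float = 0.2,
    denominator: str = "sd",
) -> EvalReport:
    """Leave-one-subject-out protocol: one model per held-out subject, trained
    on the pooled remaining subjects with a stratified validation carve-out."""
    plan = make_loso_folds(cohort)
    subject_ids, accuracies, confusions, seeds = [], [], [], []
    for f, fold in enumerate(plan.folds):
        pooled = concat_epochs([cohort[int(j)] for j in fold.train])
        tr_idx, val_idx = _stratified_split(
            pooled.labels, val_fraction, tcfg.seed * 613 + f
        )
        test_subject = cohort[int(fold.test[0])]
        seed = (tcfg.seed * 10007 + f * 101) % (2**31)
        acc, cm, _, _ = _fit_fold(
            mcfg, tcfg,
            pooled.subset(tr_idx), pooled.subset(val_idx), test_subject,
            seed, None, denominator,
        )
        subject_ids.append(test_subject.subject_id)
        accuracies.append(acc)
        confusions.append(cm)
        seeds.append(seed)
    return EvalReport(
        protocol="loso", subject_ids=subject_ids, accuracies=accuracies,
        confusions=confusions, seeds=seeds,
    )


def run_ablation(
    cohort: list[EEGEpochSet],
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    removed_block: str,
    k: int = 5,
) -> EvalReport:
    """Within-subject protocol with one architecture block switched off."""
    if removed_block not in ABLATABLE_BLOCKS and removed_block != "none":
        raise ConfigurationError(
            f"unknown ablation block {removed_block!r}; choose from "
            f"{ABLATABLE_BLOCKS + ('none',)}"
        )
    block = None if removed_block == "none" else removed_block
    report = run_within_subject(cohort, mcfg, tcfg, k=k, removed_block=block)
    report.removed_block = removed_block
    return report
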