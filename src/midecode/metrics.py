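"""Evaluation metrics, reports and interpretability exports.

Accuracy is the multiclass trace/total of the confusion matrix and Cohen's
kappa the chance-corrected agreement (p_a - p_e) / (1 - p_e) with the
expected agreement p_e computed from the row/column marginals. Paired
method comparison uses the two-sided Wilcoxon signed-rank test (delegated
to scipy; its zero/tie policy is recorded on the result).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import EEGEpochSet
from .errors import LabelError, ShapeError


def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """Counts[i, j] = number of trials with true class i predicted as j."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ShapeError(f"label arrays differ in length: {t.shape} vs {p.shape}")
    for name, arr in (("true", t), ("predicted", p)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise LabelError(f"{name} labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def accuracy(cm: np.ndarray) -> float:
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def cohen_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement (p_a - p_e) / (1 - p_e)."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_a = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum() / total**2)
    if p_e >= 1.0:
        raise ValueError("expected agreement p_e = 1; kappa undefined")
    return float((p_a - p_e) / (1.0 - p_e))


def wilcoxon_compare(accuracies_a, accuracies_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-subject scores."""
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError(f"paired samples must match: {a.shape} vs {b.shape}")
    if a.size < 5:
        raise ValueError(f"need >= 5 paired subjects, got {a.size}")
    if np.all(a == b):
        warnings.warn("all paired differences are zero; reporting p = 1")
        return 1.0
    return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)


@dataclass
class EvalReport:
    """Per-subject accuracies plus summary statistics and confusion matrices."""

    protocol: str
    subject_ids: list
    accuracies: list
    confusions: list  # one Nc x Nc array per subject
    seeds: list = field(default_factory=list)
    removed_block: str | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.accuracies))

    @property
    def kappa_pooled(self) -> float:
        """Kappa of the confusion matrix pooled over subjects."""
        return cohen_kappa(np.sum(self.confusions, axis=0))

    @property
    def kappa_mean(self) -> float:
        """Mean of per-subject kappas."""
        return float(np.mean([cohen_kappa(cm) for cm in self.confusions]))

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"subject": sid, "accuracy": acc}
            for sid, acc in zip(self.subject_ids, self.accuracies)
        ]
        rows.append(
            {
                "subject": "Avg",
                "accuracy": self.mean_accuracy,
                "k_score": self.kappa_pooled,
                "std": self.std_accuracy,
            }
        )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "protocol": self.protocol,
                "removed_block": self.removed_block,
                "subjects": self.subject_ids,
                "accuracies": [float(a) for a in self.accuracies],
                "mean_accuracy": self.mean_accuracy,
                "std_accuracy": self.std_accuracy,
                "kappa_pooled": self.kappa_pooled,
                "kappa_mean": self.kappa_mean,
                "confusions": [np.asarray(c).tolist() for c in self.confusions],
                "seeds": self.seeds,
            },
            indent=2,
        )


def export_embeddings(model, epochs: EEGEpochSet):
    """Penultimate-layer feature vector per trial (the concatenated linear-head
    inputs, pre decision fusion) plus labels, for external 2-D projection."""
    emb = model.embeddings(epochs.data)
    if not np.all(np.isfinite(emb)):
        raise ValueError("non-finite embedding values")
    return emb, epochs.labels.copy()


def kernel_spectra(model, fs: float = 250.0) -> pd.DataFrame:
    """Magnitude spectra of the multi-branch first-layer (depthwise) kernels.

    Spectra are evaluated at the post-pooling sampling rate fs / pool_width,
    so kernels of length 8/16/32 samples span 0.25/0.5/1 s and their
    frequency resolutions stand in ratio 4:2:1.
    """
    fs_pool = fs / model.cfg.pool_width
    rows = []
    for b, conv in enumerate(model.msc.depthwise):
        w = conv.weight.data[:, 0, :]  # (F2, k)
        k = w.shape[1]
        freqs = np.fft.rfftfreq(k, d=1.0 / fs_pool)
        mags = np.abs(np.fft.rfft(w, axis=1))
        for idx in range(w.shape[0]):
            for f, mag in zip(freqs, mags[idx]):
                rows.append(
                    {
                        "branch": b,
                        "kernel_index": idx,
                        "kernel_length": k,
                        "frequency_hz": float(f),
                        "magnitude": float(mag),
                    }
                )
    return pd.DataFrame(rows)
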