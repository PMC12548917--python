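"""Epoch containers, Z-score normalization, split planning and I/O.

The exchange object throughout the package is :class:`EEGEpochSet`: a
labelled trial array of shape (n_trials, C, T) with sampling-rate and
channel metadata. Normalization statistics are always fit on training data
and re-applied unchanged to validation/test data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .errors import (
    DegenerateChannelError,
    FormatError,
    InsufficientDataError,
    LabelError,
    ShapeError,
)

logger = logging.getLogger(__name__)

MIN_SAMPLES = 64  # two width-8 pooling stages must leave >= 1 time step


@dataclass
class EEGEpochSet:
    """Labelled multichannel EEG epochs.

    data: (n_trials, C, T) array; labels: integer class per trial in
    [0, n_classes); fs: sampling rate in Hz.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = "S00"
    n_classes: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ShapeError(f"data must be (n_trials, C, T), got {self.data.shape}")
        n, c, t = self.data.shape
        if len(self.labels) != n:
            raise ShapeError(f"{len(self.labels)} labels for {n} trials")
        if c < 1 or t < MIN_SAMPLES:
            raise ShapeError(f"need C >= 1 and T >= {MIN_SAMPLES}, got C={c}, T={t}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("data contains NaN or Inf")
        if self.n_classes is None:
            self.n_classes = int(self.labels.max()) + 1 if n else 0
        if n and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise LabelError(
                f"labels must lie in [0, {self.n_classes}), found "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "EEGEpochSet":
        return EEGEpochSet(
            self.data[idx], self.labels[idx], self.fs,
            list(self.channel_names), self.subject_id, self.n_classes,
        )


def concat_epochs(sets: list[EEGEpochSet], subject_id: str = "pooled") -> EEGEpochSet:
    """Pool several subjects' epochs into one set (used by LOSO training)."""
    if not sets:
        raise InsufficientDataError("no epoch sets to concatenate")
    first = sets[0]
    return EEGEpochSet(
        np.concatenate([s.data for s in sets]),
        np.concatenate([s.labels for s in sets]),
        first.fs, list(first.channel_names), subject_id,
        max(s.n_classes for s in sets),
    )


# -- Z-score normalization -----------------------------------------------------


@dataclass
class NormalizationStats:
    """Per-channel mean and variance estimated from training data."""

    mean: np.ndarray
    variance: np.ndarray


def zscore_fit(train: EEGEpochSet) -> NormalizationStats:
    """Estimate per-channel mean/variance over all training trials and times."""
    if train.n_trials == 0:
        raise InsufficientDataError("cannot fit normalization on an empty set")
    x = train.data.astype(np.float64)
    mean = x.mean(axis=(0, 2))
    variance = x.var(axis=(0, 2))
    dead = np.flatnonzero(variance == 0)
    if dead.size:
        raise DegenerateChannelError(
            f"zero-variance channel(s) {dead.tolist()} cannot be standardized"
        )
    return NormalizationStats(mean=mean, variance=variance)


def zscore_apply(
    x: EEGEpochSet, stats: NormalizationStats, denominator: str = "sd"
) -> EEGEpochSet:
    """Standardize epochs with previously fit statistics.

    denominator="sd" divides by the standard deviation (conventional Z-score,
    the default); "variance" divides by the variance (the literal printed
    form of the normalization equation).
    """
    if stats.mean.shape[0] != x.n_channels:
        raise ShapeError(
            f"stats cover {stats.mean.shape[0]} channels, data has {x.n_channels}"
        )
    if denominator not in ("sd", "variance"):
        raise ValueError(f"denominator must be 'sd' or 'variance', got {denominator!r}")
    denom = np.sqrt(stats.variance) if denominator == "sd" else stats.variance
    data = (x.data - stats.mean[None, :, None]) / denom[None, :, None]
    return EEGEpochSet(
        data.astype(np.float32), x.labels, x.fs,
        list(x.channel_names), x.subject_id, x.n_classes,
    )


# -- Split planning ------------------------------------------------------------


@dataclass
class Fold:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


@dataclass
class SplitPlan:
    folds: list[Fold]
    scheme: str  # "within_subject_kfold" | "loso"
    n_items: int = 0  # trials (k-fold) or subjects (loso)

    def validate(self):
        covered = []
        for f in self.folds:
            parts = [set(f.train.tolist()), set(f.val.tolist()), set(f.test.tolist())]
            total = sum(len(p) for p in parts)
            if len(parts[0] | parts[1] | parts[2]) != total:
                raise ShapeError("train/val/test indices overlap within a fold")
            covered.extend(f.test.tolist())
        if sorted(covered) != list(range(self.n_items)):
            raise ShapeError("test sets do not partition the items exactly once")


def make_within_subject_folds(
    epochs: EEGEpochSet, k: int = 5, seed: int = 0, val_fraction: float = 0.2
) -> SplitPlan:
    """Stratified k-fold plan: test = held-out fold, validation carved from
    the remaining trials for early stopping, train = the rest."""
    if k < 2:
        raise InsufficientDataError(f"need k >= 2 folds, got {k}")
    counts = np.bincount(epochs.labels, minlength=epochs.n_classes)
    if counts.min() < k:
        raise InsufficientDataError(
            f"need >= {k} trials per class, minimum class count is {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (rest, test) in enumerate(skf.split(epochs.data[:, 0, 0], epochs.labels)):
        sss = StratifiedShuffleSplit(
            n_splits=1, test_size=val_fraction, random_state=seed * 1009 + i
        )
        tr_pos, val_pos = next(sss.split(rest, epochs.labels[rest]))
        folds.append(Fold(train=rest[tr_pos], val=rest[val_pos], test=test))
    plan = SplitPlan(folds=folds, scheme="within_subject_kfold", n_items=epochs.n_trials)
    plan.validate()
    return plan


def make_loso_folds(cohort: list[EEGEpochSet]) -> SplitPlan:
    """Leave-one-subject-out plan over subject indices: one fold per subject,
    test = that subject, train = all others (validation carved later from the
    pooled training subjects' trials)."""
    if len(cohort) < 2:
        raise InsufficientDataError("LOSO needs at least 2 subjects")
    ids = [s.subject_id for s in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate subject_id in cohort: {ids}")
    n = len(cohort)
    folds = [
        Fold(
            train=np.array([j for j in range(n) if j != i]),
            val=np.array([], dtype=int),
            test=np.array([i]),
        )
        for i in range(n)
    ]
    plan = SplitPlan(folds=folds, scheme="loso", n_items=n)
    plan.validate()
    return plan


# -- Fixture container ---------------------------------------------------------

_FIXTURE_FIELDS = ("data", "labels")
_FIXTURE_ATTRS = ("fs", "subject_id", "channel_names", "n_classes")


def write_fixture(path, epochs: EEGEpochSet) -> None:
    """Write an epoch set to a single HDF5 file (float32 data, int16 labels)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("labels", data=epochs.labels.astype(np.int16))
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["subject_id"] = str(epochs.subject_id)
        f.attrs["channel_names"] = [str(c) for c in epochs.channel_names]
        f.attrs["n_classes"] = int(epochs.n_classes)


def read_fixture(path) -> EEGEpochSet:
    with h5py.File(path, "r") as f:
        for name in _FIXTURE_FIELDS:
            if name not in f:
                raise FormatError(f"fixture missing dataset {name!r}")
        for name in _FIXTURE_ATTRS:
            if name not in f.attrs:
                raise FormatError(f"fixture missing attribute {name!r}")
        data = f["data"][...]
        labels = f["labels"][...].astype(np.int64)
        n_classes = int(f.attrs["n_classes"])
        if labels.size and labels.max() >= n_classes:
            raise LabelError(
                f"fixture labels reach {labels.max()} but header declares "
                f"n_classes={n_classes}"
            )
        return EEGEpochSet(
            data, labels, float(f.attrs["fs"]),
            [str(c) for c in f.attrs["channel_names"]],
            str(f.attrs["subject_id"]), n_classes,
        )


# -- GDF / raw-recording epoching ---------------------------------------------


def epochs_from_raw(
    raw, event_id: dict, epoch_window: tuple[float, float] = (0.0, 4.0),
    subject_id: str = "S00",
) -> EEGEpochSet:
    """Cut cue-relative epochs out of an mne Raw object.

    event_id maps annotation codes (e.g. "769") to integer class labels.
    EOG channels are dropped; trials whose window overruns the recording are
    skipped with a logged count.
    """
    import mne

    raw = raw.copy()
    eog = [ch for ch in raw.ch_names if "EOG" in ch.upper()]
    if eog:
        raw.drop_channels(eog)
    events, mapping = mne.events_from_annotations(raw, event_id=event_id, verbose=False)
    if events.shape[0] == 0:
        raise FormatError(f"no events matching codes {sorted(event_id)} found")
    fs = raw.info["sfreq"]
    w0, w1 = epoch_window
    n_samp = int(round((w1 - w0) * fs))
    sig = raw.get_data()
    trials, labels, skipped = [], [], 0
    for onset, _, code in events:
        start = onset + int(round(w0 * fs))
        stop = start + n_samp
        if start < 0 or stop > sig.shape[1]:
            skipped += 1
            continue
        trials.append(sig[:, start:stop])
        labels.append(code)
    if skipped:
        logger.warning("skipped %d trial(s) overrunning the recording", skipped)
    if not trials:
        raise InsufficientDataError("no complete epochs could be cut")
    # mne maps annotation codes to the caller's class labels; re-apply the
    # mapping defensively in case codes were renumbered
    remap = {v: event_id[k] for k, v in mapping.items()}
    labels = np.array([remap[v] for v in labels])
    return EEGEpochSet(
        np.stack(trials), labels, fs, list(raw.ch_names), subject_id,
        int(max(event_id.values())) + 1,
    )


def load_gdf_epochs(
    path, event_codes: dict, epoch_window: tuple[float, float] = (0.0, 4.0),
    subject_id: str | None = None,
) -> EEGEpochSet:
    """Load a GDF biosignal file and cut cue-relative MI epochs.

    event_codes maps GDF annotation codes to integer class labels, e.g.
    {"769": 0, "770": 1, "771": 2, "772": 3} for the four-class cue set.
    """
    import mne

    try:
        raw = mne.io.read_raw_gdf(str(path), preload=True, verbose=False)
    except Exception as exc:  # pragma: no cover - depends on external files
        raise OSError(f"cannot read GDF file {path}: {exc}") from exc
    sid = subject_id if subject_id is not None else str(path)
    return epochs_from_raw(raw, event_codes, epoch_window, sid)
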