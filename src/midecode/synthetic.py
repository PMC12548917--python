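"""Synthetic motor-imagery EEG generator.

Emulates the class structure that motor-imagery decoding relies on:
event-related desynchronization/synchronization (ERD/ERS), i.e. class-
dependent modulation of band-limited oscillatory power (mu ~10 Hz, beta
~20-26 Hz) on electrode subsets, on top of 1/f-shaped plus white background
noise, with spatial leakage between electrodes and per-subject channel
gains. Every trial draws from an independent counter-derived random stream,
so generation is deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import NearestCentroid

from .data import EEGEpochSet
from .errors import ConfigurationError, InsufficientDataError

#: fraction of each class signal leaking into every other electrode
LEAKAGE = 0.1
#: fraction of background power carried by the 1/f (pink) component
PINK_FRACTION = 0.6
#: base amplitude of a signature oscillation before class modulation
BASE_AMPLITUDE = 1.0
#: slow amplitude-envelope frequency in Hz
ENVELOPE_HZ = 1.0


@dataclass(frozen=True)
class ClassSignature:
    """Band-limited oscillation defining one class."""

    center_freq: float  # Hz
    bandwidth: float  # Hz
    channels: tuple  # electrode indices carrying the oscillation
    modulation_depth: float = 0.5  # in [0, 1]


@dataclass
class SyntheticSpec:
    """Study conditions for the simulator; defaults mirror the 22-channel,
    250 Hz, 4 s, four-class geometry of the standard MI benchmark."""

    trials_per_class: int
    class_signatures: list
    n_subjects: int = 9
    n_channels: int = 22
    fs: float = 250.0
    epoch_duration: float = 4.0
    n_classes: int = 4
    noise_sd: float = 1.0
    subject_scale_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        self.validate()

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_duration))

    def validate(self):
        if self.n_classes < 2:
            raise ConfigurationError(f"n_classes must be >= 2, got {self.n_classes}")
        if abs(self.fs * self.epoch_duration - round(self.fs * self.epoch_duration)) > 1e-9:
            raise ConfigurationError(
                f"fs * epoch_duration = {self.fs * self.epoch_duration} is not a whole "
                "number of samples (fields fs, epoch_duration)"
            )
        if self.trials_per_class < 1:
            raise ConfigurationError(
                f"trials_per_class must be >= 1, got {self.trials_per_class}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if len(self.class_signatures) != self.n_classes:
            raise ConfigurationError(
                f"class_signatures has {len(self.class_signatures)} entries for "
                f"{self.n_classes} classes"
            )
        for k, sig in enumerate(self.class_signatures):
            if not 0.0 <= sig.modulation_depth <= 1.0:
                raise ConfigurationError(
                    f"modulation_depth of class {k} is {sig.modulation_depth}, "
                    "must lie in [0, 1]"
                )
            if sig.center_freq >= self.fs / 2:
                raise ConfigurationError(
                    f"center_freq {sig.center_freq} Hz of class {k} exceeds the "
                    f"Nyquist frequency {self.fs / 2} Hz"
                )
            for ch in sig.channels:
                if not 0 <= ch < self.n_channels:
                    raise ConfigurationError(
                        f"channel index {ch} of class {k} outside [0, {self.n_channels})"
                    )


def default_signatures(
    n_classes: int = 4, n_channels: int = 22, modulation_depth: float = 0.5
) -> list:
    """Mu/beta signatures on disjoint electrode groups, one per class."""
    freqs = [10.0, 10.0, 22.0, 26.0, 14.0, 18.0]
    bands = [2.0, 2.0, 4.0, 4.0, 2.0, 4.0]
    if n_classes > len(freqs):
        raise ConfigurationError(f"no default signatures for {n_classes} classes")
    group = max(1, n_channels // (2 * n_classes))
    sigs = []
    for k in range(n_classes):
        start = (k * n_channels // n_classes) % n_channels
        channels = tuple(range(start, min(start + group, n_channels)))
        sigs.append(ClassSignature(freqs[k], bands[k], channels, modulation_depth))
    return sigs


def bci2a_like(
    trials_per_class: int = 18, modulation_depth: float = 0.5,
    noise_sd: float = 1.0, seed: int = 0, n_subjects: int = 9,
) -> SyntheticSpec:
    """Four-class, 22-channel, 250 Hz, 4 s preset."""
    return SyntheticSpec(
        trials_per_class=trials_per_class,
        class_signatures=default_signatures(4, 22, modulation_depth),
        n_subjects=n_subjects, n_channels=22, n_classes=4,
        noise_sd=noise_sd, seed=seed,
    )


def bci2b_like(
    trials_per_class: int = 18, modulation_depth: float = 0.5,
    noise_sd: float = 1.0, seed: int = 0, n_subjects: int = 9,
) -> SyntheticSpec:
    """Two-class, 3-channel preset (left/right hand over C3/Cz/C4-like sites)."""
    sigs = [
        ClassSignature(10.0, 2.0, (0,), modulation_depth),
        ClassSignature(10.0, 2.0, (2,), modulation_depth),
    ]
    return SyntheticSpec(
        trials_per_class=trials_per_class, class_signatures=sigs,
        n_subjects=n_subjects, n_channels=3, n_classes=2,
        noise_sd=noise_sd, seed=seed,
    )


def _pink_noise(rng: np.random.Generator, c: int, t: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise per channel."""
    spec = rng.standard_normal((c, t // 2 + 1)) + 1j * rng.standard_normal((c, t // 2 + 1))
    f = np.fft.rfftfreq(t)
    scale = 1.0 / np.sqrt(np.maximum(f, f[1]))
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=t)
    sd = x.std(axis=1, keepdims=True)
    return x / np.maximum(sd, 1e-12)


def _trial_rng(spec: SyntheticSpec, subject_index: int, trial_counter: int):
    return np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(subject_index, trial_counter))
    )


def _subject_rng(spec: SyntheticSpec, subject_index: int):
    return np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(subject_index,))
    )


def generate_epochs(spec: SyntheticSpec, subject_index: int) -> EEGEpochSet:
    """Generate one subject's balanced, shuffled set of labelled epochs.

    Class k trials carry the oscillation of signature k at amplitude
    (1 + d_k) x base and every other signature j at (1 - d_j) x base, so a
    depth of 0 erases all class information while a depth near 1 produces
    strongly separable band-power contrasts.
    """
    spec.validate()
    if not 0 <= subject_index < spec.n_subjects:
        raise ConfigurationError(
            f"subject_index {subject_index} outside [0, {spec.n_subjects})"
        )
    c, t = spec.n_channels, spec.n_samples
    tvec = np.arange(t) / spec.fs

    srng = _subject_rng(spec, subject_index)
    gains = np.exp(spec.subject_scale_sd * srng.standard_normal(c))
    mix_raw = srng.random((c, c))
    mix = (1.0 - LEAKAGE) * np.eye(c) + LEAKAGE * mix_raw / mix_raw.sum(1, keepdims=True)

    n_total = spec.trials_per_class * spec.n_classes
    data = np.empty((n_total, c, t), dtype=np.float32)
    labels = np.empty(n_total, dtype=np.int64)
    counter = 0
    for k in range(spec.n_classes):
        for _ in range(spec.trials_per_class):
            rng = _trial_rng(spec, subject_index, counter)
            bg = spec.noise_sd * (
                np.sqrt(PINK_FRACTION) * _pink_noise(rng, c, t)
                + np.sqrt(1.0 - PINK_FRACTION) * rng.standard_normal((c, t))
            )
            osc = np.zeros((c, t))
            for j, sig in enumerate(spec.class_signatures):
                d = sig.modulation_depth
                amp = BASE_AMPLITUDE * ((1.0 + d) if j == k else (1.0 - d))
                f0 = rng.uniform(
                    sig.center_freq - sig.bandwidth / 2,
                    sig.center_freq + sig.bandwidth / 2,
                )
                phase = rng.uniform(0, 2 * np.pi)
                env = 1.0 + 0.5 * np.sin(
                    2 * np.pi * ENVELOPE_HZ * tvec + rng.uniform(0, 2 * np.pi)
                )
                wave = amp * env * np.sin(2 * np.pi * f0 * tvec + phase)
                for ch in sig.channels:
                    osc[ch] += wave
            x = gains[:, None] * (mix @ (bg + osc))
            data[counter] = x.astype(np.float32)
            labels[counter] = k
            counter += 1

    order = srng.permutation(n_total)
    names = [f"CH{i:02d}" for i in range(c)]
    return EEGEpochSet(
        data[order], labels[order], spec.fs, names,
        subject_id=f"SYN{subject_index:02d}", n_classes=spec.n_classes,
    )


def band_power_features(epochs: EEGEpochSet, spec: SyntheticSpec) -> np.ndarray:
    """Log mean Welch power in each class-signature band on its channel set."""
    t = epochs.n_samples
    nperseg = min(256, t)
    freqs, psd = welch(epochs.data, fs=epochs.fs, nperseg=nperseg, axis=-1)
    feats = np.empty((epochs.n_trials, len(spec.class_signatures)))
    for j, sig in enumerate(spec.class_signatures):
        lo = sig.center_freq - sig.bandwidth / 2
        hi = sig.center_freq + sig.bandwidth / 2
        fmask = (freqs >= lo) & (freqs <= hi)
        chans = list(sig.channels)
        feats[:, j] = np.log(psd[:, chans][:, :, fmask].mean(axis=(1, 2)) + 1e-20)
    return feats


def separability_oracle(epochs: EEGEpochSet, spec: SyntheticSpec, k: int = 5) -> float:
    """5-fold CV accuracy of a band-power + nearest-centroid classifier.

    A deliberately simple reference decoder: if this cannot separate the
    classes, the synthetic data carries no learnable signal and network
    failures cannot be blamed on the architecture.
    """
    counts = np.bincount(epochs.labels, minlength=epochs.n_classes)
    if counts.min() < 2:
        raise InsufficientDataError(
            f"need >= 2 trials per class, minimum is {counts.min()}"
        )
    feats = band_power_features(epochs, spec)
    k = min(k, int(counts.min()))
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=0)
    scores = cross_val_score(NearestCentroid(), feats, epochs.labels, cv=cv)
    return float(scores.mean())
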