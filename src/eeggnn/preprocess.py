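"""Standardization pipeline: channel selection, resampling, bandpass
filtering, average referencing, epoching and per-epoch z-scoring.

Pipeline order is fixed:
``select -> resample -> bandpass -> average reference -> segment -> z-score``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import MissingChannelError, ValidationError
from .io import Annotation, EpochSet, Recording, normalize_channel_name

#: The 16-channel referential montage used throughout.
DEFAULT_CHANNELS = [
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
]


@dataclass
class PreprocessConfig:
    target_channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    target_fs: float = 250.0
    band: tuple[float, float] = (0.7, 40.0)
    epoch_length_s: float = 5.0
    eps: float = 1e-8
    #: minimum event-overlap fraction for an epoch to be labeled positive;
    #: 0 means any strictly positive overlap counts.
    overlap_fraction: float = 0.0

    def __post_init__(self):
        low, high = self.band
        if not (0 < low < high < self.target_fs / 2):
            raise ValidationError(
                f"band {self.band} must satisfy 0 < low < high < Nyquist "
                f"({self.target_fs / 2})"
            )
        if self.epoch_length_s <= 0:
            raise ValidationError("epoch_length_s must be positive")
        if self.eps <= 0:
            raise ValidationError("eps must be positive")
        self.target_channels = [normalize_channel_name(c) for c in self.target_channels]


def select_channels(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Keep exactly the configured channels, in canonical order."""
    index = {name: i for i, name in enumerate(rec.channel_names)}
    missing = [c for c in cfg.target_channels if c not in index]
    if missing:
        raise MissingChannelError(missing)
    rows = [index[c] for c in cfg.target_channels]
    return rec.copy_with(
        signal=rec.signal[rows], channel_names=list(cfg.target_channels)
    )


def resample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase resampling with built-in anti-alias filtering."""
    if target_fs <= 0:
        raise ValidationError("target sampling rate must be positive")
    if abs(rec.fs - target_fs) < 1e-12:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    out = sps.resample_poly(rec.signal, ratio.numerator, ratio.denominator, axis=1)
    n_target = int(round(rec.n_samples * target_fs / rec.fs))
    out = out[:, :n_target]
    return rec.copy_with(signal=out, fs=target_fs)


def bandpass(rec: Recording, band: tuple[float, float] | None = None,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth bandpass (forward-backward), removing DC."""
    low, high = band if band is not None else (0.7, 40.0)
    nyquist = rec.fs / 2
    if not (0 < low < high < nyquist):
        raise ValidationError(f"band ({low}, {high}) outside (0, {nyquist})")
    sos = sps.butter(order, (low, high), btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return rec.copy_with(signal=out)


def average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous across-channel mean from every channel."""
    if rec.n_channels < 2:
        raise ValidationError("average reference requires at least 2 channels")
    out = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return rec.copy_with(signal=out)


def zscore_channels(x: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-row standardization ``(x - mean) / (population std + eps)``."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ValidationError("z-score requires at least 2 samples per channel")
    mean = x.mean(axis=-1, keepdims=True)
    std = x.std(axis=-1, keepdims=True)
    return (x - mean) / (std + eps)


def _epoch_label(start_s: float, stop_s: float, annotations: list[Annotation],
                 overlap_fraction: float, epoch_length_s: float) -> int:
    threshold = max(overlap_fraction * epoch_length_s, 0.0)
    for onset, dur, _ in annotations:
        overlap = min(stop_s, onset + dur) - max(start_s, onset)
        if overlap > threshold or (threshold == 0.0 and overlap > 0.0):
            return 1
    return 0


def segment_epochs(rec: Recording, cfg: PreprocessConfig,
                   annotations: list[Annotation] | None = None) -> EpochSet:
    """Cut non-overlapping consecutive epochs, discarding the remainder.

    An epoch is positive iff it overlaps an annotated event by more than the
    configured fraction of the epoch length (any overlap when the fraction
    is zero).
    """
    if annotations is None:
        annotations = rec.annotations or []
    n_per_epoch = int(round(rec.fs * cfg.epoch_length_s))
    n_epochs = rec.n_samples // n_per_epoch
    if n_epochs == 0:
        warnings.warn(
            f"recording of {rec.duration:.2f} s shorter than one "
            f"{cfg.epoch_length_s} s epoch; returning empty EpochSet",
            stacklevel=2,
        )
    epochs = np.empty((n_epochs, rec.n_channels, n_per_epoch), dtype=rec.signal.dtype)
    labels = np.zeros(n_epochs, dtype=np.int64)
    for k in range(n_epochs):
        sl = slice(k * n_per_epoch, (k + 1) * n_per_epoch)
        epochs[k] = rec.signal[:, sl]
        labels[k] = _epoch_label(
            k * cfg.epoch_length_s, (k + 1) * cfg.epoch_length_s,
            annotations, cfg.overlap_fraction, cfg.epoch_length_s,
        )
    return EpochSet(
        epochs=epochs,
        labels=labels,
        patient_ids=[rec.patient_id] * n_epochs,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
    )


def zscore_epochs(es: EpochSet, eps: float = 1e-8) -> EpochSet:
    """Apply per-channel z-scoring independently to every epoch."""
    if es.n_epochs == 0:
        return es
    return EpochSet(
        epochs=zscore_channels(es.epochs, eps=eps),
        labels=es.labels,
        patient_ids=list(es.patient_ids),
        fs=es.fs,
        channel_names=list(es.channel_names),
    )


def preprocess_recording(rec: Recording, cfg: PreprocessConfig | None = None,
                         annotations: list[Annotation] | None = None) -> EpochSet:
    """Run the full pipeline on one recording."""
    cfg = cfg or PreprocessConfig()
    rec = select_channels(rec, cfg)
    rec = resample(rec, cfg.target_fs)
    rec = bandpass(rec, cfg.band)
    rec = average_reference(rec)
    es = segment_epochs(rec, cfg, annotations)
    return zscore_epochs(es, eps=cfg.eps)
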