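"""Labeled synthetic multichannel EEG with controlled spasm-like events.

Background is 1/f^beta Gaussian noise with a mild shared-source component so
baseline connectivity is non-trivial.  Events add, to a known channel subset
only, a high-amplitude slow wave with a superimposed fast burst over a random
1-3 s sub-interval, with small per-channel lags (so both correlation- and
phase-based connectivity carry class information).  Patients differ by a
log-normal gain and an occasional swapped event channel, which makes
leave-one-patient-out generalization non-trivial.

The generator targets statistical structure, not clinical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .errors import ValidationError
from .io import EpochSet
from .preprocess import DEFAULT_CHANNELS

DEFAULT_EVENT_CHANNELS = ["F3", "F4", "C3", "C4", "T3", "T4"]


@dataclass
class SynthConfig:
    n_patients: int = 10
    epochs_per_patient: int = 40
    spasm_fraction: float = 0.25
    fs: float = 250.0
    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    background_exponent: float = 1.0  # beta of 1/f^beta
    mixing_weight: float = 0.2
    event_channels: list[str] = field(
        default_factory=lambda: list(DEFAULT_EVENT_CHANNELS)
    )
    slow_wave_hz: float = 2.0
    burst_hz: float = 20.0
    event_snr: float = 2.0
    epoch_length_s: float = 5.0
    patient_gain_sigma: float = 0.2
    channel_jitter_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.spasm_fraction < 1:
            raise ValidationError("spasm_fraction must lie in (0, 1)")
        if self.event_snr < 0:
            raise ValidationError("event_snr must be non-negative")
        missing = set(self.event_channels) - set(self.channel_names)
        if missing:
            raise ValidationError(f"event channels not in montage: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


def generate_background(cfg: SynthConfig, n_samples: int,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-channel 1/f^beta noise plus a shared source, unit variance rows."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    c = cfg.n_channels
    own = _colored_noise(rng, (c, n_samples), cfg.background_exponent)
    if cfg.mixing_weight > 0:
        shared = _colored_noise(rng, (1, n_samples), cfg.background_exponent)
        out = own + cfg.mixing_weight * shared
    else:
        out = own
    std = out.std(axis=-1, keepdims=True)
    return out / np.maximum(std, 1e-12)


def _colored_noise(rng: np.random.Generator, shape, beta: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    if beta == 0:
        return white
    spectrum = sfft.rfft(white, axis=-1)
    freqs = sfft.rfftfreq(shape[-1])
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-beta / 2.0)
    scale[0] = 0.0
    return sfft.irfft(spectrum * scale, n=shape[-1], axis=-1)


def inject_event(background: np.ndarray, cfg: SynthConfig,
                 rng: np.random.Generator | None = None,
                 event_channels: list[str] | None = None,
                 ) -> tuple[np.ndarray, tuple[float, float]]:
    """Add a slow-wave + fast-burst transient to the event channels only.

    Returns the modified copy and the (start_s, stop_s) event interval.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    channels = event_channels if event_channels is not None else cfg.event_channels
    out = np.array(background, copy=True)
    c, t = out.shape
    fs = cfg.fs
    duration = rng.uniform(1.0, 3.0)
    start = rng.uniform(0.0, t / fs - duration)
    i0, i1 = int(round(start * fs)), int(round((start + duration) * fs))
    n_ev = i1 - i0
    envelope = np.hanning(n_ev)
    index = {name: i for i, name in enumerate(cfg.channel_names)}
    lags = rng.uniform(0.01, 0.06, size=len(channels))  # seconds, per channel
    for lag, name in zip(lags, channels):
        row = index[name]
        tt = np.arange(n_ev) / fs - lag
        wave = np.sin(2 * np.pi * cfg.slow_wave_hz * tt) + \
            0.5 * np.sin(2 * np.pi * cfg.burst_hz * tt)
        wave = wave * envelope
        rms = np.sqrt(np.mean(background[row, i0:i1] ** 2))
        wave_rms = np.sqrt(np.mean(wave ** 2))
        if wave_rms > 0:
            wave = wave / wave_rms * rms * cfg.event_snr
        out[row, i0:i1] += wave
    return out, (start, start + duration)


def generate_dataset(cfg: SynthConfig) -> tuple[EpochSet, dict]:
    """Generate the full labeled corpus plus a ground-truth record.

    The ground truth lists, per patient, the actual event channels and gain,
    and per epoch the injected event interval (``None`` for non-spasm
    epochs); it is sufficient to evaluate attribution localization without
    re-reading generator internals.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.fs * cfg.epoch_length_s))
    n_pos = int(round(cfg.spasm_fraction * cfg.epochs_per_patient))

    all_epochs, labels, patient_ids = [], [], []
    truth: dict = {"patients": {}, "event_intervals": [], "event_channels": []}
    for p in range(cfg.n_patients):
        pid = f"P{p:02d}"
        gain = float(np.exp(rng.normal(0.0, cfg.patient_gain_sigma)))
        channels = list(cfg.event_channels)
        if rng.random() < cfg.channel_jitter_prob:
            spare = [c for c in cfg.channel_names if c not in channels]
            channels[rng.integers(len(channels))] = spare[rng.integers(len(spare))]
        truth["patients"][pid] = {"event_channels": channels, "gain": gain}

        label_vec = np.zeros(cfg.epochs_per_patient, dtype=np.int64)
        label_vec[:n_pos] = 1
        rng.shuffle(label_vec)
        for is_event in label_vec:
            epoch = generate_background(cfg, n_samples, rng) * gain
            if is_event:
                epoch, interval = inject_event(epoch, cfg, rng,
                                               event_channels=channels)
            else:
                interval = None
            all_epochs.append(epoch)
            labels.append(int(is_event))
            patient_ids.append(pid)
            truth["event_intervals"].append(interval)
            truth["event_channels"].append(channels if is_event else None)

    es = EpochSet(
        epochs=np.stack(all_epochs).astype(np.float32),
        labels=np.asarray(labels),
        patient_ids=patient_ids,
        fs=cfg.fs,
        channel_names=list(cfg.channel_names),
    )
    return es, truth


def patient_spasm_counts(es: EpochSet) -> dict[str, int]:
    """Per-patient positive-epoch counts (the stratification key)."""
    counts: dict[str, int] = {}
    for pid, label in zip(es.patient_ids, es.labels):
        counts[pid] = counts.get(pid, 0) + int(label)
    return counts
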