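"""Per-epoch graph construction.

Temporal graphs: sliding-window Pearson correlation of the z-scored series,
averaged over windows, on a fully connected, undirected, zero-diagonal
support.  Spectral graphs: broadband weighted phase lag index (wPLI) from
Hann-windowed, 50%-overlap cross-spectra, with per-band log Welch power as
node features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sfft
from scipy import signal as sps

from .errors import ValidationError
from .io import EpochSet

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.7, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}


@dataclass
class GraphConfig:
    window_len_samples: int = 250
    step_samples: int = 125
    eps: float = 1e-8
    wpli_segment_len: int = 250
    wpli_overlap: float = 0.5
    wpli_band: tuple[float, float] = (0.7, 40.0)
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self):
        if self.window_len_samples < 1 or self.step_samples < 1:
            raise ValidationError("window and step must be >= 1 sample")
        if not 0 <= self.wpli_overlap < 1:
            raise ValidationError("wpli_overlap must lie in [0, 1)")
        edges = list(self.bands.values())
        for (lo, hi) in edges:
            if not 0 < lo < hi:
                raise ValidationError(f"invalid band ({lo}, {hi})")
        for (_, hi), (lo, _) in zip(edges[:-1], edges[1:]):
            if lo < hi:
                raise ValidationError("bands must be ordered and disjoint")


@dataclass
class ChannelGraph:
    """One epoch's graph for one modality."""

    node_features: np.ndarray  # (C, F)
    weights: np.ndarray  # (C, C), symmetric, zero diagonal
    modality: str  # "temporal" | "spectral"
    channel_names: list[str]

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features)
        self.weights = np.asarray(self.weights)
        c = len(self.channel_names)
        if self.weights.shape != (c, c):
            raise ValidationError("weights must be square (C x C)")
        if self.node_features.shape[0] != c:
            raise ValidationError("node_features rows must match channel count")
        if self.modality not in ("temporal", "spectral"):
            raise ValidationError(f"unknown modality {self.modality!r}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


def window_count(t: int, length: int, step: int) -> int:
    """Number of sliding windows: ``K = floor((T - L) / S) + 1``."""
    if t < length:
        raise ValidationError(f"series of {t} samples shorter than window {length}")
    return (t - length) // step + 1


def windowed_pearson(z: np.ndarray, cfg: GraphConfig | None = None) -> np.ndarray:
    """Sliding-window Pearson correlation stack, shape (K, C, C).

    ``z`` is expected to already be z-scored per channel; each window is
    centered and scaled internally (windows of a standardized series are not
    themselves standardized).  The correlation stabilizer ``eps`` enters the
    denominator, so degenerate windows yield near-zero correlations instead
    of raising.
    """
    cfg = cfg or GraphConfig()
    batched = _windowed_pearson_batch(z[None, ...], cfg)
    return batched[0]


def _windowed_pearson_batch(z: np.ndarray, cfg: GraphConfig) -> np.ndarray:
    """Vectorized (B, C, T) -> (B, K, C, C)."""
    z = np.asarray(z, dtype=np.float64)
    b, c, t = z.shape
    length, step = cfg.window_len_samples, cfg.step_samples
    window_count(t, length, step)  # validates T >= L
    win = sliding_window_view(z, length, axis=-1)[:, :, ::step, :]  # (B,C,K,L)
    centered = win - win.mean(axis=-1, keepdims=True)
    std = win.std(axis=-1)  # population std, (B,C,K)
    xc = np.ascontiguousarray(centered.transpose(0, 2, 1, 3))  # (B,K,C,L)
    cov = xc @ xc.transpose(0, 1, 3, 2) / length  # population covariance
    denom = std.transpose(0, 2, 1)[..., :, None] * std.transpose(0, 2, 1)[..., None, :]
    return cov / (denom + cfg.eps)


def build_temporal_graph(epoch: np.ndarray, cfg: GraphConfig | None = None,
                         channel_names: list[str] | None = None) -> ChannelGraph:
    """Average the windowed correlations into edge weights; node features are
    the z-scored series itself."""
    cfg = cfg or GraphConfig()
    epoch = np.asarray(epoch)
    r = windowed_pearson(epoch, cfg)
    w = r.mean(axis=0)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    names = channel_names or [f"CH{i}" for i in range(epoch.shape[0])]
    return ChannelGraph(
        node_features=epoch, weights=w, modality="temporal", channel_names=names
    )


def _segment_ffts(epoch: np.ndarray, fs: float, cfg: GraphConfig) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed rFFTs of overlapping segments: returns (X, freqs) with
    X of shape (n_segments, C, F)."""
    epoch = np.asarray(epoch, dtype=np.float64)
    c, t = epoch.shape
    nper = cfg.wpli_segment_len
    if nper > t:
        raise ValidationError(
            f"wpli segment length {nper} exceeds epoch length {t}"
        )
    step = max(int(round(nper * (1 - cfg.wpli_overlap))), 1)
    starts = range(0, t - nper + 1, step)
    window = sps.get_window("hann", nper)
    segs = np.stack([epoch[:, s : s + nper] for s in starts])  # (n, C, nper)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    x = sfft.rfft(segs * window, axis=-1)
    freqs = sfft.rfftfreq(nper, d=1.0 / fs)
    return x, freqs


def wpli(epoch: np.ndarray, fs: float, cfg: GraphConfig | None = None) -> np.ndarray:
    """Broadband weighted phase lag index, shape (C, C) in [0, 1].

    ``wPLI_ij = |mean Im(S_ij)| / mean |Im(S_ij)|`` with the mean pooled over
    Welch-style segments and all in-band frequency bins; 0/0 is defined as 0.
    """
    cfg = cfg or GraphConfig()
    x, freqs = _segment_ffts(epoch, fs, cfg)
    lo, hi = cfg.wpli_band
    in_band = (freqs >= lo) & (freqs <= hi)
    xb = x[:, :, in_band]  # (n, C, F)
    # Im(S_ij) per segment and bin, pooled into both means
    im = np.einsum("nif,njf->nijf", xb, xb.conj()).imag
    num = np.abs(im.mean(axis=(0, 3)))
    den = np.abs(im).mean(axis=(0, 3))
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-300)
    out = np.clip((out + out.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(out, 0.0)
    return out


def spectral_node_features(epoch: np.ndarray, fs: float,
                           cfg: GraphConfig | None = None) -> np.ndarray:
    """Log mean Welch power per configured band, shape (C, n_bands)."""
    cfg = cfg or GraphConfig()
    epoch = np.asarray(epoch, dtype=np.float64)
    nyquist = fs / 2
    for name, (lo, hi) in cfg.bands.items():
        if hi > nyquist:
            raise ValidationError(f"band {name} ({lo}, {hi}) exceeds Nyquist {nyquist}")
    nper = min(cfg.wpli_segment_len, epoch.shape[-1])
    freqs, psd = sps.welch(
        epoch, fs=fs, nperseg=nper,
        noverlap=int(round(nper * cfg.wpli_overlap)), window="hann", axis=-1,
    )
    tiny = np.finfo(np.float64).tiny
    if np.any(psd.sum(axis=-1) <= 0):
        warnings.warn("all-zero channel: band power floored at machine-tiny",
                      stacklevel=2)
    band_edges = list(cfg.bands.values())
    feats = np.empty((epoch.shape[0], len(band_edges)))
    for b, (lo, hi) in enumerate(band_edges):
        mask = (freqs >= lo) & (freqs < hi)
        if b == len(band_edges) - 1:
            mask |= freqs == hi
        feats[:, b] = np.log(np.maximum(psd[:, mask].mean(axis=-1), tiny))
    return feats


def build_spectral_graph(epoch: np.ndarray, fs: float,
                         cfg: GraphConfig | None = None,
                         channel_names: list[str] | None = None) -> ChannelGraph:
    cfg = cfg or GraphConfig()
    epoch = np.asarray(epoch)
    names = channel_names or [f"CH{i}" for i in range(epoch.shape[0])]
    return ChannelGraph(
        node_features=spectral_node_features(epoch, fs, cfg),
        weights=wpli(epoch, fs, cfg),
        modality="spectral",
        channel_names=names,
    )


def build_graphs(es: EpochSet, cfg: GraphConfig | None = None,
                 modality: str = "both"):
    """Build graphs for every epoch of a (z-scored) :class:`EpochSet`.

    Returns ``(temporal, spectral)`` lists; either may be ``None`` when a
    single modality is requested.
    """
    cfg = cfg or GraphConfig()
    temporal = spectral = None
    if modality in ("temporal", "both"):
        r = _windowed_pearson_batch(es.epochs, cfg)  # (B, K, C, C)
        w = r.mean(axis=1)
        w = (w + w.transpose(0, 2, 1)) / 2.0
        idx = np.arange(w.shape[1])
        w[:, idx, idx] = 0.0
        temporal = [
            ChannelGraph(
                node_features=es.epochs[i], weights=w[i],
                modality="temporal", channel_names=list(es.channel_names),
            )
            for i in range(es.n_epochs)
        ]
    if modality in ("spectral", "both"):
        spectral = [
            build_spectral_graph(
                es.epochs[i], es.fs, cfg, channel_names=list(es.channel_names)
            )
            for i in range(es.n_epochs)
        ]
    return temporal, spectral
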