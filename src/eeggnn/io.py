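"""Reading EDF recordings and persisting epochs, graphs and checkpoints.

The on-disk epoch store is deliberately plain: a raw little-endian float32
tensor plus a JSON sidecar, so any language can read it back.  The EDF reader
is a self-contained implementation of the (16-bit integer) EDF/EDF+ container;
only referential recordings with a uniform sampling rate are supported.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EDFError, UnsupportedFormatError, ValidationError

#: Modern 10-10 names mapped onto the older 10-20 temporal labels used here.
CHANNEL_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

Annotation = tuple[float, float, str]


def normalize_channel_name(name: str) -> str:
    """Canonicalize a channel label: strip, uppercase, drop an ``EEG`` prefix
    and a reference suffix (``-REF``/``-LE``), then apply montage aliases."""
    label = name.strip().upper()
    if label.startswith("EEG "):
        label = label[4:].strip()
    label = re.sub(r"-(REF|LE|AVG)$", "", label)
    return CHANNEL_ALIASES.get(label, label)


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts."""

    signal: np.ndarray  # (channels, samples)
    channel_names: list[str]
    fs: float
    patient_id: str = ""
    annotations: list[Annotation] | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be a 2-D (channels x samples) array")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValidationError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.fs > 0:
            raise ValidationError("sampling rate must be positive")
        if self.annotations:
            duration = self.n_samples / self.fs
            for onset, dur, _ in self.annotations:
                if onset < 0 or onset + dur > duration + 1e-9:
                    raise ValidationError(
                        f"annotation [{onset}, {onset + dur}] outside recording "
                        f"of {duration:.3f} s"
                    )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "Recording":
        fields = dict(
            signal=self.signal,
            channel_names=list(self.channel_names),
            fs=self.fs,
            patient_id=self.patient_id,
            annotations=self.annotations,
        )
        fields.update(kwargs)
        return Recording(**fields)


@dataclass
class EpochSet:
    """Fixed-length labeled segments with per-epoch patient provenance."""

    epochs: np.ndarray  # (n_epochs, channels, samples)
    labels: np.ndarray  # (n_epochs,) in {0, 1}
    patient_ids: list[str]
    fs: float
    channel_names: list[str]

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs)
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 3:
            raise ValidationError("epochs must be (n_epochs, channels, samples)")
        n = self.epochs.shape[0]
        if self.labels.shape != (n,):
            raise ValidationError(
                f"{self.labels.shape[0] if self.labels.ndim else 0} labels "
                f"for {n} epochs"
            )
        if len(self.patient_ids) != n:
            raise ValidationError(f"{len(self.patient_ids)} patient ids for {n} epochs")
        if self.epochs.shape[1] != len(self.channel_names):
            raise ValidationError("channel dimension does not match channel_names")
        if n and not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be binary")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_length_s(self) -> float:
        return self.epochs.shape[2] / self.fs

    def subset(self, index) -> "EpochSet":
        index = np.asarray(index)
        return EpochSet(
            epochs=self.epochs[index],
            labels=self.labels[index],
            patient_ids=[self.patient_ids[i] for i in np.atleast_1d(index)],
            fs=self.fs,
            channel_names=list(self.channel_names),
        )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_SIGNAL_FIELDS = (  # (name, width)
    ("label", 16), ("transducer", 80), ("dimension", 8), ("phys_min", 8),
    ("phys_max", 8), ("dig_min", 8), ("dig_max", 8), ("prefilter", 80),
    ("n_samples", 8), ("reserved", 32),
)


def read_edf(path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (microvolt scale).

    Channel labels are normalized (uppercase, stripped, aliased); per-signal
    physical scaling is applied.  All retained signals must share one
    sampling rate.
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise EDFError(f"cannot read EDF file {path}: {exc}") from exc
    if len(raw) < 256:
        raise EDFError(f"truncated EDF header in {path}")
    try:
        header_bytes = int(raw[184:192].decode("ascii").strip())
        n_records = int(raw[236:244].decode("ascii").strip())
        record_duration = float(raw[244:252].decode("ascii").strip())
        n_signals = int(raw[252:256].decode("ascii").strip())
    except (ValueError, UnicodeDecodeError) as exc:
        raise EDFError(f"malformed EDF header in {path}: {exc}") from exc
    if len(raw) < header_bytes or header_bytes != 256 * (1 + n_signals):
        raise EDFError(f"truncated or inconsistent EDF header in {path}")

    fields: dict[str, list[str]] = {}
    offset = 256
    for name, width in _EDF_SIGNAL_FIELDS:
        block = raw[offset : offset + width * n_signals]
        fields[name] = [
            block[i * width : (i + 1) * width].decode("ascii", "replace").strip()
            for i in range(n_signals)
        ]
        offset += width * n_signals

    samples_per_record = [int(s) for s in fields["n_samples"]]
    record_size = 2 * sum(samples_per_record)
    data = raw[header_bytes:]
    if n_records < 0:  # unknown length: infer from file size
        n_records = len(data) // record_size
    if len(data) < n_records * record_size:
        raise EDFError(f"truncated EDF data in {path}")

    flat = np.frombuffer(data[: n_records * record_size], dtype="<i2")
    flat = flat.reshape(n_records, record_size // 2)

    signals, names, rates = [], [], []
    col = 0
    for s in range(n_signals):
        nspr = samples_per_record[s]
        chunk = flat[:, col : col + nspr]
        col += nspr
        label = fields["label"][s]
        if label.upper().startswith("EDF ANNOTATIONS"):
            continue
        pmin, pmax = float(fields["phys_min"][s]), float(fields["phys_max"][s])
        dmin, dmax = int(fields["dig_min"][s]), int(fields["dig_max"][s])
        if dmax == dmin:
            raise EDFError(f"degenerate digital range for signal {label} in {path}")
        gain = (pmax - pmin) / (dmax - dmin)
        physical = (chunk.astype(np.float64).ravel() - dmin) * gain + pmin
        signals.append(physical)
        names.append(normalize_channel_name(label))
        rates.append(nspr / record_duration)
    if not signals:
        raise EDFError(f"no data signals in {path}")
    if len(set(rates)) != 1:
        raise UnsupportedFormatError(
            f"{path}: signals with differing sampling rates ({sorted(set(rates))})"
        )
    return Recording(
        signal=np.vstack(signals),
        channel_names=names,
        fs=rates[0],
        patient_id=path.stem,
    )


def write_edf(path, rec: Recording) -> Path:
    """Write a referential EDF file (test fixtures and interchange).

    Requires an integer number of samples per one-second data record.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError("write_edf requires an integer sampling rate")
    fs = int(round(fs))
    n_records = rec.n_samples // fs
    if n_records * fs != rec.n_samples:
        raise ValidationError("write_edf requires a whole number of 1-s records")
    n_sig = rec.n_channels

    pmaxs = np.maximum(np.abs(rec.signal).max(axis=1), 1e-6)
    dmin, dmax = -32768, 32767
    digital = np.empty((n_sig, rec.n_samples), dtype="<i2")
    for i in range(n_sig):
        scaled = rec.signal[i] / pmaxs[i] * dmax
        digital[i] = np.clip(np.round(scaled), dmin, dmax).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        return text.encode("ascii")[:width].ljust(width)

    header = b"".join([
        pad("0", 8),
        pad(rec.patient_id or "X", 80),
        pad("Startdate 01-JAN-2000", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + n_sig)), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(n_sig), 4),
    ])
    sig_values = {
        "label": rec.channel_names,
        "transducer": [""] * n_sig,
        "dimension": ["uV"] * n_sig,
        "phys_min": [f"{-p:.6g}"[:8] for p in pmaxs],
        "phys_max": [f"{p:.6g}"[:8] for p in pmaxs],
        "dig_min": [str(dmin)] * n_sig,
        "dig_max": [str(dmax)] * n_sig,
        "prefilter": [""] * n_sig,
        "n_samples": [str(fs)] * n_sig,
        "reserved": [""] * n_sig,
    }
    for name, width in _EDF_SIGNAL_FIELDS:
        header += b"".join(pad(v, width) for v in sig_values[name])

    body = digital.reshape(n_sig, n_records, fs).transpose(1, 0, 2).tobytes()
    path.write_bytes(header + body)
    return path


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations_csv(path) -> list[Annotation]:
    """Read ``onset_s,duration_s,label`` rows (header optional)."""
    out: list[Annotation] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        try:
            onset, dur = float(parts[0]), float(parts[1])
        except ValueError:
            continue  # header row
        label = parts[2] if len(parts) > 2 else "event"
        out.append((onset, dur, label))
    return out


def read_chbmit_summary(path, edf_name: str) -> list[Annotation]:
    """Extract seizure intervals for one EDF file from a CHB-MIT style
    ``*-summary.txt`` file."""
    text = Path(path).read_text()
    blocks = re.split(r"File Name:", text)[1:]
    for block in blocks:
        name = block.strip().splitlines()[0].strip()
        if name != edf_name:
            continue
        starts = [int(m) for m in re.findall(
            r"Seizure(?:\s+\d+)?\s+Start Time:\s*(\d+)", block)]
        ends = [int(m) for m in re.findall(
            r"Seizure(?:\s+\d+)?\s+End Time:\s*(\d+)", block)]
        return [(float(s), float(e - s), "seizure") for s, e in zip(starts, ends)]
    return []


# ---------------------------------------------------------------------------
# epoch / graph / checkpoint stores
# ---------------------------------------------------------------------------

def write_epochs(es: EpochSet, out_dir) -> Path:
    """Persist an :class:`EpochSet` as ``epochs.bin`` (little-endian float32)
    plus ``manifest.json``.  Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tensor = np.ascontiguousarray(es.epochs, dtype="<f4")
    (out_dir / "epochs.bin").write_bytes(tensor.tobytes())
    manifest = {
        "format": "eeggnn-epochs-v1",
        "n_epochs": int(es.n_epochs),
        "shape": list(tensor.shape),
        "dtype": "<f4",
        "labels": [int(v) for v in es.labels],
        "patient_ids": list(es.patient_ids),
        "fs": float(es.fs),
        "channel_names": list(es.channel_names),
        "epoch_length_s": float(es.epoch_length_s),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_epochs(path) -> EpochSet:
    """Load an epoch store from its directory or manifest path."""
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    manifest = json.loads(path.read_text())
    shape = tuple(manifest["shape"])
    data = np.frombuffer(
        (path.parent / "epochs.bin").read_bytes(), dtype=manifest["dtype"]
    ).reshape(shape)
    return EpochSet(
        epochs=data,
        labels=np.asarray(manifest["labels"], dtype=np.int64),
        patient_ids=list(manifest["patient_ids"]),
        fs=manifest["fs"],
        channel_names=list(manifest["channel_names"]),
    )


def write_graphs(graphs, out_dir, name: str) -> Path:
    """Persist a list of same-shape :class:`~eeggnn.graphs.ChannelGraph`
    objects: one JSON header plus float32 blocks for weights and features."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not graphs:
        raise ValidationError("no graphs to write")
    weights = np.stack([g.weights for g in graphs]).astype("<f4")
    feats = np.stack([g.node_features for g in graphs]).astype("<f4")
    (out_dir / f"{name}_weights.bin").write_bytes(weights.tobytes())
    (out_dir / f"{name}_features.bin").write_bytes(feats.tobytes())
    header = {
        "format": "eeggnn-graphs-v1",
        "modality": graphs[0].modality,
        "channel_names": list(graphs[0].channel_names),
        "n_graphs": len(graphs),
        "weights_shape": list(weights.shape),
        "features_shape": list(feats.shape),
        "dtype": "<f4",
    }
    header_path = out_dir / f"{name}.json"
    header_path.write_text(json.dumps(header, indent=1))
    return header_path


def read_graphs(path):
    """Inverse of :func:`write_graphs`."""
    from .graphs import ChannelGraph  # local import to avoid a cycle

    path = Path(path)
    header = json.loads(path.read_text())
    stem = path.with_suffix("")
    weights = np.frombuffer(
        Path(f"{stem}_weights.bin").read_bytes(), dtype=header["dtype"]
    ).reshape(header["weights_shape"])
    feats = np.frombuffer(
        Path(f"{stem}_features.bin").read_bytes(), dtype=header["dtype"]
    ).reshape(header["features_shape"])
    return [
        ChannelGraph(
            node_features=feats[i],
            weights=weights[i],
            modality=header["modality"],
            channel_names=list(header["channel_names"]),
        )
        for i in range(header["n_graphs"])
    ]


def save_checkpoint(path, params: dict[str, np.ndarray], config: dict) -> Path:
    """Save a flat parameter map (``.npz``) with a JSON config echo."""
    path = Path(path)
    np.savez(path, **{k: np.asarray(v) for k, v in params.items()})
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    path.with_suffix(".json").write_text(json.dumps(config, indent=1, default=str))
    return path


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    with np.load(path) as archive:
        params = {k: archive[k] for k in archive.files}
    config_path = path.with_suffix(".json")
    config = json.loads(config_path.read_text()) if config_path.exists() else {}
    return params, config
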