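"""Gradient-times-input attribution with cross-modal score fusion.

Attribution is taken with respect to the pre-sigmoid logit (the logit avoids
vanishing gradients near saturated probabilities).  Per-modality channel
scores are the mean over the non-channel axis; fused scores are the convex
combination ``lam * temporal + (1 - lam) * spectral``; region evidence is the
per-region sum of fused channel scores, which conserves total evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .errors import MontageError, ValidationError
from .graphs import ChannelGraph
from .io import normalize_channel_name
from .model import REGION_NAMES, CrossModalGraphClassifier, RegionMap

#: Schematic 2-D scalp positions (10-20 system, nose up, unit head circle).
ELECTRODE_POSITIONS = {
    "FP1": (-0.31, 0.95), "FP2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.48), "FZ": (0.0, 0.48),
    "F4": (0.40, 0.48), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.50, 0.0), "CZ": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.40, -0.48), "PZ": (0.0, -0.48),
    "P4": (0.40, -0.48), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}


@dataclass
class AttributionResult:
    temporal_attr: np.ndarray  # (C, T)
    spectral_attr: np.ndarray  # (C, F)
    fused_channel_scores: np.ndarray  # (C,)
    region_evidence: np.ndarray  # (R,)
    region_names: tuple[str, ...]
    lam: float
    normalization: dict


def gradient_x_input(model_fn, x: np.ndarray) -> np.ndarray:
    """Elementwise ``input * d(model_fn)/d(input)`` for a differentiable
    scalar-valued ``model_fn`` built from :class:`~eeggnn.autodiff.Tensor`
    operations."""
    t = Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)
    out = model_fn(t)
    if not isinstance(out, Tensor):
        raise ValidationError("model_fn must return a Tensor")
    out.backward()
    if not np.all(np.isfinite(t.grad)):
        raise FloatingPointError("non-finite gradients in attribution")
    return t.data * t.grad


def channel_scores(attr: np.ndarray) -> np.ndarray:
    """Per-channel mean over the non-channel axis."""
    attr = np.asarray(attr)
    if attr.ndim == 1:
        return attr
    return attr.mean(axis=tuple(range(1, attr.ndim)))


def fuse_attributions(t_scores: np.ndarray, s_scores: np.ndarray,
                      lam: float = 0.5) -> np.ndarray:
    if not 0 <= lam <= 1:
        raise ValidationError("fusion coefficient must lie in [0, 1]")
    return lam * np.asarray(t_scores) + (1.0 - lam) * np.asarray(s_scores)


def region_evidence(scores: np.ndarray, rmap: RegionMap,
                    channel_names: list[str]) -> np.ndarray:
    """Sum of channel scores per anatomical region, ordered as
    :data:`~eeggnn.model.REGION_NAMES`."""
    indices = rmap.indices(channel_names)
    scores = np.asarray(scores)
    return np.array([scores[indices[r]].sum() for r in REGION_NAMES])


def attribute_epoch(model: CrossModalGraphClassifier,
                    temporal_graph: ChannelGraph,
                    spectral_graph: ChannelGraph,
                    lam: float = 0.5) -> AttributionResult:
    """Full per-segment attribution: gradient-times-input per modality on the
    node-feature inputs (edge weights held constant), temporal averaging,
    fixed-coefficient fusion, and region aggregation."""
    xt = Tensor(temporal_graph.node_features[None].astype(np.float32),
                requires_grad=True)
    xs = Tensor(spectral_graph.node_features[None].astype(np.float32),
                requires_grad=True)
    logit = model.forward_batch(
        xt, temporal_graph.weights[None].astype(np.float32),
        xs, spectral_graph.weights[None].astype(np.float32),
        training=False,
    )
    logit.reshape(()).backward()
    if xt.grad is None or xs.grad is None or not (
        np.all(np.isfinite(xt.grad)) and np.all(np.isfinite(xs.grad))
    ):
        raise FloatingPointError("non-finite attribution gradients")
    temporal_attr = (xt.data * xt.grad)[0].astype(np.float64)
    spectral_attr = (xs.data * xs.grad)[0].astype(np.float64)
    t_scores = channel_scores(temporal_attr)
    s_scores = channel_scores(spectral_attr)
    fused = fuse_attributions(t_scores, s_scores, lam)
    evidence = region_evidence(fused, model.region_map, model.channel_names)
    return AttributionResult(
        temporal_attr=temporal_attr,
        spectral_attr=spectral_attr,
        fused_channel_scores=fused,
        region_evidence=evidence,
        region_names=REGION_NAMES,
        lam=lam,
        normalization={"scheme": "none"},
    )


def render_topomap(scores: np.ndarray, channel_names: list[str], out_path,
                   title: str | None = None) -> tuple[Path, dict]:
    """Render an interpolated scalp map of per-sample min-max normalized
    scores.  Returns the image path and the normalization record."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.interpolate import griddata

    scores = np.asarray(scores, dtype=np.float64)
    names = [normalize_channel_name(c) for c in channel_names]
    unknown = [c for c in names if c not in ELECTRODE_POSITIONS]
    if unknown:
        raise MontageError(f"no scalp coordinates for channels: {unknown}")
    lo, hi = float(scores.min()), float(scores.max())
    record = {"scheme": "minmax", "min": lo, "max": hi}
    normalized = np.zeros_like(scores) if hi == lo else (scores - lo) / (hi - lo)

    points = np.array([ELECTRODE_POSITIONS[c] for c in names])
    grid = np.linspace(-1.1, 1.1, 120)
    gx, gy = np.meshgrid(grid, grid)
    interpolated = griddata(points, normalized, (gx, gy), method="cubic")
    interpolated[gx ** 2 + gy ** 2 > 1.1 ** 2] = np.nan

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(interpolated, extent=(-1.1, 1.1, -1.1, 1.1), origin="lower",
              cmap="RdBu_r", vmin=0.0, vmax=1.0)
    ax.add_patch(plt.Circle((0, 0), 1.05, fill=False, linewidth=1.5))
    ax.scatter(points[:, 0], points[:, 1], s=12, c="black", zorder=3)
    for (x, y), name in zip(points, names):
        ax.annotate(name, (x, y), fontsize=6, ha="center", va="bottom")
    ax.set_xlim(-1.2, 1.2)
    ax.set_ylim(-1.2, 1.3)
    ax.axis("off")
    if title:
        ax.set_title(title)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return out_path, record
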