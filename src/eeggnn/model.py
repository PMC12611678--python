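"""The cross-modal temporal-spectral graph classifier.

Forward composition per 5-s segment: multi-scale 1-D convolutional encoding
of the raw series -> per-modality projection to a shared width -> edge-
conditioned graph convolution on the connectivity weights -> attention
pooling into five anatomical regions -> bidirectional multi-head cross-modal
attention -> gated fusion -> two-layer classifier with dropout.

Implemented on the package's NumPy autodiff engine; public per-sample
operations (``multiscale_encode`` .. ``forward``) mirror the batched
internals with plain-array interfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .autodiff import (
    Tensor, concat, conv1d_valid, dropout, einsum, layer_norm, linear,
    softmax, stack,
)
from .errors import MontageError, ValidationError
from .graphs import ChannelGraph
from .io import normalize_channel_name

REGION_NAMES = ("frontal", "central", "parietal", "occipital", "temporal")


@dataclass
class ModelConfig:
    kernel_sizes: list[int] = field(default_factory=lambda: [100, 50, 25])
    hidden_width: int = 64  # D
    n_heads: int = 4
    n_regions: int = 5
    edge_mlp_hidden: int = 64
    classifier_hidden: int = 128
    dropout_rate: float = 0.5
    conv_channels: int = 8
    n_spectral_features: int = 5
    bn_momentum: float = 0.1

    def __post_init__(self):
        if self.hidden_width % self.n_heads:
            raise ValidationError(
                f"hidden width {self.hidden_width} not divisible by "
                f"{self.n_heads} heads"
            )
        for name in ("hidden_width", "n_heads", "edge_mlp_hidden",
                     "classifier_hidden", "conv_channels", "n_spectral_features"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if any(k <= 0 for k in self.kernel_sizes):
            raise ValidationError("kernel sizes must be positive")

    @property
    def head_dim(self) -> int:
        return self.hidden_width // self.n_heads

    def to_dict(self) -> dict:
        return {
            "kernel_sizes": list(self.kernel_sizes),
            "hidden_width": self.hidden_width,
            "n_heads": self.n_heads,
            "n_regions": self.n_regions,
            "edge_mlp_hidden": self.edge_mlp_hidden,
            "classifier_hidden": self.classifier_hidden,
            "dropout_rate": self.dropout_rate,
            "conv_channels": self.conv_channels,
            "n_spectral_features": self.n_spectral_features,
            "bn_momentum": self.bn_momentum,
        }


class RegionMap:
    """Channel label -> anatomical region assignment."""

    def __init__(self, assignment: dict[str, str]):
        self.assignment = {
            normalize_channel_name(ch): region.lower()
            for ch, region in assignment.items()
        }
        unknown = set(self.assignment.values()) - set(REGION_NAMES)
        if unknown:
            raise MontageError(f"unknown regions: {sorted(unknown)}")

    @classmethod
    def default(cls) -> "RegionMap":
        with resources.files("eeggnn.data").joinpath("regions.yaml").open() as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def from_yaml(cls, path) -> "RegionMap":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_mapping(cls, region_to_channels: dict[str, list[str]]) -> "RegionMap":
        assignment = {}
        for region, channels in region_to_channels.items():
            for ch in channels:
                assignment[ch] = region
        return cls(assignment)

    def region_of(self, channel: str) -> str:
        key = normalize_channel_name(channel)
        if key not in self.assignment:
            raise MontageError(f"channel {channel!r} has no region assignment")
        return self.assignment[key]

    def indices(self, channel_names: list[str]) -> dict[str, np.ndarray]:
        """Per-region channel indices for an ordered channel list; every
        channel must be mapped and every region non-empty."""
        groups: dict[str, list[int]] = {r: [] for r in REGION_NAMES}
        for i, ch in enumerate(channel_names):
            groups[self.region_of(ch)].append(i)
        empty = [r for r, idx in groups.items() if not idx]
        if empty:
            raise ValidationError(f"empty regions for this montage: {empty}")
        return {r: np.asarray(idx, dtype=np.intp) for r, idx in groups.items()}


@dataclass
class RegionFeatures:
    """Region embeddings plus the attention weights that produced them."""

    features: np.ndarray  # (R, D)
    attention: dict[str, np.ndarray]  # region -> per-channel weights
    region_names: tuple[str, ...] = REGION_NAMES


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape, dtype=np.float32) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def init_parameters(cfg: ModelConfig, seed: int = 0) -> dict[str, Tensor]:
    """Deterministic parameter initialization (Glorot-uniform weights)."""
    rng = np.random.default_rng(seed)
    d = cfg.hidden_width
    o = cfg.conv_channels
    p: dict[str, np.ndarray] = {}
    for k in cfg.kernel_sizes:
        p[f"enc.conv{k}.w"] = _glorot(rng, (k, o))
        p[f"enc.bn{k}.gamma"] = np.ones(o, dtype=np.float32)
        p[f"enc.bn{k}.beta"] = np.zeros(o, dtype=np.float32)
    p["enc.proj.w"] = _glorot(rng, (len(cfg.kernel_sizes) * o, d))
    p["enc.proj.b"] = np.zeros(d, dtype=np.float32)
    p["proj.t.w"] = _glorot(rng, (d, d))
    p["proj.t.b"] = np.zeros(d, dtype=np.float32)
    p["proj.s.w"] = _glorot(rng, (cfg.n_spectral_features, d))
    p["proj.s.b"] = np.zeros(d, dtype=np.float32)
    for m in ("t", "s"):
        p[f"ecc.{m}.w1"] = _glorot(rng, (1, cfg.edge_mlp_hidden))
        p[f"ecc.{m}.b1"] = np.zeros(cfg.edge_mlp_hidden, dtype=np.float32)
        p[f"ecc.{m}.w2"] = _glorot(rng, (cfg.edge_mlp_hidden, d * d))
        p[f"ecc.{m}.b2"] = np.zeros(d * d, dtype=np.float32)
        p[f"ecc.{m}.ln.gamma"] = np.ones(d, dtype=np.float32)
        p[f"ecc.{m}.ln.beta"] = np.zeros(d, dtype=np.float32)
        for r in REGION_NAMES:
            p[f"pool.{m}.{r}"] = (
                rng.standard_normal(d).astype(np.float32) / math.sqrt(d)
            )
        p[f"gate.{m}.w"] = _glorot(rng, (2 * d, d))
        p[f"gate.{m}.b"] = np.zeros(d, dtype=np.float32)
    for direction in ("t", "s"):  # queries drawn from this modality
        for name in ("wq", "wk", "wv", "wo"):
            p[f"att.{direction}.{name}"] = _glorot(rng, (d, d))
    p["clf.w1"] = _glorot(rng, (2 * cfg.n_regions * d, cfg.classifier_hidden))
    p["clf.b1"] = np.zeros(cfg.classifier_hidden, dtype=np.float32)
    p["clf.w2"] = _glorot(rng, (cfg.classifier_hidden, 1))
    p["clf.b2"] = np.zeros(1, dtype=np.float32)
    return {k: Tensor(v, requires_grad=True) for k, v in p.items()}


def init_bn_state(cfg: ModelConfig) -> dict[str, np.ndarray]:
    state = {}
    for k in cfg.kernel_sizes:
        state[f"enc.bn{k}.mean"] = np.zeros(cfg.conv_channels, dtype=np.float32)
        state[f"enc.bn{k}.var"] = np.ones(cfg.conv_channels, dtype=np.float32)
    return state


# ---------------------------------------------------------------------------
# batched internals (Tensor in / Tensor out)
# ---------------------------------------------------------------------------

def _bn_relu_pool(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
                  running_var, training: bool, momentum: float,
                  eps: float = 1e-5) -> Tensor:
    """Fused BatchNorm (over all axes but the feature-map axis) -> ReLU ->
    mean over time: (B, C, O, L) -> (B, C, O).

    One custom op with an analytic backward; composing this from elementwise
    primitives would allocate ~10 full-size temporaries per branch and
    dominates the training step otherwise.
    """
    b, c, o, length = x.shape
    if training:
        mu = x.data.mean(axis=(0, 1, 3))
        var = x.data.var(axis=(0, 1, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + eps)).astype(x.data.dtype)
    xhat = x.data - mu.reshape(1, 1, -1, 1).astype(x.data.dtype)
    xhat *= inv.reshape(1, 1, -1, 1)
    y = np.multiply(gamma.data.reshape(1, 1, -1, 1), xhat)
    y += beta.data.reshape(1, 1, -1, 1)
    mask = y > 0
    np.multiply(y, mask, out=y)
    out_data = y.mean(axis=-1)

    def backward(g):
        # single reusable full-size buffer; reductions via einsum (no temps)
        gy = np.multiply(mask, (g[..., None] / length).astype(x.data.dtype))
        if beta.requires_grad:
            beta._accumulate(gy.sum(axis=(0, 1, 3)))
        if gamma.requires_grad:
            gamma._accumulate(np.einsum("bcol,bcol->o", gy, xhat))
        if x.requires_grad:
            np.multiply(gy, gamma.data.reshape(1, 1, -1, 1), out=gy)  # gxhat
            if training:
                n = b * c * length
                mean_g = gy.sum(axis=(0, 1, 3)) / n
                mean_gx = np.einsum("bcol,bcol->o", gy, xhat) / n
                gy -= mean_g.reshape(1, 1, -1, 1)
                np.multiply(xhat, mean_gx.reshape(1, 1, -1, 1), out=xhat)
                gy -= xhat
            gy *= inv.reshape(1, 1, -1, 1)
            x._accumulate(gy)

    return Tensor._make(out_data, (x, gamma, beta), backward)


def _encode(x: Tensor, params, cfg: ModelConfig, bn_state, training: bool) -> Tensor:
    """(B, C, T) -> (B, C, D) multi-scale temporal embedding."""
    t_len = x.shape[-1]
    if t_len < max(cfg.kernel_sizes):
        raise ValidationError(
            f"epoch length {t_len} shorter than largest kernel "
            f"{max(cfg.kernel_sizes)}"
        )
    pooled = []
    for k in cfg.kernel_sizes:
        h = conv1d_valid(x, params[f"enc.conv{k}.w"])  # (B, C, O, L_k)
        pooled.append(_bn_relu_pool(
            h, params[f"enc.bn{k}.gamma"], params[f"enc.bn{k}.beta"],
            bn_state[f"enc.bn{k}.mean"], bn_state[f"enc.bn{k}.var"],
            training, cfg.bn_momentum,
        ))  # BN + ReLU + global average pool -> (B, C, O)
    return linear(concat(pooled, axis=-1), params["enc.proj.w"], params["enc.proj.b"])


def _project(features: Tensor, params, modality: str) -> Tensor:
    return linear(features, params[f"proj.{modality}.w"], params[f"proj.{modality}.b"])


def _masked_mean_messages(kernels: Tensor, nodes: Tensor) -> Tensor:
    """Mean over neighbors j != i of ``W_ij @ x_j``:
    (B, C, C, D, D), (B, C, D) -> (B, C, D).

    The self-loop exclusion is folded into a three-operand einsum so the
    (B, C, C, D, D) kernel block is touched once per pass.
    """
    c = nodes.shape[1]
    mask = (1.0 - np.eye(c, dtype=nodes.data.dtype)) / (c - 1)
    out_data = np.einsum("bijde,bje,ij->bid", kernels.data, nodes.data, mask)

    def backward(g):
        if kernels.requires_grad:
            kernels._accumulate(
                np.einsum("bid,bje,ij->bijde", g, nodes.data, mask)
            )
        if nodes.requires_grad:
            nodes._accumulate(
                np.einsum("bid,bijde,ij->bje", g, kernels.data, mask)
            )

    return Tensor._make(out_data, (kernels, nodes), backward)


def _edge_conditioned(nodes: Tensor, weights: Tensor, params, modality: str,
                      d: int) -> Tensor:
    """(B, C, D), (B, C, C) -> (B, C, D) edge-conditioned message passing."""
    if np.isnan(weights.data).any():
        raise ValidationError("NaN edge attribute")
    b, c, _ = nodes.shape
    attrs = weights.reshape(b, c, c, 1).reshape(b * c * c, 1)
    h = linear(attrs, params[f"ecc.{modality}.w1"], params[f"ecc.{modality}.b1"]).relu()
    kernels = linear(h, params[f"ecc.{modality}.w2"], params[f"ecc.{modality}.b2"])
    agg = _masked_mean_messages(kernels.reshape(b, c, c, d, d), nodes)
    return layer_norm(
        agg.relu(),
        params[f"ecc.{modality}.ln.gamma"], params[f"ecc.{modality}.ln.beta"],
    )


def _region_pool(z: Tensor, region_indices: dict[str, np.ndarray], params,
                 modality: str) -> tuple[Tensor, dict[str, np.ndarray]]:
    """(B, C, D) -> (B, R, D) softmax attention pooling within regions."""
    outputs, alphas = [], {}
    for region in REGION_NAMES:
        idx = region_indices[region]
        zr = z.take(idx, axis=1)  # (B, n_r, D)
        scores = zr @ params[f"pool.{modality}.{region}"]  # (B, n_r)
        alpha = softmax(scores, axis=-1)
        alphas[region] = alpha.data
        outputs.append(einsum("bi,bid->bd", alpha, zr))
    return stack(outputs, axis=1), alphas


def _attend(queries_from: Tensor, keys_values_from: Tensor, params,
            direction: str, cfg: ModelConfig) -> Tensor:
    """One direction of multi-head cross-attention, (B, R, D) -> (B, R, D)."""
    b, r, d = queries_from.shape
    h, dh = cfg.n_heads, cfg.head_dim

    def split_heads(t: Tensor) -> Tensor:
        return t.reshape(b, r, h, dh).transpose((0, 2, 1, 3))  # (B, H, R, dh)

    q = split_heads(queries_from @ params[f"att.{direction}.wq"])
    k = split_heads(keys_values_from @ params[f"att.{direction}.wk"])
    v = split_heads(keys_values_from @ params[f"att.{direction}.wv"])
    scores = einsum("bhrd,bhsd->bhrs", q, k) * (1.0 / math.sqrt(dh))
    att = softmax(scores, axis=-1)
    mixed = einsum("bhrs,bhsd->bhrd", att, v)
    merged = mixed.transpose((0, 2, 1, 3)).reshape(b, r, d)
    return merged @ params[f"att.{direction}.wo"]


def _gate(raw: Tensor, enhanced: Tensor, params, modality: str) -> Tensor:
    g = linear(
        concat([raw, enhanced], axis=-1),
        params[f"gate.{modality}.w"], params[f"gate.{modality}.b"],
    ).sigmoid()
    return g * enhanced + (1.0 - g) * raw


def _classify(fused_t: Tensor, fused_s: Tensor, params, cfg: ModelConfig,
              training: bool, rng: np.random.Generator | None) -> Tensor:
    b = fused_t.shape[0]
    flat = concat([fused_t, fused_s], axis=1).reshape(b, -1)
    h = linear(flat, params["clf.w1"], params["clf.b1"]).relu()
    if training and cfg.dropout_rate > 0:
        if rng is None:
            raise ValidationError("training-mode classify requires an RNG")
        h = dropout(h, cfg.dropout_rate, rng)
    return linear(h, params["clf.w2"], params["clf.b2"]).reshape(b)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class CrossModalGraphClassifier:
    """End-to-end segment classifier over paired temporal/spectral graphs."""

    def __init__(self, cfg: ModelConfig | None = None,
                 region_map: RegionMap | None = None,
                 channel_names: list[str] | None = None, seed: int = 0):
        from .preprocess import DEFAULT_CHANNELS

        self.cfg = cfg or ModelConfig()
        self.region_map = region_map or RegionMap.default()
        self.channel_names = [
            normalize_channel_name(c) for c in (channel_names or DEFAULT_CHANNELS)
        ]
        self.region_indices = self.region_map.indices(self.channel_names)
        self.params = init_parameters(self.cfg, seed=seed)
        self.bn_state = init_bn_state(self.cfg)
        self.last_attention: dict[str, dict[str, np.ndarray]] = {}

    # -- forward ------------------------------------------------------------
    def forward_batch(self, xt, wt, xs, ws, training: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
        """Logits for a batch.  Inputs may be arrays or Tensors:
        ``xt`` (B, C, T) z-scored series, ``wt`` (B, C, C) temporal weights,
        ``xs`` (B, C, F) spectral node features, ``ws`` (B, C, C) wPLI."""
        xt = xt if isinstance(xt, Tensor) else Tensor(np.asarray(xt, dtype=np.float32))
        xs = xs if isinstance(xs, Tensor) else Tensor(np.asarray(xs, dtype=np.float32))
        wt = wt if isinstance(wt, Tensor) else Tensor(np.asarray(wt, dtype=np.float32))
        ws = ws if isinstance(ws, Tensor) else Tensor(np.asarray(ws, dtype=np.float32))
        d = self.cfg.hidden_width

        h_ms = _encode(xt, self.params, self.cfg, self.bn_state, training)
        xhat_t = _project(h_ms, self.params, "t")
        xhat_s = _project(xs, self.params, "s")
        z_t = _edge_conditioned(xhat_t, wt, self.params, "t", d)
        z_s = _edge_conditioned(xhat_s, ws, self.params, "s", d)
        u_t, alpha_t = _region_pool(z_t, self.region_indices, self.params, "t")
        u_s, alpha_s = _region_pool(z_s, self.region_indices, self.params, "s")
        self.last_attention = {"t": alpha_t, "s": alpha_s}
        enh_t = _attend(u_t, u_s, self.params, "t", self.cfg)
        enh_s = _attend(u_s, u_t, self.params, "s", self.cfg)
        fused_t = _gate(u_t, enh_t, self.params, "t")
        fused_s = _gate(u_s, enh_s, self.params, "s")
        return _classify(fused_t, fused_s, self.params, self.cfg, training, rng)

    def predict_logits(self, xt, wt, xs, ws) -> np.ndarray:
        return self.forward_batch(xt, wt, xs, ws, training=False).data

    def predict_proba(self, xt, wt, xs, ws) -> np.ndarray:
        logits = self.predict_logits(xt, wt, xs, ws)
        return 1.0 / (1.0 + np.exp(-logits))

    # -- persistence --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: p.data.copy() for k, p in self.params.items()}
        out.update({f"state.{k}": v.copy() for k, v in self.bn_state.items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.asarray(state[k], dtype=p.data.dtype).reshape(p.data.shape)
        for k in self.bn_state:
            self.bn_state[k] = np.asarray(
                state[f"state.{k}"], dtype=np.float32
            ).copy()


# ---------------------------------------------------------------------------
# per-sample operation surface (plain arrays in, plain arrays out)
# ---------------------------------------------------------------------------

def multiscale_encode(x: np.ndarray, params, cfg: ModelConfig,
                      bn_state=None, training: bool = False) -> np.ndarray:
    """(N, T) -> (N, D): parallel valid convolutions, BN, ReLU, per-branch
    global average pooling, concatenation, affine map to width D."""
    bn_state = bn_state if bn_state is not None else init_bn_state(cfg)
    out = _encode(Tensor(np.asarray(x)[None, ...]), params, cfg, bn_state, training)
    return out.data[0]


def project_nodes(features: np.ndarray, params, modality: str) -> np.ndarray:
    features = np.asarray(features)
    expected = params[f"proj.{modality}.w"].shape[0]
    if features.shape[-1] != expected:
        raise ValidationError(
            f"{modality} projection expects width {expected}, "
            f"got {features.shape[-1]}"
        )
    return _project(Tensor(features[None, ...]), params, modality).data[0]


def edge_conditioned_conv(nodes: np.ndarray, weights: np.ndarray, params,
                          modality: str) -> np.ndarray:
    nodes = np.asarray(nodes)
    d = nodes.shape[-1]
    out = _edge_conditioned(
        Tensor(nodes[None, ...]), Tensor(np.asarray(weights)[None, ...]),
        params, modality, d,
    )
    return out.data[0]


def region_attention_pool(nodes: np.ndarray, rmap: RegionMap, params,
                          modality: str,
                          channel_names: list[str]) -> RegionFeatures:
    indices = rmap.indices(channel_names)
    u, alphas = _region_pool(Tensor(np.asarray(nodes)[None, ...]), indices,
                             params, modality)
    return RegionFeatures(
        features=u.data[0],
        attention={r: a[0] for r, a in alphas.items()},
    )


def cross_modal_attention(u_t: np.ndarray, u_s: np.ndarray, params,
                          cfg: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    ut = Tensor(np.asarray(u_t)[None, ...])
    us = Tensor(np.asarray(u_s)[None, ...])
    enh_t = _attend(ut, us, params, "t", cfg)
    enh_s = _attend(us, ut, params, "s", cfg)
    return enh_t.data[0], enh_s.data[0]


def gated_fusion(raw: np.ndarray, enhanced: np.ndarray, params,
                 modality: str) -> np.ndarray:
    raw, enhanced = np.asarray(raw), np.asarray(enhanced)
    if raw.shape != enhanced.shape:
        raise ValidationError("raw/enhanced shape mismatch")
    return _gate(Tensor(raw[None]), Tensor(enhanced[None]), params, modality).data[0]


def classify(fused_t: np.ndarray, fused_s: np.ndarray, params, cfg: ModelConfig,
             training: bool = False,
             rng: np.random.Generator | None = None) -> float:
    logit = _classify(
        Tensor(np.asarray(fused_t)[None]), Tensor(np.asarray(fused_s)[None]),
        params, cfg, training, rng,
    )
    return float(1.0 / (1.0 + np.exp(-logit.data[0])))


def forward(temporal_graph: ChannelGraph, spectral_graph: ChannelGraph,
            model: CrossModalGraphClassifier) -> float:
    """Probability that one segment is a spasm."""
    if temporal_graph.channel_names != spectral_graph.channel_names:
        raise ValidationError("temporal and spectral graphs disagree on channels")
    return float(model.predict_proba(
        temporal_graph.node_features[None],
        temporal_graph.weights[None],
        spectral_graph.node_features[None],
        spectral_graph.weights[None],
    )[0])
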