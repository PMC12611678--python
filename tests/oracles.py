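"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is written with explicit loops and textbook formulas, sharing
no code path with the package implementation it checks.
"""

import math

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps


def pearson_windows_oracle(z, length, step, eps):
    """Per-window Pearson correlations, explicit loops."""
    c, t = z.shape
    k = (t - length) // step + 1
    out = np.zeros((k, c, c))
    for w in range(k):
        seg = z[:, w * step : w * step + length]
        for i in range(c):
            for j in range(c):
                xi = seg[i] - seg[i].mean()
                xj = seg[j] - seg[j].mean()
                cov = (xi * xj).mean()
                out[w, i, j] = cov / (seg[i].std() * seg[j].std() + eps)
    return out


def temporal_weights_oracle(z, length, step, eps):
    w = pearson_windows_oracle(z, length, step, eps).mean(axis=0)
    np.fill_diagonal(w, 0.0)
    return w


def wpli_oracle(epoch, fs, segment_len, overlap, band):
    """Pooled-imaginary-cross-spectrum wPLI, explicit loops per pair."""
    c, t = epoch.shape
    step = int(round(segment_len * (1 - overlap)))
    window = sps.get_window("hann", segment_len)
    freqs = sfft.rfftfreq(segment_len, 1.0 / fs)
    bins = [b for b in range(len(freqs)) if band[0] <= freqs[b] <= band[1]]
    out = np.zeros((c, c))
    for i in range(c):
        for j in range(c):
            if i == j:
                continue
            ims = []
            for start in range(0, t - segment_len + 1, step):
                si = epoch[i, start : start + segment_len]
                sj = epoch[j, start : start + segment_len]
                fi = np.fft.rfft((si - si.mean()) * window)
                fj = np.fft.rfft((sj - sj.mean()) * window)
                cross = fi * np.conj(fj)
                for b in bins:
                    ims.append(cross[b].imag)
            ims = np.asarray(ims)
            denom = np.abs(ims).mean()
            out[i, j] = abs(ims.mean()) / denom if denom > 0 else 0.0
    return out


def ecc_oracle(nodes, weights, params, modality, d):
    """Explicit double-loop edge-conditioned message passing (incl. MLP,
    mean aggregation over j != i, ReLU and LayerNorm)."""
    w1 = params[f"ecc.{modality}.w1"].data
    b1 = params[f"ecc.{modality}.b1"].data
    w2 = params[f"ecc.{modality}.w2"].data
    b2 = params[f"ecc.{modality}.b2"].data
    g = params[f"ecc.{modality}.ln.gamma"].data
    b = params[f"ecc.{modality}.ln.beta"].data
    c = nodes.shape[0]
    out = np.zeros((c, d))
    for i in range(c):
        acc = np.zeros(d)
        for j in range(c):
            if j == i:
                continue
            h = np.maximum(weights[i, j] * w1[0] + b1, 0.0)
            kernel = (h @ w2 + b2).reshape(d, d)
            acc += kernel @ nodes[j]
        acc = np.maximum(acc / (c - 1), 0.0)
        normed = (acc - acc.mean()) / np.sqrt(acc.var() + 1e-5)
        out[i] = normed * g + b
    return out


def region_pool_oracle(nodes, region_indices, params, modality, region_names):
    """Softmax-weighted sums per region, explicit loops."""
    features, alphas = [], {}
    for region in region_names:
        idx = region_indices[region]
        w = params[f"pool.{modality}.{region}"].data
        scores = np.array([nodes[i] @ w for i in idx])
        e = np.exp(scores - scores.max())
        alpha = e / e.sum()
        features.append(sum(a * nodes[i] for a, i in zip(alpha, idx)))
        alphas[region] = alpha
    return np.stack(features), alphas


def attention_oracle(u_q, u_kv, wq, wk, wv, wo, n_heads):
    """Per-head dense scaled-dot-product cross-attention."""
    r, d = u_q.shape
    dh = d // n_heads
    q = u_q @ wq
    k = u_kv @ wk
    v = u_kv @ wv
    heads = []
    for h in range(n_heads):
        sl = slice(h * dh, (h + 1) * dh)
        scores = q[:, sl] @ k[:, sl].T / math.sqrt(dh)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        att = e / e.sum(axis=1, keepdims=True)
        heads.append(att @ v[:, sl])
    return np.concatenate(heads, axis=1) @ wo


def auc_pairwise_oracle(scores, labels):
    """Brute-force O(P*N) concordance probability, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
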