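"""Lightweight attention-fusion CNN for binary slice classification.

Architecture: three depthwise-separable convolution (DSC) blocks — each a
3×3 per-channel depthwise filter composed with a 1×1 pointwise channel
mixer, then ReLU and 2×2 max-pooling — whose pooled outputs are flattened,
densely projected into a shared 32-dimensional latent space, and
standardized per vector. A shared two-layer perceptron scores each block's
vector with one logit; a softmax over the three logits yields attention
weights on the 2-simplex; the weighted sum of the three vectors feeds a
single sigmoid unit. The attention weights are exposed per item so the
low/mid/high feature-level contributions can be interpreted.

The whole network is implemented in NumPy (float64) with explicit
backpropagation and a seeded Adam/binary-cross-entropy trainer, making
every forward pass, gradient, and training run bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np

__all__ = [
    "ModelConfig",
    "AttentionWeights",
    "AttentionScorer",
    "AttentionFusionNet",
    "TrainingHistory",
    "dsc_forward",
    "attention_fuse",
    "build_model",
    "train",
    "save_model",
    "load_model",
    "block_output_sides",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (reference configuration by default)."""

    input_size: tuple[int, int, int] = (150, 150, 3)
    block_filters: tuple[int, int, int] = (32, 64, 128)
    kernel: int = 3
    pool: int = 2
    projection_dim: int = 32
    attention_hidden: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_filters) != 3:
            raise ValueError("exactly three blocks are required")
        if any(n <= 0 for n in self.block_filters):
            raise ValueError("block_filters must be strictly positive")
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd ('same' padding)")
        h, w, c = self.input_size
        if min(block_output_sides((h, w, c), self.pool)[-1]) < 1:
            raise ValueError(
                f"input {h}×{w} too small to survive three {self.pool}×"
                f"{self.pool} pools")


def block_output_sides(input_size: tuple[int, int, int],
                       pool: int = 2) -> list[tuple[int, int]]:
    """Spatial sides after each block's pool (floor semantics on odd sides)."""
    h, w = input_size[0], input_size[1]
    sides = []
    for _ in range(3):
        h, w = h // pool, w // pool
        sides.append((h, w))
    return sides


@dataclass(frozen=True)
class AttentionWeights:
    """Softmax attention over the three feature levels; sums to one."""

    low: float
    mid: float
    high: float

    def as_array(self) -> np.ndarray:
        return np.array([self.low, self.mid, self.high])


# ---------------------------------------------------------------------------
# primitive layers (forward + backward)
# ---------------------------------------------------------------------------

def _depthwise(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """'same'-padded depthwise conv: one k×k filter per input channel.

    ``x``: (B, H, W, C); ``w``: (k, k, C).
    """
    k = w.shape[0]
    p = k // 2
    B, H, W, C = x.shape
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    out = np.zeros_like(x)
    for dy in range(k):
        for dx in range(k):
            out += xp[:, dy:dy + H, dx:dx + W, :] * w[dy, dx]
    return out


def _depthwise_backward(x, w, g):
    k = w.shape[0]
    p = k // 2
    B, H, W, C = x.shape
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    gw = np.zeros_like(w)
    gxp = np.zeros_like(xp)
    for dy in range(k):
        for dx in range(k):
            gw[dy, dx] = np.einsum("bhwc,bhwc->c",
                                   xp[:, dy:dy + H, dx:dx + W, :], g)
            gxp[:, dy:dy + H, dx:dx + W, :] += g * w[dy, dx]
    return gxp[:, p:p + H, p:p + W, :], gw


def _pointwise(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """1×1 conv mixing channels M→N. ``w``: (M, N); ``b``: (N,)."""
    return x @ w + b


def dsc_forward(x: np.ndarray, dw_w: np.ndarray, pw_w: np.ndarray,
                pw_b: np.ndarray | None = None) -> np.ndarray:
    """One depthwise-separable convolution: depthwise then pointwise.

    ``x`` may be (H, W, M) or batched (B, H, W, M); the composition is
    linear, equal to a standard convolution whose kernel has the
    rank-1-per-channel structure ``K[:, :, m, n] = dw_w[:, :, m] *
    pw_w[m, n]``.
    """
    squeeze = x.ndim == 3
    xb = x[None] if squeeze else x
    if xb.shape[-1] != dw_w.shape[-1]:
        raise ValueError(
            f"input has {xb.shape[-1]} channels but depthwise kernel expects "
            f"{dw_w.shape[-1]}")
    if dw_w.shape[-1] != pw_w.shape[0]:
        raise ValueError("depthwise/pointwise channel mismatch")
    b = np.zeros(pw_w.shape[1]) if pw_b is None else pw_b
    out = _pointwise(_depthwise(xb, dw_w), pw_w, b)
    return out[0] if squeeze else out


def _maxpool2(x: np.ndarray):
    """2×2 max-pool with floor semantics; returns output and argmax cache."""
    B, H, W, C = x.shape
    H2, W2 = H // 2, W // 2
    v = x[:, :H2 * 2, :W2 * 2, :].reshape(B, H2, 2, W2, 2, C)
    cand = v.transpose(0, 1, 3, 5, 2, 4).reshape(B, H2, W2, C, 4)
    idx = cand.argmax(axis=-1)
    out = np.take_along_axis(cand, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _maxpool2_backward(g: np.ndarray, cache) -> np.ndarray:
    idx, shape = cache
    B, H, W, C = shape
    H2, W2 = H // 2, W // 2
    gcand = np.zeros((B, H2, W2, C, 4), dtype=g.dtype)
    np.put_along_axis(gcand, idx[..., None], g[..., None], axis=-1)
    gx = np.zeros(shape, dtype=g.dtype)
    gx[:, :H2 * 2, :W2 * 2, :] = (
        gcand.reshape(B, H2, W2, C, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(B, H2 * 2, W2 * 2, C))
    return gx


_EPS = 1e-6


def _standardize(v: np.ndarray):
    """Per-vector standardization (mean 0, unit scale) along the last axis."""
    mu = v.mean(axis=-1, keepdims=True)
    u = v - mu
    s = np.sqrt((u ** 2).mean(axis=-1, keepdims=True))
    y = u / (s + _EPS)
    return y, (u, s)


def _standardize_backward(g: np.ndarray, cache) -> np.ndarray:
    u, s = cache
    d = u.shape[-1]
    sig = s + _EPS
    gu = (g - g.mean(axis=-1, keepdims=True)) / sig
    proj = (g * u).sum(axis=-1, keepdims=True)
    gu -= u * proj / (d * np.maximum(s, 1e-12) * sig ** 2)
    return gu


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class AttentionScorer:
    """Shared two-layer perceptron scoring one logit per feature level."""

    w1: np.ndarray  # (D, hidden)
    b1: np.ndarray
    w2: np.ndarray  # (hidden, 1)
    b2: np.ndarray

    def logits(self, f: np.ndarray) -> np.ndarray:
        """``f``: (..., 3, D) → logits (..., 3)."""
        h = np.maximum(f @ self.w1 + self.b1, 0.0)
        return (h @ self.w2)[..., 0] + self.b2[0]


def attention_fuse(f_low: np.ndarray, f_mid: np.ndarray, f_high: np.ndarray,
                   scorer: AttentionScorer):
    """Softmax-weighted fusion of the three feature-level vectors.

    Returns ``(fused, AttentionWeights)`` for single vectors, or
    ``(fused, (B, 3) weight array)`` for batched (B, D) inputs.
    """
    if not (f_low.shape == f_mid.shape == f_high.shape):
        raise ValueError("feature vectors must share one shape")
    single = f_low.ndim == 1
    f = np.stack([f_low, f_mid, f_high], axis=-2)  # (..., 3, D)
    w = _softmax(scorer.logits(f))
    fused = (w[..., None] * f).sum(axis=-2)
    if single:
        return fused, AttentionWeights(*(float(x) for x in w))
    return fused, w


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class AttentionFusionNet:
    """Three DSC blocks + attention fusion + sigmoid head (pure NumPy).

    ``dtype`` selects the arithmetic precision: float64 by default (used
    by all correctness checks), float32 for faster training at scale.
    """

    def __init__(self, cfg: ModelConfig, dtype=np.float64) -> None:
        self.cfg = cfg
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(cfg.seed)
        h, w, c_in = cfg.input_size
        k, d = cfg.kernel, cfg.projection_dim
        p: dict[str, np.ndarray] = {}
        m = c_in
        side = (h, w)
        self._flat_dims: list[int] = []
        for i, n in enumerate(cfg.block_filters, start=1):
            p[f"dw{i}_w"] = rng.normal(0, np.sqrt(2.0 / (k * k)), (k, k, m))
            p[f"pw{i}_w"] = rng.normal(0, np.sqrt(2.0 / m), (m, n))
            p[f"pw{i}_b"] = np.zeros(n)
            side = (side[0] // cfg.pool, side[1] // cfg.pool)
            flat = side[0] * side[1] * n
            self._flat_dims.append(flat)
            p[f"proj{i}_w"] = rng.normal(0, np.sqrt(2.0 / flat), (flat, d))
            p[f"proj{i}_b"] = np.zeros(d)
            m = n
        hid = cfg.attention_hidden
        p["attn_w1"] = rng.normal(0, np.sqrt(2.0 / d), (d, hid))
        p["attn_b1"] = np.zeros(hid)
        p["attn_w2"] = rng.normal(0, np.sqrt(2.0 / hid), (hid, 1))
        p["attn_b2"] = np.zeros(1)
        p["head_w"] = rng.normal(0, np.sqrt(1.0 / d), (d, 1))
        p["head_b"] = np.zeros(1)
        self.params = {k: v.astype(self.dtype) for k, v in p.items()}

    # -- forward ------------------------------------------------------------

    @property
    def scorer(self) -> AttentionScorer:
        p = self.params
        return AttentionScorer(p["attn_w1"], p["attn_b1"],
                               p["attn_w2"], p["attn_b2"])

    def _check_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != tuple(self.cfg.input_size):
            raise ValueError(
                f"batch items of shape {x.shape[1:]} do not match model "
                f"input {tuple(self.cfg.input_size)}")
        return x

    def forward(self, x: np.ndarray, cache: bool = False):
        """Return ``(probabilities, attention weights (B, 3))``."""
        x = self._check_batch(x)
        p = self.params
        caches = {"x0": x}
        feats = []
        cur = x
        for i in range(1, 4):
            z_dw = _depthwise(cur, p[f"dw{i}_w"])
            z = _pointwise(z_dw, p[f"pw{i}_w"], p[f"pw{i}_b"])
            a = np.maximum(z, 0.0)
            pooled, pc = _maxpool2(a)
            flat = pooled.reshape(pooled.shape[0], -1)
            proj = flat @ p[f"proj{i}_w"] + p[f"proj{i}_b"]
            norm, sc = _standardize(proj)
            feats.append(norm)
            caches[f"b{i}"] = (cur, z_dw, z, pc, pooled.shape, flat, sc)
            cur = pooled
        f = np.stack(feats, axis=1)  # (B, 3, D)
        h = f @ p["attn_w1"] + p["attn_b1"]
        hr = np.maximum(h, 0.0)
        logits = (hr @ p["attn_w2"])[..., 0] + p["attn_b2"][0]
        wts = _softmax(logits)
        fused = (wts[..., None] * f).sum(axis=1)
        zout = (fused @ p["head_w"])[:, 0] + p["head_b"][0]
        prob = 1.0 / (1.0 + np.exp(-zout))
        caches.update(f=f, h=h, hr=hr, wts=wts, fused=fused, prob=prob)
        if cache:
            return prob, wts, caches
        return prob, wts

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def predict(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(x) >= threshold).astype(int)

    # -- backward -----------------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean binary cross-entropy and its gradients w.r.t. every parameter."""
        y = np.asarray(y, dtype=self.dtype)
        prob, wts, c = self.forward(x, cache=True)
        B = y.shape[0]
        eps = 1e-12
        loss = float(-np.mean(y * np.log(prob + eps)
                              + (1 - y) * np.log(1 - prob + eps)))
        p = self.params
        g: dict[str, np.ndarray] = {}

        dz = (prob - y) / B                                  # (B,)
        fused = c["fused"]
        g["head_w"] = fused.T @ dz[:, None]
        g["head_b"] = np.array([dz.sum()])
        g_fused = dz[:, None] @ p["head_w"].T                # (B, D)

        f = c["f"]                                           # (B, 3, D)
        # fused = sum_b w_b f_b
        g_w = np.einsum("bd,bkd->bk", g_fused, f)            # (B, 3)
        g_f = wts[..., None] * g_fused[:, None, :]           # via fusion
        # softmax backward
        g_logits = wts * (g_w - (wts * g_w).sum(axis=1, keepdims=True))
        # scorer backward (shared weights: sum over batch and block axes)
        hr = c["hr"]
        g_hr = g_logits[..., None] * p["attn_w2"][None, None, :, 0]
        g["attn_w2"] = np.einsum("bkh,bk->h", hr, g_logits)[:, None]
        g["attn_b2"] = np.array([g_logits.sum()])
        g_h = g_hr * (c["h"] > 0)
        g["attn_w1"] = np.einsum("bkd,bkh->dh", f, g_h)
        g["attn_b1"] = g_h.sum(axis=(0, 1))
        g_f = g_f + g_h @ p["attn_w1"].T

        g_pooled_next: np.ndarray | None = None
        for i in range(3, 0, -1):
            cur, z_dw, z, pc, pooled_shape, flat, sc = c[f"b{i}"]
            gf_i = _standardize_backward(g_f[:, i - 1, :], sc)
            g[f"proj{i}_w"] = flat.T @ gf_i
            g[f"proj{i}_b"] = gf_i.sum(axis=0)
            g_flat = gf_i @ p[f"proj{i}_w"].T
            g_pooled = g_flat.reshape(pooled_shape)
            if g_pooled_next is not None:
                g_pooled = g_pooled + g_pooled_next
            g_a = _maxpool2_backward(g_pooled, pc)
            g_z = g_a * (z > 0)
            g[f"pw{i}_b"] = g_z.sum(axis=(0, 1, 2))
            g[f"pw{i}_w"] = np.einsum("bhwm,bhwn->mn", z_dw, g_z)
            g_zdw = g_z @ p[f"pw{i}_w"].T
            g_cur, g[f"dw{i}_w"] = _depthwise_backward(cur, p[f"dw{i}_w"],
                                                       g_zdw)
            g_pooled_next = g_cur
        return loss, g


def build_model(cfg: ModelConfig, dtype=np.float64) -> AttentionFusionNet:
    """Construct the network with seeded weight initialization."""
    return AttentionFusionNet(cfg, dtype=dtype)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainingHistory:
    """Per-epoch mean training loss (one entry per epoch)."""

    losses: list[float] = field(default_factory=list)


def train(model: AttentionFusionNet, x: np.ndarray, y: np.ndarray,
          lr: float = 1e-3, epochs: int = 20, batch_size: int = 32,
          seed: int = 0) -> TrainingHistory:
    """Adam / binary cross-entropy training, fully seeded.

    ``x``: (N, H, W, C); ``y``: binary labels (N,). Shuffling and the
    optimizer state derive only from ``seed`` and the model's weights, so
    equal inputs reproduce identical loss histories and final weights.
    """
    y = np.asarray(y, dtype=model.dtype)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes to be present")
    x = np.asarray(x, dtype=model.dtype)
    rng = np.random.default_rng(seed)
    p = model.params
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(w) for k, w in p.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = TrainingHistory()
    n = x.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss, grads = model.loss_and_grads(x[idx], y[idx])
            epoch_losses.append(loss)
            t += 1
            for k, gk in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * gk
                v[k] = b2 * v[k] + (1 - b2) * gk ** 2
                mhat = m[k] / (1 - b1 ** t)
                vhat = v[k] / (1 - b2 ** t)
                p[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        history.losses.append(float(np.mean(epoch_losses)))
    return history


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model: AttentionFusionNet, path: str | Path) -> Path:
    """Save weights as ``.npz`` with a JSON sidecar of the ModelConfig."""
    path = Path(path)
    np.savez(path, **model.params)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(asdict(model.cfg), indent=2))
    return path


def load_model(path: str | Path) -> AttentionFusionNet:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    raw = json.loads(sidecar.read_text())
    raw["input_size"] = tuple(raw["input_size"])
    raw["block_filters"] = tuple(raw["block_filters"])
    model = AttentionFusionNet(ModelConfig(**raw))
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as f:
        for k in model.params:
            model.params[k] = f[k]
    return model
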