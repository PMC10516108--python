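"""Minimal transformer-decoder (GPT) implemented in NumPy.

Forward and backward passes are hand-written; the model is small enough
(desk-scale profiles) that NumPy matmuls on one CPU are adequate. Layout:

    token-emb + pos-emb -> [LN -> causal MHA -> +res -> LN -> MLP -> +res] x B
    -> LN -> linear head (no bias)

Dropout is applied after the attention projection and after the MLP
projection (i.e. after each feed-forward network, not on the output head).
Weights are N(0, init_std^2); layer-norm gains 1; biases 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LN_EPS = 1e-5
_GELU_C = 0.7978845608028654  # sqrt(2/pi)


@dataclass
class GPTConfig:
    vocab_size: int
    context_length: int
    embed_dim: int = 256
    n_blocks: int = 8
    n_heads: int = 8
    dropout: float = 0.10
    init_std: float = 0.02
    layernorm_init: float = 1.0
    bias_init: float = 0.0

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads


def _gelu_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GELU (tanh approximation); returns (value, tanh-term) for reuse in backward."""
    t = np.tanh(_GELU_C * (x + 0.044715 * (x * x * x)))
    return 0.5 * x * (1.0 + t), t


def _gelu(x: np.ndarray) -> np.ndarray:
    return _gelu_forward(x)[0]


def _gelu_grad(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """d GELU / dx given the cached tanh term ``t``."""
    du = _GELU_C * (1.0 + 3 * 0.044715 * (x * x))
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du


def _layernorm_forward(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_backward(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    return dx, dg, db


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class GPT:
    """Parameter container plus forward/backward/step logic."""

    LINEAR_WEIGHTS = ("qkv_w", "proj_w", "fc_w", "out_w", "head_w")

    def __init__(self, config: GPTConfig, seed: int):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        p: dict[str, np.ndarray] = {}

        def w(*shape):
            return rng.normal(0.0, c.init_std, size=shape).astype(np.float32)

        p["wte"] = w(c.vocab_size, c.embed_dim)
        p["wpe"] = w(c.context_length, c.embed_dim)
        for i in range(c.n_blocks):
            p[f"b{i}.ln1_g"] = np.full(c.embed_dim, c.layernorm_init, np.float32)
            p[f"b{i}.ln1_b"] = np.full(c.embed_dim, c.bias_init, np.float32)
            p[f"b{i}.qkv_w"] = w(c.embed_dim, 3 * c.embed_dim)
            p[f"b{i}.qkv_b"] = np.full(3 * c.embed_dim, c.bias_init, np.float32)
            p[f"b{i}.proj_w"] = w(c.embed_dim, c.embed_dim)
            p[f"b{i}.proj_b"] = np.full(c.embed_dim, c.bias_init, np.float32)
            p[f"b{i}.ln2_g"] = np.full(c.embed_dim, c.layernorm_init, np.float32)
            p[f"b{i}.ln2_b"] = np.full(c.embed_dim, c.bias_init, np.float32)
            p[f"b{i}.fc_w"] = w(c.embed_dim, 4 * c.embed_dim)
            p[f"b{i}.fc_b"] = np.full(4 * c.embed_dim, c.bias_init, np.float32)
            p[f"b{i}.out_w"] = w(4 * c.embed_dim, c.embed_dim)
            p[f"b{i}.out_b"] = np.full(c.embed_dim, c.bias_init, np.float32)
        p["lnf_g"] = np.full(c.embed_dim, c.layernorm_init, np.float32)
        p["lnf_b"] = np.full(c.embed_dim, c.bias_init, np.float32)
        p["head_w"] = w(c.embed_dim, c.vocab_size)
        self.params = p

    # ------------------------------------------------------------------ #
    # training forward / backward
    # ------------------------------------------------------------------ #

    def _attention_forward(self, x, i, mask):
        c, p = self.config, self.params
        B, T, d = x.shape
        qkv = x @ p[f"b{i}.qkv_w"] + p[f"b{i}.qkv_b"]
        q, k, v = np.split(qkv, 3, axis=-1)

        def heads(z):  # (B,T,d) -> (B,nh,T,hd)
            return z.reshape(B, T, c.n_heads, c.head_dim).transpose(0, 2, 1, 3)

        q, k, v = heads(q), heads(k), heads(v)
        att = q @ k.transpose(0, 1, 3, 2) / np.sqrt(c.head_dim)
        att = np.where(mask[:T, :T], att, -np.inf)
        att = _softmax(att)
        y = att @ v  # (B,nh,T,hd)
        y = y.transpose(0, 2, 1, 3).reshape(B, T, d)
        out = y @ p[f"b{i}.proj_w"] + p[f"b{i}.proj_b"]
        return out, (x, q, k, v, att, y)

    def _attention_backward(self, dout, i, cache, grads):
        c, p = self.config, self.params
        x, q, k, v, att, y = cache
        B, T, d = x.shape
        grads[f"b{i}.proj_w"] += y.reshape(-1, d).T @ dout.reshape(-1, d)
        grads[f"b{i}.proj_b"] += dout.sum((0, 1))
        dy = (dout @ p[f"b{i}.proj_w"].T).reshape(B, T, c.n_heads, c.head_dim)
        dy = dy.transpose(0, 2, 1, 3)  # (B,nh,T,hd)
        datt = dy @ v.transpose(0, 1, 3, 2)
        dv = att.transpose(0, 1, 3, 2) @ dy
        # softmax backward
        ds = att * (datt - (datt * att).sum(-1, keepdims=True))
        ds /= np.sqrt(c.head_dim)
        dq = ds @ k
        dk = ds.transpose(0, 1, 3, 2) @ q

        def merge(z):  # (B,nh,T,hd) -> (B,T,d)
            return z.transpose(0, 2, 1, 3).reshape(B, T, d)

        dqkv = np.concatenate([merge(dq), merge(dk), merge(dv)], axis=-1)
        grads[f"b{i}.qkv_w"] += x.reshape(-1, d).T @ dqkv.reshape(-1, 3 * d)
        grads[f"b{i}.qkv_b"] += dqkv.sum((0, 1))
        return dqkv @ p[f"b{i}.qkv_w"].T

    def forward_backward(self, idx, targets, pad_index, rng=None):
        """One training step's loss and parameter gradients.

        Targets equal to ``pad_index`` are excluded from the loss. ``rng``
        enables dropout (training mode); None disables it.
        """
        c, p = self.config, self.params
        B, T = idx.shape
        mask = np.tril(np.ones((T, T), dtype=bool))
        drop = c.dropout if rng is not None else 0.0

        x = p["wte"][idx] + p["wpe"][:T]
        caches = []
        for i in range(c.n_blocks):
            h1, ln1c = _layernorm_forward(x, p[f"b{i}.ln1_g"], p[f"b{i}.ln1_b"])
            a, ac = self._attention_forward(h1, i, mask)
            if drop > 0:
                m1 = (rng.random(a.shape) >= drop) / (1 - drop)
                a = a * m1
            else:
                m1 = None
            x1 = x + a
            h2, ln2c = _layernorm_forward(x1, p[f"b{i}.ln2_g"], p[f"b{i}.ln2_b"])
            z = h2 @ p[f"b{i}.fc_w"] + p[f"b{i}.fc_b"]
            g, tz = _gelu_forward(z)
            mlp = g @ p[f"b{i}.out_w"] + p[f"b{i}.out_b"]
            if drop > 0:
                m2 = (rng.random(mlp.shape) >= drop) / (1 - drop)
                mlp = mlp * m2
            else:
                m2 = None
            x2 = x1 + mlp
            caches.append((ln1c, ac, m1, x1, ln2c, h2, z, tz, g, m2))
            x = x2
        hf, lnfc = _layernorm_forward(x, p["lnf_g"], p["lnf_b"])
        logits = hf @ p["head_w"]

        # masked token-level cross-entropy
        valid = targets != pad_index
        n_valid = int(valid.sum())
        probs = _softmax(logits)
        eps = 1e-12
        tgt_probs = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
        loss = float(-(np.log(tgt_probs + eps) * valid).sum() / max(n_valid, 1))

        # backward
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = probs.copy()
        np.put_along_axis(
            dlogits,
            targets[..., None],
            np.take_along_axis(dlogits, targets[..., None], axis=-1) - 1.0,
            axis=-1,
        )
        dlogits *= valid[..., None] / max(n_valid, 1)

        d = c.embed_dim
        grads["head_w"] += hf.reshape(-1, d).T @ dlogits.reshape(-1, c.vocab_size)
        dhf = dlogits @ p["head_w"].T
        dx, dg_, db_ = _layernorm_backward(dhf, lnfc)
        grads["lnf_g"] += dg_
        grads["lnf_b"] += db_

        for i in reversed(range(c.n_blocks)):
            ln1c, ac, m1, x1, ln2c, h2, z, tz, g, m2 = caches[i]
            dmlp = dx * m2 if m2 is not None else dx
            grads[f"b{i}.out_w"] += g.reshape(-1, 4 * d).T @ dmlp.reshape(-1, d)
            grads[f"b{i}.out_b"] += dmlp.sum((0, 1))
            dgelu = dmlp @ p[f"b{i}.out_w"].T
            dz = dgelu * _gelu_grad(z, tz)
            grads[f"b{i}.fc_w"] += h2.reshape(-1, d).T @ dz.reshape(-1, 4 * d)
            grads[f"b{i}.fc_b"] += dz.sum((0, 1))
            dh2 = dz @ p[f"b{i}.fc_w"].T
            dx1, dg_, db_ = _layernorm_backward(dh2, ln2c)
            grads[f"b{i}.ln2_g"] += dg_
            grads[f"b{i}.ln2_b"] += db_
            dx1 = dx1 + dx  # residual
            da = dx1 * m1 if m1 is not None else dx1
            dh1 = self._attention_backward(da, i, ac, grads)
            dx0, dg_, db_ = _layernorm_backward(dh1, ln1c)
            grads[f"b{i}.ln1_g"] += dg_
            grads[f"b{i}.ln1_b"] += db_
            dx = dx0 + dx1  # residual

        grads["wpe"][:T] += dx.sum(0)
        np.add.at(grads["wte"], idx.reshape(-1), dx.reshape(-1, d))
        return loss, grads

    def loss(self, idx, targets, pad_index) -> float:
        """Evaluation-mode mean cross-entropy (no dropout, no gradients)."""
        logits = self.logits(idx)
        valid = targets != pad_index
        probs = _softmax(logits)
        tgt = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
        return float(-(np.log(tgt + 1e-12) * valid).sum() / max(int(valid.sum()), 1))

    def logits(self, idx: np.ndarray) -> np.ndarray:
        """Full-sequence logits in evaluation mode (no dropout)."""
        c, p = self.config, self.params
        B, T = idx.shape
        mask = np.tril(np.ones((T, T), dtype=bool))
        x = p["wte"][idx] + p["wpe"][:T]
        for i in range(c.n_blocks):
            h1, _ = _layernorm_forward(x, p[f"b{i}.ln1_g"], p[f"b{i}.ln1_b"])
            a, _ = self._attention_forward(h1, i, mask)
            x = x + a
            h2, _ = _layernorm_forward(x, p[f"b{i}.ln2_g"], p[f"b{i}.ln2_b"])
            z = h2 @ p[f"b{i}.fc_w"] + p[f"b{i}.fc_b"]
            x = x + _gelu(z) @ p[f"b{i}.out_w"] + p[f"b{i}.out_b"]
        hf, _ = _layernorm_forward(x, p["lnf_g"], p["lnf_b"])
        return hf @ p["head_w"]

    # ------------------------------------------------------------------ #
    # incremental (KV-cached) sampling
    # ------------------------------------------------------------------ #

    def init_cache(self, batch: int) -> dict:
        c = self.config
        return {
            "t": 0,
            "k": [
                np.empty((batch, c.n_heads, c.context_length, c.head_dim), np.float32)
                for _ in range(c.n_blocks)
            ],
            "v": [
                np.empty((batch, c.n_heads, c.context_length, c.head_dim), np.float32)
                for _ in range(c.n_blocks)
            ],
        }

    def step(self, tokens: np.ndarray, cache: dict) -> np.ndarray:
        """Advance one position for a batch of sequences; returns (B, V) logits."""
        c, p = self.config, self.params
        B = tokens.shape[0]
        t = cache["t"]
        x = p["wte"][tokens] + p["wpe"][t]  # (B, d)
        for i in range(c.n_blocks):
            h1, _ = _layernorm_forward(x, p[f"b{i}.ln1_g"], p[f"b{i}.ln1_b"])
            qkv = h1 @ p[f"b{i}.qkv_w"] + p[f"b{i}.qkv_b"]
            q, k, v = np.split(qkv, 3, axis=-1)
            q = q.reshape(B, c.n_heads, c.head_dim)
            cache["k"][i][:, :, t] = k.reshape(B, c.n_heads, c.head_dim)
            cache["v"][i][:, :, t] = v.reshape(B, c.n_heads, c.head_dim)
            K = cache["k"][i][:, :, : t + 1]
            V = cache["v"][i][:, :, : t + 1]
            att = _softmax((K @ q[..., None])[..., 0] / np.sqrt(c.head_dim))
            y = (att[:, :, None, :] @ V)[:, :, 0]  # (B, nh, hd)
            a = y.reshape(B, c.embed_dim) @ p[f"b{i}.proj_w"] + p[f"b{i}.proj_b"]
            x = x + a
            h2, _ = _layernorm_forward(x, p[f"b{i}.ln2_g"], p[f"b{i}.ln2_b"])
            z = h2 @ p[f"b{i}.fc_w"] + p[f"b{i}.fc_b"]
            x = x + _gelu(z) @ p[f"b{i}.out_w"] + p[f"b{i}.out_b"]
        cache["t"] = t + 1
        hf, _ = _layernorm_forward(x, p["lnf_g"], p["lnf_b"])
        return hf @ p["head_w"]


class AdamW:
    """Adam with decoupled weight decay restricted to linear-layer weights."""

    def __init__(self, params, betas=(0.965, 0.99), weight_decay=0.1, eps=1e-8):
        self.betas = betas
        self.weight_decay = weight_decay
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    @staticmethod
    def is_linear_weight(name: str) -> bool:
        return name.split(".")[-1] in GPT.LINEAR_WEIGHTS

    def step(self, params, grads, lr: float, clip_norm: float | None = None):
        if clip_norm is not None:
            total = float(np.sqrt(sum(float((g**2).sum()) for g in grads.values())))
            if total > clip_norm:
                scale = clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        b1, b2 = self.betas
        self.t += 1
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            update = (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)
            if self.weight_decay and self.is_linear_weight(k):
                params[k] -= lr * self.weight_decay * params[k]
            params[k] -= lr * update
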