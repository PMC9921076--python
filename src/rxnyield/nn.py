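"""A compact NumPy transformer encoder with hand-written backprop.

The encoder follows the post-layer-norm BERT block layout.  Its embedding is
the SUM of three learned tables — token, position, and Equivalent Id — which
is the architectural hook for condition enrichment: the Equivalent-Id table
adds role / molar-ratio-class information to every token vector.  Row 0 of
that table (the null id) is pinned at exactly zero, so a sequence whose ids
are all null passes through the network as if the enriched layer did not
exist; this is what makes null-id pretraining and enriched fine-tuning share
one set of weights.

Everything is dense float32 by default (float64 available for gradient
checking).  Heads: masked-token prediction (cross-entropy), a bounded
regression head (sigmoid-squashed scalar, squared error against {0,1}
labels), and a two-way softmax classification head for comparison.
"""

from __future__ import annotations

import numpy as np

_NEG_INF = -1e9


def gelu(x: np.ndarray) -> np.ndarray:
    # tanh approximation; the derivative below matches it exactly
    c = np.sqrt(2.0 / np.pi).astype(x.dtype) if hasattr(x, "dtype") else np.sqrt(2 / np.pi)
    u = c * (x + 0.044715 * x**3)
    return 0.5 * x * (1.0 + np.tanh(u))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    c = np.sqrt(2.0 / np.pi)
    u = c * (x + 0.044715 * x**3)
    t = np.tanh(u)
    du = c * (1.0 + 3 * 0.044715 * x**2)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * du


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def layernorm_forward(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def layernorm_backward(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def init_encoder_params(
    vocab_size: int,
    n_equivalent_ids: int,
    max_len: int,
    hidden: int,
    n_layers: int,
    ffn: int,
    rng: np.random.Generator,
    dtype=np.float32,
) -> dict[str, np.ndarray]:
    """Gaussian(0, 0.02) init as in BERT; null equivalent row pinned to 0."""
    s = 0.02

    def w(*shape):
        return rng.normal(0.0, s, size=shape).astype(dtype)

    p = {
        "tok_emb": w(vocab_size, hidden),
        "pos_emb": w(max_len, hidden),
        "eq_emb": w(n_equivalent_ids, hidden),
        "ln_emb_g": np.ones(hidden, dtype=dtype),
        "ln_emb_b": np.zeros(hidden, dtype=dtype),
    }
    p["eq_emb"][0] = 0.0
    for l in range(n_layers):
        for name in ("wq", "wk", "wv", "wo"):
            p[f"l{l}_{name}"] = w(hidden, hidden)
            p[f"l{l}_b{name[1]}"] = np.zeros(hidden, dtype=dtype)
        p[f"l{l}_ln1_g"] = np.ones(hidden, dtype=dtype)
        p[f"l{l}_ln1_b"] = np.zeros(hidden, dtype=dtype)
        p[f"l{l}_w1"] = w(hidden, ffn)
        p[f"l{l}_b1"] = np.zeros(ffn, dtype=dtype)
        p[f"l{l}_w2"] = w(ffn, hidden)
        p[f"l{l}_b2"] = np.zeros(hidden, dtype=dtype)
        p[f"l{l}_ln2_g"] = np.ones(hidden, dtype=dtype)
        p[f"l{l}_ln2_b"] = np.zeros(hidden, dtype=dtype)
    return p


def _dropout(x, rate, rng):
    if rate <= 0.0 or rng is None:
        return x, None
    keep = (rng.random(x.shape) >= rate).astype(x.dtype)
    scale = np.asarray(1.0 / (1.0 - rate), dtype=x.dtype)
    return x * keep * scale, keep * scale


def encoder_forward(
    params: dict,
    tok_ids: np.ndarray,
    eq_ids: np.ndarray,
    pad_mask: np.ndarray,
    n_layers: int,
    n_heads: int,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    use_enriched: bool = True,
):
    """Run the encoder; returns hidden states (B, T, H) and a backprop cache.

    ``pad_mask`` is True at real positions.  Pass ``rng`` only when training
    (enables dropout).  ``use_enriched=False`` skips the Equivalent-Id table
    entirely — used to verify that null ids are exactly equivalent.
    """
    B, T = tok_ids.shape
    H = params["tok_emb"].shape[1]
    dh = H // n_heads
    scale = np.asarray(1.0 / np.sqrt(dh), dtype=params["tok_emb"].dtype)

    x = params["tok_emb"][tok_ids] + params["pos_emb"][:T][None, :, :]
    if use_enriched:
        x = x + params["eq_emb"][eq_ids]
    x, ln_emb_cache = layernorm_forward(x, params["ln_emb_g"], params["ln_emb_b"])
    x, emb_drop = _dropout(x, dropout, rng)

    attn_bias = np.where(pad_mask[:, None, None, :], 0.0, _NEG_INF).astype(x.dtype)

    caches = []
    for l in range(n_layers):
        x_in = x
        q = x @ params[f"l{l}_wq"] + params[f"l{l}_bq"]
        k = x @ params[f"l{l}_wk"] + params[f"l{l}_bk"]
        v = x @ params[f"l{l}_wv"] + params[f"l{l}_bv"]
        qh = q.reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)
        kh = k.reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)
        vh = v.reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)
        scores = (qh @ kh.transpose(0, 1, 3, 2)) * scale + attn_bias
        p = softmax(scores)
        ctx = (p @ vh).transpose(0, 2, 1, 3).reshape(B, T, H)
        attn_out = ctx @ params[f"l{l}_wo"] + params[f"l{l}_bo"]
        attn_out, attn_drop = _dropout(attn_out, dropout, rng)
        h1, ln1_cache = layernorm_forward(
            x_in + attn_out, params[f"l{l}_ln1_g"], params[f"l{l}_ln1_b"]
        )
        z1 = h1 @ params[f"l{l}_w1"] + params[f"l{l}_b1"]
        a1 = gelu(z1)
        ffn_out = a1 @ params[f"l{l}_w2"] + params[f"l{l}_b2"]
        ffn_out, ffn_drop = _dropout(ffn_out, dropout, rng)
        x, ln2_cache = layernorm_forward(
            h1 + ffn_out, params[f"l{l}_ln2_g"], params[f"l{l}_ln2_b"]
        )
        caches.append(
            (x_in, qh, kh, vh, p, ctx, attn_drop, ln1_cache, h1, z1, a1, ffn_drop, ln2_cache)
        )
    cache = {
        "tok_ids": tok_ids,
        "eq_ids": eq_ids,
        "ln_emb": ln_emb_cache,
        "emb_drop": emb_drop,
        "layers": caches,
        "n_heads": n_heads,
        "use_enriched": use_enriched,
        "scale": scale,
    }
    return x, cache


def encoder_backward(params: dict, dx: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
    """Backprop through the encoder; returns grads keyed like ``params``.

    The null Equivalent-Id row's gradient is zeroed so the row stays pinned.
    """
    B, T, H = dx.shape
    nh = cache["n_heads"]
    dh = H // nh
    scale = cache["scale"]
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    for l in reversed(range(len(cache["layers"]))):
        (x_in, qh, kh, vh, p, ctx, attn_drop, ln1_cache, h1, z1, a1, ffn_drop,
         ln2_cache) = cache["layers"][l]

        dres2, dg, db = layernorm_backward(dx, ln2_cache)
        grads[f"l{l}_ln2_g"] += dg
        grads[f"l{l}_ln2_b"] += db
        dffn_out = dres2 if ffn_drop is None else dres2 * ffn_drop
        grads[f"l{l}_b2"] += dffn_out.sum(axis=(0, 1))
        grads[f"l{l}_w2"] += a1.reshape(-1, a1.shape[-1]).T @ dffn_out.reshape(-1, H)
        da1 = dffn_out @ params[f"l{l}_w2"].T
        dz1 = da1 * gelu_grad(z1)
        grads[f"l{l}_b1"] += dz1.sum(axis=(0, 1))
        grads[f"l{l}_w1"] += h1.reshape(-1, H).T @ dz1.reshape(-1, dz1.shape[-1])
        dh1 = dres2 + dz1 @ params[f"l{l}_w1"].T

        dres1, dg, db = layernorm_backward(dh1, ln1_cache)
        grads[f"l{l}_ln1_g"] += dg
        grads[f"l{l}_ln1_b"] += db
        dattn_out = dres1 if attn_drop is None else dres1 * attn_drop
        grads[f"l{l}_bo"] += dattn_out.sum(axis=(0, 1))
        grads[f"l{l}_wo"] += ctx.reshape(-1, H).T @ dattn_out.reshape(-1, H)
        dctx = (dattn_out @ params[f"l{l}_wo"].T).reshape(B, T, nh, dh).transpose(0, 2, 1, 3)

        dp = dctx @ vh.transpose(0, 1, 3, 2)
        dvh = p.transpose(0, 1, 3, 2) @ dctx
        ds = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
        dqh = (ds @ kh) * scale
        dkh = (ds.transpose(0, 1, 3, 2) @ qh) * scale

        dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, H)
        dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, H)
        dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, H)
        x_flat = x_in.reshape(-1, H)
        for name, d in (("q", dq), ("k", dk), ("v", dv)):
            grads[f"l{l}_w{name}"] += x_flat.T @ d.reshape(-1, H)
            grads[f"l{l}_b{name}"] += d.sum(axis=(0, 1))
        dx = (
            dres1
            + dq @ params[f"l{l}_wq"].T
            + dk @ params[f"l{l}_wk"].T
            + dv @ params[f"l{l}_wv"].T
        )

    if cache["emb_drop"] is not None:
        dx = dx * cache["emb_drop"]
    dx, dg, db = layernorm_backward(dx, cache["ln_emb"])
    grads["ln_emb_g"] += dg
    grads["ln_emb_b"] += db

    np.add.at(grads["tok_emb"], cache["tok_ids"], dx)
    grads["pos_emb"][:T] += dx.sum(axis=0)
    if cache["use_enriched"]:
        np.add.at(grads["eq_emb"], cache["eq_ids"], dx)
        grads["eq_emb"][0] = 0.0  # null row stays pinned at zero
    return grads


# ---------------------------------------------------------------------------
# Heads


def mlm_loss_and_grads(h, params, target_pos, target_ids):
    """Cross-entropy over masked positions.  ``target_pos`` = (rows, cols)."""
    rows, cols = target_pos
    hs = h[rows, cols]  # (M, H)
    logits = hs @ params["mlm_w"] + params["mlm_b"]
    p = softmax(logits)
    M = len(rows)
    loss = -np.mean(np.log(p[np.arange(M), target_ids] + 1e-12))
    dlogits = p
    dlogits[np.arange(M), target_ids] -= 1.0
    dlogits /= M
    grads = {
        "mlm_w": hs.T @ dlogits,
        "mlm_b": dlogits.sum(axis=0),
    }
    dh = np.zeros_like(h)
    dh[rows, cols] = dlogits @ params["mlm_w"].T
    return loss, grads, dh


def mean_pool(h, pad_mask):
    """Mean of the hidden states over real (non-pad) positions.

    Returns the pooled (B, H) matrix and a scatter function mapping a pooled
    gradient back onto the full (B, T, H) states.
    """
    m = pad_mask.astype(h.dtype)
    counts = m.sum(axis=1, keepdims=True)
    pooled = (h * m[:, :, None]).sum(axis=1) / counts

    def scatter(dpooled):
        return (m / counts)[:, :, None] * dpooled[:, None, :]

    return pooled, scatter


def regression_head_forward(pooled, params):
    """Bounded score from the pooled state: sigmoid(w·h + b) in [0, 1]."""
    z = pooled @ params["head_w"] + params["head_b"]
    return 1.0 / (1.0 + np.exp(-z))


def regression_loss_and_grads(pooled, params, y):
    z = pooled @ params["head_w"] + params["head_b"]
    x = 1.0 / (1.0 + np.exp(-z))
    B = len(y)
    loss = np.mean((x - y) ** 2)
    dz = 2.0 * (x - y) * x * (1.0 - x) / B
    grads = {"head_w": pooled.T @ dz,
             "head_b": np.asarray([dz.sum()], dtype=pooled.dtype)}
    dpooled = dz[:, None] * params["head_w"][None, :]
    return loss, grads, dpooled


def classification_head_forward(pooled, params):
    """Two-class softmax probabilities from the pooled state."""
    return softmax(pooled @ params["head_w"] + params["head_b"])


def classification_loss_and_grads(pooled, params, y):
    logits = pooled @ params["head_w"] + params["head_b"]
    p = softmax(logits)
    B = len(y)
    loss = -np.mean(np.log(p[np.arange(B), y] + 1e-12))
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads = {"head_w": pooled.T @ dlogits, "head_b": dlogits.sum(axis=0)}
    dpooled = dlogits @ params["head_w"].T
    return loss, grads, dpooled


# ---------------------------------------------------------------------------
# Optimizer


class Adam:
    """Plain Adam with global-norm gradient clipping."""

    def __init__(self, params: dict, lr: float, clip_norm: float = 5.0,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.clip_norm = clip_norm
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                                for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, g in grads.items():
            if k not in params:
                continue
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            params[k] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
        if "eq_emb" in params:
            params["eq_emb"][0] = 0.0
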