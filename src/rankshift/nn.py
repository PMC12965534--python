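"""A minimal pre-LN transformer encoder in NumPy with manual backpropagation.

Sized for desk-scale corpora (hundreds of genes, thousands of cells): two
layers and a 64-dimensional hidden state train in seconds per epoch on one
CPU core, and everything is bit-reproducible under a fixed seed because the
only source of randomness is a ``numpy.random.Generator``.

Architecture: learned token + position embeddings, pre-layer-norm blocks
(multi-head self-attention with key padding mask, then a GELU feed-forward of
width 4*d), residual connections, and a final layer norm. Dropout is applied
to the embedding and to each residual branch during training only, so
inference is deterministic and batching-invariant.
"""

from __future__ import annotations

import math

import numpy as np

PAD = 0
_NEG_INF = np.float32(-1e9)
_LN_EPS = 1e-5
_GELU_A = 1.702  # sigmoid ("quick") GELU coefficient


def gelu(x: np.ndarray) -> np.ndarray:
    """Sigmoid-approximated GELU, x * sigmoid(1.702 x)."""
    return x / (1.0 + np.exp(np.float32(-_GELU_A) * x))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(np.float32(-_GELU_A) * x))
    return s * (1.0 + np.float32(_GELU_A) * x * (1.0 - s))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def _layernorm_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


def _linear_fwd(x, W, b):
    return x @ W + b, x


def _linear_bwd(dy, x, W):
    x2 = x.reshape(-1, x.shape[-1])
    dy2 = dy.reshape(-1, dy.shape[-1])
    dW = x2.T @ dy2
    db = dy2.sum(0)
    dx = dy @ W.T
    return dx, dW, db


def _dropout_mask(rng, shape, p, dtype):
    return (rng.random(shape) >= p).astype(dtype) / dtype.type(1.0 - p)


class TinyTransformerEncoder:
    """Encoder backbone: tokens (B, L) padded with 0 -> hidden states (B, L, d)."""

    def __init__(
        self,
        vocab_size: int,
        d_model: int = 64,
        n_layers: int = 2,
        n_heads: int = 4,
        context_length: int = 128,
        dropout: float = 0.1,
        seed: int = 0,
    ):
        if d_model % n_heads != 0:
            raise ValueError(f"d_model {d_model} not divisible by n_heads {n_heads}")
        self.vocab_size = vocab_size
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.context_length = context_length
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        init = lambda *shape: (0.02 * rng.standard_normal(shape)).astype(np.float32)
        p: dict[str, np.ndarray] = {
            "tok_emb": init(vocab_size, d_model),
            "pos_emb": init(context_length, d_model),
            "lnf.g": np.ones(d_model, np.float32),
            "lnf.b": np.zeros(d_model, np.float32),
        }
        for i in range(n_layers):
            pre = f"l{i}."
            p[pre + "ln1.g"] = np.ones(d_model, np.float32)
            p[pre + "ln1.b"] = np.zeros(d_model, np.float32)
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[pre + name] = init(d_model, d_model)
            for name in ("bq", "bk", "bv", "bo"):
                p[pre + name] = np.zeros(d_model, np.float32)
            p[pre + "ln2.g"] = np.ones(d_model, np.float32)
            p[pre + "ln2.b"] = np.zeros(d_model, np.float32)
            p[pre + "W1"] = init(d_model, 4 * d_model)
            p[pre + "b1"] = np.zeros(4 * d_model, np.float32)
            p[pre + "W2"] = init(4 * d_model, d_model)
            p[pre + "b2"] = np.zeros(d_model, np.float32)
        self.params = p

    # ---- forward -----------------------------------------------------------

    def forward(self, tokens: np.ndarray, train: bool = False, rng=None):
        """Return (H, cache); H has zero-meaningless rows at PAD positions."""
        p = self.params
        B, L = tokens.shape
        if L > self.context_length:
            raise ValueError(
                f"sequence length {L} exceeds context length {self.context_length}"
            )
        key_mask = tokens != PAD  # (B, L)
        x = p["tok_emb"][tokens] + p["pos_emb"][None, :L, :]
        dtype = x.dtype
        cache: dict = {"tokens": tokens, "key_mask": key_mask, "layers": [], "L": L}
        if train and self.dropout > 0:
            m = _dropout_mask(rng, x.shape, self.dropout, x.dtype)
            x = x * m
            cache["emb_drop"] = m
        h = self.n_heads
        dh = self.d_head
        scale = np.float32(1.0 / math.sqrt(dh))
        add_mask = np.where(key_mask[:, None, None, :], np.float32(0), _NEG_INF)
        for i in range(self.n_layers):
            pre = f"l{i}."
            lc: dict = {}
            a, lc["ln1"] = _layernorm_fwd(x, p[pre + "ln1.g"], p[pre + "ln1.b"])
            q, _ = _linear_fwd(a, p[pre + "Wq"], p[pre + "bq"])
            k, _ = _linear_fwd(a, p[pre + "Wk"], p[pre + "bk"])
            v, _ = _linear_fwd(a, p[pre + "Wv"], p[pre + "bv"])
            lc["a"] = a
            qh = q.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
            kh = k.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
            vh = v.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
            scores = (qh @ kh.transpose(0, 1, 3, 2)) * scale + add_mask
            A = softmax(scores, -1)
            ctx = A @ vh  # (B, h, L, dh)
            ctx_m = ctx.transpose(0, 2, 1, 3).reshape(B, L, self.d_model)
            out, _ = _linear_fwd(ctx_m, p[pre + "Wo"], p[pre + "bo"])
            lc.update(qh=qh, kh=kh, vh=vh, A=A, ctx_m=ctx_m)
            if train and self.dropout > 0:
                m = _dropout_mask(rng, out.shape, self.dropout, dtype)
                out = out * m
                lc["attn_drop"] = m
            x = x + out
            a2, lc["ln2"] = _layernorm_fwd(x, p[pre + "ln2.g"], p[pre + "ln2.b"])
            f1, _ = _linear_fwd(a2, p[pre + "W1"], p[pre + "b1"])
            g1 = gelu(f1)
            f2, _ = _linear_fwd(g1, p[pre + "W2"], p[pre + "b2"])
            lc.update(a2=a2, f1=f1, g1=g1)
            if train and self.dropout > 0:
                m = _dropout_mask(rng, f2.shape, self.dropout, dtype)
                f2 = f2 * m
                lc["ffn_drop"] = m
            x = x + f2
            cache["layers"].append(lc)
        H, cache["lnf"] = _layernorm_fwd(x, p["lnf.g"], p["lnf.b"])
        return H, cache

    # ---- backward ----------------------------------------------------------

    def backward(self, cache: dict, dH: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        grads: dict[str, np.ndarray] = {}
        B, L = cache["tokens"].shape
        h, dh_dim = self.n_heads, self.d_head
        scale = np.float32(1.0 / math.sqrt(dh_dim))

        dx, grads["lnf.g"], grads["lnf.b"] = _layernorm_bwd(dH, cache["lnf"])
        for i in reversed(range(self.n_layers)):
            pre = f"l{i}."
            lc = cache["layers"][i]
            # FFN branch
            df2 = dx.copy()
            if "ffn_drop" in lc:
                df2 = df2 * lc["ffn_drop"]
            dg1, grads[pre + "W2"], grads[pre + "b2"] = _linear_bwd(
                df2, lc["g1"], p[pre + "W2"]
            )
            df1 = dg1 * gelu_grad(lc["f1"])
            da2, grads[pre + "W1"], grads[pre + "b1"] = _linear_bwd(
                df1, lc["a2"], p[pre + "W1"]
            )
            dres, grads[pre + "ln2.g"], grads[pre + "ln2.b"] = _layernorm_bwd(
                da2, lc["ln2"]
            )
            dx = dx + dres
            # attention branch
            dout = dx.copy()
            if "attn_drop" in lc:
                dout = dout * lc["attn_drop"]
            dctx_m, grads[pre + "Wo"], grads[pre + "bo"] = _linear_bwd(
                dout, lc["ctx_m"], p[pre + "Wo"]
            )
            dctx = dctx_m.reshape(B, L, h, dh_dim).transpose(0, 2, 1, 3)
            A, qh, kh, vh = lc["A"], lc["qh"], lc["kh"], lc["vh"]
            dA = dctx @ vh.transpose(0, 1, 3, 2)
            dvh = A.transpose(0, 1, 3, 2) @ dctx
            dscores = (dA - (dA * A).sum(-1, keepdims=True)) * A
            dqh = (dscores @ kh) * scale
            dkh = (dscores.transpose(0, 1, 3, 2) @ qh) * scale
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, L, self.d_model)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, L, self.d_model)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, L, self.d_model)
            da = np.zeros_like(dq)
            for dy, w in ((dq, "Wq"), (dk, "Wk"), (dv, "Wv")):
                d_in, dW, db = _linear_bwd(dy, lc["a"], p[pre + w])
                grads[pre + w] = dW
                grads[pre + "b" + w[1:].lower()] = db
                da = da + d_in
            dres, grads[pre + "ln1.g"], grads[pre + "ln1.b"] = _layernorm_bwd(
                da, lc["ln1"]
            )
            dx = dx + dres

        if "emb_drop" in cache:
            dx = dx * cache["emb_drop"]
        grads["pos_emb"] = np.zeros_like(p["pos_emb"])
        grads["pos_emb"][:L] = dx.sum(0)
        dtok = np.zeros_like(p["tok_emb"])
        np.add.at(dtok, cache["tokens"].ravel(), dx.reshape(-1, self.d_model))
        grads["tok_emb"] = dtok
        return grads


class Adam:
    """Standard Adam over a parameter dict; updates in place."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        lr_t = self.lr * math.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for k, g in grads.items():
            g = g.astype(self.params[k].dtype, copy=False)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            self.params[k] -= lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)


def pad_batch(token_lists, context_length: int) -> np.ndarray:
    """Stack variable-length token sequences into a (B, L) PAD-padded array.

    Always pads to the full context length so a cell's forward pass is
    independent of which other cells share its batch.
    """
    out = np.full((len(token_lists), context_length), PAD, dtype=np.int64)
    for i, toks in enumerate(token_lists):
        if len(toks) > context_length:
            raise ValueError(
                f"encoding of length {len(toks)} exceeds context length {context_length}"
            )
        out[i, : len(toks)] = toks
    return out


def mean_pool(H: np.ndarray, tokens: np.ndarray) -> np.ndarray:
    """Mean of hidden states over non-PAD positions, per sequence."""
    mask = (tokens != PAD).astype(H.dtype)
    n = mask.sum(1, keepdims=True)
    return (H * mask[:, :, None]).sum(1) / n


def mean_pool_backward(dpooled: np.ndarray, tokens: np.ndarray, L: int) -> np.ndarray:
    mask = (tokens != PAD).astype(dpooled.dtype)
    n = mask.sum(1, keepdims=True)
    return dpooled[:, None, :] * (mask / n)[:, :, None]
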