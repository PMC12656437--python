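"""Dense tile segmentation with a lightweight spectral Vision Transformer.

Every pixel of a 20x16 tile is one token: its 184-band normalized spectrum is
used directly as the embedding, with no patch projection.  Four pre-norm
transformer blocks (8-head self-attention over the 320 tokens, then a
two-layer GELU MLP, residual around each, LayerNorm before each) refine the
tokens, and a final per-token linear layer maps 184 -> 13 class scores.  By
default there is no positional embedding, so the network is exactly
permutation-equivariant over pixel positions -- the spatial context it
exploits comes purely from which spectra co-occur in a tile.

The network, its backward pass and the optimizer live in plain NumPy: the
model is small enough (about 1.6 M parameters) that batched BLAS matmuls
train it on a CPU in minutes.  Forward activations needed by the backward
pass are kept in an explicit cache, so inference can run cache-free.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf

_SQRT2 = np.float32(np.sqrt(2.0))
_INV_SQRT_2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))
_LN_EPS = 1e-6

TILE_SHAPE = (20, 16)
N_TOKENS = TILE_SHAPE[0] * TILE_SHAPE[1]


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture hyper-parameters.

    The embedding width equals the spectral dimensionality (184) and stays
    fixed through the network; with 8 heads each head attends in a 23-dim
    subspace.  ``mlp_hidden`` follows the usual 4x convention.
    """

    n_blocks: int = 4
    n_heads: int = 8
    embed_dim: int = 184
    mlp_hidden: int = 736
    n_classes: int = 13
    positional_embedding: str = "none"  # "none" | "learned"
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}")
        if self.positional_embedding not in ("none", "learned"):
            raise ValueError(f"unknown positional_embedding {self.positional_embedding!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated-normal init at ±2 std (resampled, not clipped)."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out.astype(np.float32)


def init_params(config: SegModelConfig, seed: int = 0) -> dict[str, np.ndarray]:
    """Seeded initialisation: truncated-normal(0.02) weights, zero biases,
    unit/zero LayerNorm parameters."""
    rng = np.random.default_rng(seed)
    d, h, c = config.embed_dim, config.mlp_hidden, config.n_classes
    params: dict[str, np.ndarray] = {}
    if config.positional_embedding == "learned":
        params["pos_embed"] = _trunc_normal(rng, (N_TOKENS, d))
    for i in range(config.n_blocks):
        p = f"block{i}."
        params[p + "ln1.g"] = np.ones(d, dtype=np.float32)
        params[p + "ln1.b"] = np.zeros(d, dtype=np.float32)
        params[p + "attn.w_qkv"] = _trunc_normal(rng, (d, 3 * d))
        params[p + "attn.b_qkv"] = np.zeros(3 * d, dtype=np.float32)
        params[p + "attn.w_out"] = _trunc_normal(rng, (d, d))
        params[p + "attn.b_out"] = np.zeros(d, dtype=np.float32)
        params[p + "ln2.g"] = np.ones(d, dtype=np.float32)
        params[p + "ln2.b"] = np.zeros(d, dtype=np.float32)
        params[p + "mlp.w1"] = _trunc_normal(rng, (d, h))
        params[p + "mlp.b1"] = np.zeros(h, dtype=np.float32)
        params[p + "mlp.w2"] = _trunc_normal(rng, (h, d))
        params[p + "mlp.b2"] = np.zeros(d, dtype=np.float32)
    params["head.w"] = _trunc_normal(rng, (d, c))
    params["head.b"] = np.zeros(c, dtype=np.float32)
    return params


def param_count(params: dict[str, np.ndarray]) -> int:
    return int(sum(p.size for p in params.values()))


# ---------------------------------------------------------------------------
# layers: forward + backward
# ---------------------------------------------------------------------------


def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    inv = 1.0 / np.sqrt((xc * xc).mean(axis=-1, keepdims=True) + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    dg = (dy * xhat).sum(axis=(0, 1))
    db = dy.sum(axis=(0, 1))
    return dx, dg, db


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x):
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    return cdf + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


def _softmax_lastaxis(x):
    z = x - x.max(axis=-1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=-1, keepdims=True)
    return z


def _attention_fwd(x, w_qkv, b_qkv, w_out, b_out, n_heads):
    """Multi-head self-attention over the token axis.

    Head-wise score/value products run as looped 2-D GEMMs, which on a single
    CPU core outperforms NumPy's batched 4-D matmul for these shapes.
    """
    bsz, n_tok, d = x.shape
    hd = d // n_heads
    scale = 1.0 / np.sqrt(hd)
    qkv = x.reshape(bsz * n_tok, d) @ w_qkv + b_qkv  # (B*T, 3d)
    qkv = qkv.reshape(bsz, n_tok, 3, n_heads, hd).transpose(2, 0, 3, 1, 4)
    q, k, v = (a.reshape(bsz * n_heads, n_tok, hd) for a in qkv)
    scores = np.empty((bsz * n_heads, n_tok, n_tok), dtype=x.dtype)
    for i in range(bsz * n_heads):
        np.matmul(q[i], k[i].T, out=scores[i])
    scores *= scale
    att = _softmax_lastaxis(scores)
    ctx = np.empty_like(q)
    for i in range(bsz * n_heads):
        np.matmul(att[i], v[i], out=ctx[i])
    ctx_merged = (
        ctx.reshape(bsz, n_heads, n_tok, hd).transpose(0, 2, 1, 3).reshape(bsz * n_tok, d)
    )
    out = (ctx_merged @ w_out + b_out).reshape(bsz, n_tok, d)
    cache = (x, q, k, v, att, ctx_merged, w_qkv, w_out, scale)
    return out, cache


def _attention_bwd(dy, cache, n_heads):
    x, q, k, v, att, ctx_merged, w_qkv, w_out, scale = cache
    bsz, n_tok, d = x.shape
    hd = d // n_heads
    dy2 = dy.reshape(bsz * n_tok, d)
    dw_out = ctx_merged.T @ dy2
    db_out = dy2.sum(axis=0)
    dctx = (dy2 @ w_out.T).reshape(bsz, n_tok, n_heads, hd).transpose(0, 2, 1, 3)
    dctx = np.ascontiguousarray(dctx).reshape(bsz * n_heads, n_tok, hd)
    dq = np.empty_like(q)
    dk = np.empty_like(k)
    dv = np.empty_like(v)
    datt = np.empty((bsz * n_heads, n_tok, n_tok), dtype=dy.dtype)
    for i in range(bsz * n_heads):
        np.matmul(att[i].T, dctx[i], out=dv[i])
        np.matmul(dctx[i], v[i].T, out=datt[i])
    ds = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
    ds *= scale
    for i in range(bsz * n_heads):
        np.matmul(ds[i], k[i], out=dq[i])
        np.matmul(ds[i].T, q[i], out=dk[i])
    dqkv = np.stack([dq, dk, dv])  # (3, B*h, T, hd)
    dqkv = (
        dqkv.reshape(3, bsz, n_heads, n_tok, hd)
        .transpose(1, 3, 0, 2, 4)
        .reshape(bsz * n_tok, 3 * d)
    )
    dw_qkv = x.reshape(bsz * n_tok, d).T @ dqkv
    db_qkv = dqkv.sum(axis=0)
    dx = (dqkv @ w_qkv.T).reshape(bsz, n_tok, d)
    return dx, dw_qkv, db_qkv, dw_out, db_out


def _mlp_fwd(x, w1, b1, w2, b2):
    bsz, n_tok, d = x.shape
    x2 = x.reshape(bsz * n_tok, d)
    pre = x2 @ w1 + b1
    act = _gelu(pre)
    out = (act @ w2 + b2).reshape(bsz, n_tok, d)
    return out, (x2, pre, act, w1, w2)


def _mlp_bwd(dy, cache):
    x2, pre, act, w1, w2 = cache
    bsz_tok = x2.shape[0]
    dy2 = dy.reshape(bsz_tok, -1)
    dw2 = act.T @ dy2
    db2 = dy2.sum(axis=0)
    dpre = (dy2 @ w2.T) * _gelu_grad(pre)
    dw1 = x2.T @ dpre
    db1 = dpre.sum(axis=0)
    dx = (dpre @ w1.T).reshape(dy.shape)
    return dx, dw1, db1, dw2, db2


# ---------------------------------------------------------------------------
# whole-model forward / backward
# ---------------------------------------------------------------------------


def forward(
    params: dict[str, np.ndarray],
    tiles: np.ndarray,
    config: SegModelConfig,
    need_cache: bool = False,
    drop_rng: np.random.Generator | None = None,
):
    """Compute (B, 20, 16, n_classes) logits for a (B, 20, 16, 184) batch.

    Returns ``(logits, cache)``; the cache is ``None`` unless requested (it
    holds every intermediate needed by :func:`backward` and is large).
    Residual-branch dropout is applied only when ``drop_rng`` is given and
    ``config.dropout > 0`` (training); evaluation is always deterministic.
    """
    tiles = np.asarray(tiles, dtype=np.float32)
    if tiles.ndim == 3:
        tiles = tiles[None]
    bsz, th, tw, d = tiles.shape
    if (th, tw) != TILE_SHAPE or d != config.embed_dim:
        raise ValueError(
            f"expected tiles of shape (B, {TILE_SHAPE[0]}, {TILE_SHAPE[1]}, {config.embed_dim}), got {tiles.shape}"
        )
    x = tiles.reshape(bsz, N_TOKENS, d)
    if config.positional_embedding == "learned":
        x = x + params["pos_embed"][None]
    use_dropout = drop_rng is not None and config.dropout > 0
    keep = 1.0 - config.dropout
    caches = []
    for i in range(config.n_blocks):
        p = f"block{i}."
        h1, c_ln1 = _layernorm_fwd(x, params[p + "ln1.g"], params[p + "ln1.b"])
        a_out, c_att = _attention_fwd(
            h1,
            params[p + "attn.w_qkv"],
            params[p + "attn.b_qkv"],
            params[p + "attn.w_out"],
            params[p + "attn.b_out"],
            config.n_heads,
        )
        mask_a = mask_m = None
        if use_dropout:
            mask_a = (drop_rng.random(a_out.shape) < keep).astype(np.float32) / keep
            a_out = a_out * mask_a
        x = x + a_out
        h2, c_ln2 = _layernorm_fwd(x, params[p + "ln2.g"], params[p + "ln2.b"])
        m_out, c_mlp = _mlp_fwd(
            h2, params[p + "mlp.w1"], params[p + "mlp.b1"], params[p + "mlp.w2"], params[p + "mlp.b2"]
        )
        if use_dropout:
            mask_m = (drop_rng.random(m_out.shape) < keep).astype(np.float32) / keep
            m_out = m_out * mask_m
        x = x + m_out
        if need_cache:
            caches.append((c_ln1, c_att, c_ln2, c_mlp, mask_a, mask_m))
    feats = x.reshape(bsz * N_TOKENS, d)
    logits = (feats @ params["head.w"] + params["head.b"]).reshape(bsz, th, tw, config.n_classes)
    if not np.isfinite(logits).all():
        raise FloatingPointError("non-finite logits")
    cache = (caches, feats) if need_cache else None
    return logits, cache


def backward(
    params: dict[str, np.ndarray],
    cache,
    dlogits: np.ndarray,
    config: SegModelConfig,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. every parameter, given d(loss)/d(logits)."""
    caches, feats = cache
    bsz = dlogits.shape[0]
    d = config.embed_dim
    dl = dlogits.reshape(bsz * N_TOKENS, config.n_classes).astype(np.float32)
    grads: dict[str, np.ndarray] = {
        "head.w": feats.T @ dl,
        "head.b": dl.sum(axis=0),
    }
    dx = (dl @ params["head.w"].T).reshape(bsz, N_TOKENS, d)
    for i in reversed(range(config.n_blocks)):
        p = f"block{i}."
        c_ln1, c_att, c_ln2, c_mlp, mask_a, mask_m = caches[i]
        dbranch = dx if mask_m is None else dx * mask_m
        dm, dw1, db1, dw2, db2 = _mlp_bwd(dbranch, c_mlp)
        grads[p + "mlp.w1"], grads[p + "mlp.b1"] = dw1, db1
        grads[p + "mlp.w2"], grads[p + "mlp.b2"] = dw2, db2
        dh2, dg2, dbeta2 = _layernorm_bwd(dm, c_ln2)
        grads[p + "ln2.g"], grads[p + "ln2.b"] = dg2, dbeta2
        dx = dx + dh2
        dbranch = dx if mask_a is None else dx * mask_a
        da, dw_qkv, db_qkv, dw_out, db_out = _attention_bwd(dbranch, c_att, config.n_heads)
        grads[p + "attn.w_qkv"], grads[p + "attn.b_qkv"] = dw_qkv, db_qkv
        grads[p + "attn.w_out"], grads[p + "attn.b_out"] = dw_out, db_out
        dh1, dg1, dbeta1 = _layernorm_bwd(da, c_ln1)
        grads[p + "ln1.g"], grads[p + "ln1.b"] = dg1, dbeta1
        dx = dx + dh1
    if config.positional_embedding == "learned":
        grads["pos_embed"] = dx.sum(axis=0)
    return grads


def predict_tiles(
    params: dict[str, np.ndarray], tiles: np.ndarray, config: SegModelConfig
) -> np.ndarray:
    """Per-pixel argmax class map(s); ties resolve to the lowest class index,
    which favours the background class `meat` (index 0)."""
    logits, _ = forward(params, tiles, config)
    return np.argmax(logits, axis=-1).astype(np.uint8)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path: str | Path, params: dict[str, np.ndarray], config: SegModelConfig) -> None:
    """Write params as ``.npz`` plus a JSON sidecar holding the config."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **params)
    path.with_suffix(".json").write_text(json.dumps(asdict(config), indent=2) + "\n")


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], SegModelConfig]:
    path = Path(path)
    config = SegModelConfig(**json.loads(path.with_suffix(".json").read_text()))
    with np.load(path.with_suffix(".npz")) as archive:
        params = {k: archive[k] for k in archive.files}
    return params, config
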