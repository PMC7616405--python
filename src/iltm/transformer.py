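"""Autoregressive transformer prior over raster-ordered token sequences.

A decoder-only transformer models p(s_i | s_<i) over the discrete latent
tokens of the quantizer.  Beyond the standard causal factorization it
supports *token masking*: given a per-sequence binary mask of suspected
anomalous positions, masked tokens are removed from the conditioning
context, so that position i's distribution is p(s_i | s_<i \\ masked).

Masking contract
----------------
Two mechanisms together make the removal exact (bit-for-bit):

* the input embedding of a masked token is replaced by a dedicated learned
  MASK embedding, so the token's value never enters the network;
* masked positions are excluded as attention *keys* for every query
  (their pre-softmax scores are set to -inf, i.e. column masking), so even
  their positional presence carries no information to other positions.

Predictions *at* masked positions are still computed (from the unmasked
context alone), which is what allows them to be resampled.  A begin-of-
sequence token anchors the first prediction and is never maskable; the
cross-entropy loss averages over unmasked target positions only, so with
all-zero masks training reduces exactly to ordinary autoregressive
maximum likelihood.

Implementation: pre-LayerNorm blocks, learned positional embeddings, GELU
MLPs, hand-derived NumPy gradients (finite-difference-checked in tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import Adam, glorot, layer_norm, layer_norm_grad, softmax
from .exceptions import ContextLengthError, DegenerateTrainingError, TrainingError

__all__ = [
    "TransformerConfig",
    "TokenSequence",
    "TokenLikelihoods",
    "TransformerModel",
    "rasterize",
    "derasterize",
    "token_likelihoods",
    "token_likelihoods_batch",
    "next_token_distribution",
    "train_transformer",
    "save_transformer",
    "load_transformer",
]

NEG_INF = -1e30        # exact zero after softmax (exp underflows)
LIKELIHOOD_FLOOR = 1e-12


@dataclass(frozen=True)
class TransformerConfig:
    vocab: int = 64          # codebook size K; BOS=K and MASK=K+1 are internal
    context: int = 65        # must be >= sequence length + 1 (for BOS)
    d_model: int = 128
    n_heads: int = 4
    n_layers: int = 4
    d_ff: int | None = None
    epochs: int = 30
    batch_size: int = 64
    lr: float = 1e-3
    dtype: str = "float64"

    @property
    def ff(self) -> int:
        return 4 * self.d_model if self.d_ff is None else self.d_ff

    @property
    def bos(self) -> int:
        return self.vocab

    @property
    def mask_id(self) -> int:
        return self.vocab + 1


@dataclass(frozen=True)
class TokenSequence:
    """Raster-ordered (row-major) token sequence with its origin geometry."""

    s: np.ndarray            # (l,) integers in [0, K)
    shape: tuple[int, int]   # latent grid (h, w)

    def __post_init__(self):
        if self.s.ndim != 1 or len(self.s) != self.shape[0] * self.shape[1]:
            raise ValueError("sequence length must equal h*w")

    def __len__(self) -> int:
        return len(self.s)


@dataclass(frozen=True)
class TokenLikelihoods:
    """Per-position likelihood of the observed token and full distributions."""

    p: np.ndarray            # (l,) in (0, 1]
    dists: np.ndarray        # (l, K), each row sums to 1
    mask: np.ndarray         # (l,) bool; True = position was masked (flagged)


@dataclass
class TransformerModel:
    params: dict[str, np.ndarray]
    config: TransformerConfig
    loss_log: list[float] = field(default_factory=list)


def rasterize(Z_iq: np.ndarray) -> TokenSequence:
    """Row-major flattening of a 2D index grid."""
    if Z_iq.ndim != 2:
        raise ValueError("expected a 2D index grid")
    return TokenSequence(s=Z_iq.reshape(-1).astype(np.int64), shape=Z_iq.shape)


def derasterize(seq: TokenSequence) -> np.ndarray:
    return seq.s.reshape(seq.shape)


# ---------------------------------------------------------------- model core

def init_params(config: TransformerConfig, seed) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    d, ffd = config.d_model, config.ff
    dt = np.dtype(config.dtype)
    p: dict[str, np.ndarray] = {
        "Wtok": 0.02 * rng.standard_normal((config.vocab + 2, d)),
        "Wpos": 0.02 * rng.standard_normal((config.context, d)),
        "g_f": np.ones(d), "b_f": np.zeros(d),
        "Wout": np.zeros((d, config.vocab)), "bout": np.zeros(config.vocab),
    }
    for i in range(config.n_layers):
        p[f"g1_{i}"], p[f"b1_{i}"] = np.ones(d), np.zeros(d)
        p[f"Wq_{i}"] = glorot(rng, d, d)
        p[f"Wk_{i}"] = glorot(rng, d, d)
        p[f"Wv_{i}"] = glorot(rng, d, d)
        p[f"Wo_{i}"] = glorot(rng, d, d)
        p[f"bq_{i}"], p[f"bk_{i}"] = np.zeros(d), np.zeros(d)
        p[f"bv_{i}"], p[f"bo_{i}"] = np.zeros(d), np.zeros(d)
        p[f"g2_{i}"], p[f"b2_{i}"] = np.ones(d), np.zeros(d)
        p[f"W1_{i}"] = glorot(rng, d, ffd)
        p[f"b1m_{i}"] = np.zeros(ffd)
        p[f"W2_{i}"] = glorot(rng, ffd, d)
        p[f"b2m_{i}"] = np.zeros(d)
    return {k: v.astype(dt) for k, v in p.items()}


def _outer_grad(x, dy):
    """sum_bt x[b,t,:] (x) dy[b,t,:] as a single BLAS matmul."""
    return x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])


def _gelu_cdf(x):
    from scipy.special import erf
    return 0.5 * (1.0 + erf(x * x.dtype.type(0.7071067811865476)))


def _split_heads(x, n_heads):
    b, t, d = x.shape
    return x.reshape(b, t, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    b, h, t, dk = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, t, h * dk)


def _forward(params, config, ids, key_masked, need_cache=False):
    """ids: (B, T) int; key_masked: (B, T) bool -> logits (B, T, K).

    Row p of the logits predicts the token at sequence position p (input
    position p holds BOS for p=0, else token s_{p-1}).
    """
    B, T = ids.shape
    d, nh = config.d_model, config.n_heads
    dk = d // nh
    X = params["Wtok"][ids] + params["Wpos"][:T]
    dt = X.dtype
    # attention bias: causal plus key-column masking
    causal = np.triu(np.full((T, T), NEG_INF, dtype=dt), k=1)
    bias = (causal[None, None]
            + np.where(key_masked[:, None, None, :], dt.type(NEG_INF),
                       dt.type(0.0)))
    cache = {"ids": ids, "X0": X, "layers": []} if need_cache else None
    for i in range(config.n_layers):
        Xn, ln1c = layer_norm(X, params[f"g1_{i}"], params[f"b1_{i}"])
        Q = Xn @ params[f"Wq_{i}"] + params[f"bq_{i}"]
        K_ = Xn @ params[f"Wk_{i}"] + params[f"bk_{i}"]
        V = Xn @ params[f"Wv_{i}"] + params[f"bv_{i}"]
        Qh, Kh, Vh = (_split_heads(a, nh) for a in (Q, K_, V))
        scores = Qh @ Kh.transpose(0, 1, 3, 2) / np.sqrt(dk) + bias
        A = softmax(scores, axis=-1)
        ctx = _merge_heads(A @ Vh)
        attn_out = ctx @ params[f"Wo_{i}"] + params[f"bo_{i}"]
        X1 = X + attn_out
        X1n, ln2c = layer_norm(X1, params[f"g2_{i}"], params[f"b2_{i}"])
        H1 = X1n @ params[f"W1_{i}"] + params[f"b1m_{i}"]
        Phi = _gelu_cdf(H1)
        Hg = H1 * Phi
        mlp_out = Hg @ params[f"W2_{i}"] + params[f"b2m_{i}"]
        X2 = X1 + mlp_out
        if need_cache:
            cache["layers"].append(
                dict(Xn=Xn, ln1c=ln1c, Qh=Qh, Kh=Kh, Vh=Vh, A=A, ctx=ctx,
                     X1n=X1n, ln2c=ln2c, H1=H1, Hg=Hg, Phi=Phi, X=X, X1=X1))
        X = X2
    Xf, lnfc = layer_norm(X, params["g_f"], params["b_f"])
    logits = Xf @ params["Wout"] + params["bout"]
    if need_cache:
        cache["Xf"], cache["lnfc"], cache["Xlast"] = Xf, lnfc, X
    return logits, cache


def _backward(params, config, cache, dlogits):
    """Backprop from dlogits to parameter grads."""
    nh = config.n_heads
    dk = config.d_model // nh
    grads = {}
    Xf = cache["Xf"]
    grads["Wout"] = _outer_grad(Xf, dlogits)
    grads["bout"] = dlogits.sum(axis=(0, 1))
    dXf = dlogits @ params["Wout"].T
    dX, grads["g_f"], grads["b_f"] = layer_norm_grad(dXf, cache["lnfc"])
    for i in reversed(range(config.n_layers)):
        L = cache["layers"][i]
        # MLP branch
        dmlp = dX
        grads[f"W2_{i}"] = _outer_grad(L["Hg"], dmlp)
        grads[f"b2m_{i}"] = dmlp.sum(axis=(0, 1))
        dHg = dmlp @ params[f"W2_{i}"].T
        H1, Phi = L["H1"], L["Phi"]
        pdf = np.exp(H1 * H1 * H1.dtype.type(-0.5)) \
            * H1.dtype.type(0.3989422804014327)
        dH1 = dHg * (Phi + H1 * pdf)
        grads[f"W1_{i}"] = _outer_grad(L["X1n"], dH1)
        grads[f"b1m_{i}"] = dH1.sum(axis=(0, 1))
        dX1n = dH1 @ params[f"W1_{i}"].T
        dX1_ln, grads[f"g2_{i}"], grads[f"b2_{i}"] = layer_norm_grad(dX1n, L["ln2c"])
        dX1 = dX + dX1_ln
        # attention branch
        dattn = dX1
        grads[f"Wo_{i}"] = _outer_grad(L["ctx"], dattn)
        grads[f"bo_{i}"] = dattn.sum(axis=(0, 1))
        dctx = _split_heads(dattn @ params[f"Wo_{i}"].T, nh)
        A, Vh = L["A"], L["Vh"]
        dA = dctx @ Vh.transpose(0, 1, 3, 2)
        dVh = A.transpose(0, 1, 3, 2) @ dctx
        dscores = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQh = dscores @ L["Kh"] / np.sqrt(dk)
        dKh = dscores.transpose(0, 1, 3, 2) @ L["Qh"] / np.sqrt(dk)
        dQ, dK, dV = (_merge_heads(a) for a in (dQh, dKh, dVh))
        Xn = L["Xn"]
        grads[f"Wq_{i}"] = _outer_grad(Xn, dQ)
        grads[f"Wk_{i}"] = _outer_grad(Xn, dK)
        grads[f"Wv_{i}"] = _outer_grad(Xn, dV)
        grads[f"bq_{i}"] = dQ.sum(axis=(0, 1))
        grads[f"bk_{i}"] = dK.sum(axis=(0, 1))
        grads[f"bv_{i}"] = dV.sum(axis=(0, 1))
        dXn = (dQ @ params[f"Wq_{i}"].T + dK @ params[f"Wk_{i}"].T
               + dV @ params[f"Wv_{i}"].T)
        dX_ln, grads[f"g1_{i}"], grads[f"b1_{i}"] = layer_norm_grad(dXn, L["ln1c"])
        dX = dX1 + dX_ln
    grads["Wpos"] = dX.sum(axis=0)
    grads["Wtok"] = np.zeros_like(params["Wtok"])
    np.add.at(grads["Wtok"], cache["ids"], dX)
    # positions beyond T get zero grad; trim Wpos grad to full shape
    if grads["Wpos"].shape[0] != params["Wpos"].shape[0]:
        full = np.zeros_like(params["Wpos"])
        full[:grads["Wpos"].shape[0]] = grads["Wpos"]
        grads["Wpos"] = full
    return grads


def _prep_inputs(config, S, M):
    """Sequences S (B, l), masks M (B, l) -> ids (B, l+1), key_masked."""
    B, l = S.shape
    if l + 1 > config.context:
        raise ContextLengthError(f"sequence length {l} exceeds context "
                                 f"{config.context} - 1")
    if S.min() < 0 or S.max() >= config.vocab:
        raise ValueError("token values out of vocabulary range")
    ids = np.empty((B, l + 1), dtype=np.int64)
    ids[:, 0] = config.bos
    ids[:, 1:] = np.where(M, config.mask_id, S)
    key_masked = np.zeros((B, l + 1), dtype=bool)
    key_masked[:, 1:] = M
    return ids, key_masked


# ---------------------------------------------------------------- inference

def token_likelihoods_batch(model: TransformerModel, S: np.ndarray,
                            M: np.ndarray | None = None, *,
                            return_dists: bool = False):
    """Vectorized likelihoods for a batch of sequences.

    Returns p (B, l) and, optionally, the full distributions (B, l, K).
    """
    S = np.asarray(S)
    if M is None:
        M = np.zeros_like(S, dtype=bool)
    M = np.asarray(M, dtype=bool)
    if M.shape != S.shape:
        raise ValueError("mask shape must match sequence shape")
    ids, key_masked = _prep_inputs(model.config, S, M)
    logits, _ = _forward(model.params, model.config, ids, key_masked)
    dists = softmax(logits[:, :-1, :], axis=-1)
    p = np.take_along_axis(dists, S[..., None], axis=-1)[..., 0]
    p = np.maximum(p, LIKELIHOOD_FLOOR)
    return (p, dists) if return_dists else p


def token_likelihoods(model: TransformerModel, s: TokenSequence,
                      mask: np.ndarray | None = None) -> TokenLikelihoods:
    """Per-position p(s_i | s_<i minus masked) and full distributions.

    Masked positions still receive a likelihood entry (computed from the
    unmasked context), flagged in the returned ``mask``.
    """
    m = np.zeros(len(s), dtype=bool) if mask is None else np.asarray(mask, bool)
    if len(m) != len(s):
        raise ValueError("mask length must match sequence length")
    p, dists = token_likelihoods_batch(model, s.s[None], m[None],
                                       return_dists=True)
    return TokenLikelihoods(p=p[0], dists=dists[0], mask=m.copy())


def next_token_distribution(model: TransformerModel, prefix: np.ndarray,
                            mask: np.ndarray | None = None) -> np.ndarray:
    """Distribution over the K tokens at position len(prefix)."""
    prefix = np.asarray(prefix, dtype=np.int64)
    cfg = model.config
    if len(prefix) + 1 > cfg.context:
        raise ContextLengthError("prefix too long for model context")
    m = np.zeros(len(prefix), bool) if mask is None else np.asarray(mask, bool)
    ids = np.concatenate([[cfg.bos], np.where(m, cfg.mask_id, prefix)])[None]
    key_masked = np.concatenate([[False], m])[None]
    logits, _ = _forward(model.params, cfg, ids, key_masked)
    return softmax(logits[0, -1])


# ---------------------------------------------------------------- training

def masked_cross_entropy(model_or_params, config_or_none=None, S=None, M=None,
                         *, with_grads: bool = False):
    """Mean cross-entropy over unmasked positions of a batch.

    Callable as ``masked_cross_entropy(model, S=..., M=...)`` or with an
    explicit (params, config) pair.  With ``with_grads=True`` also returns
    parameter gradients.
    """
    if isinstance(model_or_params, TransformerModel):
        params, config = model_or_params.params, model_or_params.config
    else:
        params, config = model_or_params, config_or_none
    S = np.asarray(S)
    M = np.zeros_like(S, bool) if M is None else np.asarray(M, bool)
    counted = ~M
    n_counted = int(counted.sum())
    if n_counted == 0:
        raise DegenerateTrainingError("every position is masked in every sequence")
    ids, key_masked = _prep_inputs(config, S, M)
    logits, cache = _forward(params, config, ids, key_masked,
                             need_cache=with_grads)
    pred = logits[:, :-1, :]
    z = pred - pred.max(axis=-1, keepdims=True)
    logZ = np.log(np.exp(z).sum(axis=-1))
    logp = np.take_along_axis(z, S[..., None], axis=-1)[..., 0] - logZ
    loss = -(logp * counted).sum() / n_counted
    if not with_grads:
        return loss
    probs = softmax(pred, axis=-1)
    dpred = probs.copy()
    np.put_along_axis(dpred, S[..., None],
                      np.take_along_axis(dpred, S[..., None], axis=-1) - 1.0,
                      axis=-1)
    dpred *= (counted / n_counted)[..., None]
    dlogits = np.zeros_like(logits)
    dlogits[:, :-1, :] = dpred
    grads = _backward(params, config, cache, dlogits)
    return loss, grads


def train_transformer(sequences, masks=None,
                      config: TransformerConfig = TransformerConfig(),
                      seed: int = 0) -> TransformerModel:
    """Train the prior by masked maximum likelihood.

    ``sequences``: (N, l) array or list of TokenSequence; ``masks``: aligned
    (N, l) binary array (None = all-zero masks, i.e. plain autoregressive
    training).
    """
    if sequences is None or len(sequences) == 0:
        raise ValueError("no training sequences")
    if isinstance(sequences, (list, tuple)) and isinstance(sequences[0],
                                                           TokenSequence):
        S = np.stack([t.s for t in sequences])
    else:
        S = np.asarray(sequences, dtype=np.int64)
    M = (np.zeros_like(S, bool) if masks is None
         else np.asarray(masks, bool))
    if M.shape != S.shape:
        raise ValueError("masks must align one-to-one with sequences")
    if (~M).sum() == 0:
        raise DegenerateTrainingError("every position is masked in every sequence")

    rng = np.random.default_rng(seed)
    params = init_params(config, rng)
    model = TransformerModel(params=params, config=config)
    if config.epochs == 0:
        return model
    opt = Adam(params, lr=config.lr)
    n = len(S)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total, weight = 0.0, 0.0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            if (~M[sel]).sum() == 0:
                continue  # batch fully masked; contributes nothing
            loss, grads = masked_cross_entropy(params, config, S[sel], M[sel],
                                               with_grads=True)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.step(grads)
            total += loss * len(sel)
            weight += len(sel)
        model.loss_log.append(total / max(weight, 1))
    return model


# ---------------------------------------------------------------- checkpoints

def save_transformer(model: TransformerModel, path) -> None:
    with open(Path(path), "wb") as f:
        np.savez(f, __config__=json.dumps(asdict(model.config)),
                 __loss_log__=json.dumps(model.loss_log), **model.params)


def load_transformer(path) -> TransformerModel:
    with np.load(Path(path), allow_pickle=False) as z:
        config = TransformerConfig(**json.loads(str(z["__config__"])))
        log = json.loads(str(z["__loss_log__"]))
        params = {k: z[k] for k in z.files if not k.startswith("__")}
    return TransformerModel(params=params, config=config, loss_log=log)
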