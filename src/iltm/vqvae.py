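"""Vector-quantized autoencoder over small grayscale images.

The encoder maps an image x (H, W) to a continuous latent grid
Z (h, w, n_z) through a stack of non-overlapping space-to-depth (factor-2)
+ linear + ReLU stages, so an image is downsampled by 2**n_stages.  Each
latent site is replaced by its nearest codebook vector (Euclidean distance,
ties broken by lowest index), yielding the quantized latent Z_q and the
integer index grid Z_iq.  The decoder mirrors the encoder and supports
stochastic decoding: with dropout active, repeated decodes of the same Z_q
give different plausible reconstructions — the sampling mechanism the
KDE anomaly scorer relies on.

Training uses the standard VQ recipe: L2 reconstruction loss, codebook
loss ||sg(Z) - e||^2 and beta-weighted commitment loss ||Z - sg(e)||^2,
with the straight-through estimator copying decoder gradients past the
quantizer.  All gradients are hand-derived NumPy; see tests for the
finite-difference checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import Adam, glorot, relu, sigmoid
from .exceptions import TrainingError

__all__ = [
    "VqvaeConfig",
    "Codebook",
    "QuantizedLatent",
    "VqvaeModel",
    "encode",
    "quantize",
    "embed",
    "decode",
    "reconstruct",
    "train_vqvae",
    "save_vqvae",
    "load_vqvae",
]


@dataclass(frozen=True)
class VqvaeConfig:
    """Architecture and training hyper-parameters.

    ``n_stages`` factor-2 downsampling stages give a total factor of
    2**n_stages (default 4: 32x32 -> 8x8 latents).
    """

    n_stages: int = 2
    hidden: int = 64
    n_z: int = 32
    K: int = 64
    dropout: float = 0.2
    beta: float = 0.25
    epochs: int = 30
    batch_size: int = 64
    lr: float = 2e-3
    codebook_init_scale: float = 0.5
    revive_dead_codes: bool = False

    @property
    def factor(self) -> int:
        return 2 ** self.n_stages


@dataclass(frozen=True)
class Codebook:
    """K embedding vectors of dimension n_z."""

    vectors: np.ndarray  # (K, n_z)

    def __post_init__(self):
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 2:
            raise ValueError("codebook needs at least 2 vectors")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("codebook entries must be finite")

    @property
    def K(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_z(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class QuantizedLatent:
    """Continuous latent Z, its quantization Z_q and the index grid Z_iq."""

    Z: np.ndarray     # (h, w, n_z)
    Z_q: np.ndarray   # (h, w, n_z)
    Z_iq: np.ndarray  # (h, w) integer indices in [0, K)


@dataclass
class VqvaeModel:
    params: dict[str, np.ndarray]
    config: VqvaeConfig
    loss_log: list[dict] = field(default_factory=list)

    @property
    def codebook(self) -> Codebook:
        return Codebook(self.params["C"])

    def latent_shape(self, image_shape: tuple[int, int]) -> tuple[int, int]:
        f = self.config.factor
        return image_shape[0] // f, image_shape[1] // f


# ---------------------------------------------------------------- internals

def _space_to_depth(x: np.ndarray) -> np.ndarray:
    b, h, w, c = x.shape
    return (x.reshape(b, h // 2, 2, w // 2, 2, c)
             .transpose(0, 1, 3, 2, 4, 5)
             .reshape(b, h // 2, w // 2, 4 * c))


def _depth_to_space(x: np.ndarray) -> np.ndarray:
    b, h, w, c4 = x.shape
    c = c4 // 4
    return (x.reshape(b, h, w, 2, 2, c)
             .transpose(0, 1, 3, 2, 4, 5)
             .reshape(b, 2 * h, 2 * w, c))


def init_params(config: VqvaeConfig, seed) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    p: dict[str, np.ndarray] = {}
    c_in = 1
    for i in range(config.n_stages):
        p[f"We{i}"] = glorot(rng, 4 * c_in, config.hidden)
        p[f"be{i}"] = np.zeros(config.hidden)
        c_in = config.hidden
    p["Wh"] = glorot(rng, config.hidden, config.n_z)
    p["bh"] = np.zeros(config.n_z)
    p["Wd0"] = glorot(rng, config.n_z, config.hidden)
    p["bd0"] = np.zeros(config.hidden)
    for i in range(config.n_stages - 1):
        p[f"Wu{i}"] = glorot(rng, config.hidden, 4 * config.hidden)
        p[f"bu{i}"] = np.zeros(4 * config.hidden)
    p["Wo"] = glorot(rng, config.hidden, 4 * 1)
    p["bo"] = np.zeros(4)
    # seeded uniform codebook
    p["C"] = rng.uniform(-config.codebook_init_scale, config.codebook_init_scale,
                         size=(config.K, config.n_z))
    return p


def _encode_fwd(params, config, x):
    """x: (B, H, W) -> Z (B, h, w, n_z) plus cache."""
    a = x[..., None]
    cache = []
    for i in range(config.n_stages):
        s = _space_to_depth(a)
        pre = s @ params[f"We{i}"] + params[f"be{i}"]
        a = relu(pre)
        cache.append((s, pre))
    Z = a @ params["Wh"] + params["bh"]
    cache.append(a)
    return Z, cache


def _encode_bwd(params, config, cache, dZ):
    grads = {}
    a_last = cache[-1]
    grads["Wh"] = np.einsum("bhwc,bhwz->cz", a_last, dZ)
    grads["bh"] = dZ.sum(axis=(0, 1, 2))
    da = dZ @ params["Wh"].T
    for i in reversed(range(config.n_stages)):
        s, pre = cache[i]
        dpre = da * (pre > 0)
        grads[f"We{i}"] = np.einsum("bhwc,bhwd->cd", s, dpre)
        grads[f"be{i}"] = dpre.sum(axis=(0, 1, 2))
        ds = dpre @ params[f"We{i}"].T
        da = _depth_to_space(ds) if i > 0 else None  # input grad unused
    return grads


def _decode_fwd(params, config, Zq, drop_masks=None):
    """Zq: (B, h, w, n_z) -> xhat (B, H, W) plus cache.

    drop_masks: list of pre-scaled dropout masks (inverted dropout), one per
    dropout site, or None for deterministic decoding.
    """
    cache = {"Zq": Zq, "drop": drop_masks}
    pre0 = Zq @ params["Wd0"] + params["bd0"]
    a = relu(pre0)
    cache["pre0"] = pre0
    if drop_masks is not None:
        a = a * drop_masks[0]
    cache["a0"] = a
    ups = []
    for i in range(config.n_stages - 1):
        pre = a @ params[f"Wu{i}"] + params[f"bu{i}"]
        up = _depth_to_space(pre)
        a2 = relu(up)
        if drop_masks is not None:
            a2 = a2 * drop_masks[i + 1]
        ups.append((a, pre, up, a2))
        a = a2
    cache["ups"] = ups
    preo = a @ params["Wo"] + params["bo"]
    out = _depth_to_space(preo)
    xhat = sigmoid(out)
    cache["a_last"], cache["xhat"] = a, xhat
    return xhat[..., 0], cache


def _decode_bwd(params, config, cache, dxhat):
    grads = {}
    xhat = cache["xhat"]
    drop = cache["drop"]
    dout = dxhat[..., None] * xhat * (1.0 - xhat)
    dpreo = _space_to_depth(dout)
    a_last = cache["a_last"]
    grads["Wo"] = np.einsum("bhwc,bhwd->cd", a_last, dpreo)
    grads["bo"] = dpreo.sum(axis=(0, 1, 2))
    da = dpreo @ params["Wo"].T
    for i in reversed(range(config.n_stages - 1)):
        a_in, pre, up, _ = cache["ups"][i]
        if drop is not None:
            da = da * drop[i + 1]
        dup = da * (up > 0)
        dpre = _space_to_depth(dup)
        grads[f"Wu{i}"] = np.einsum("bhwc,bhwd->cd", a_in, dpre)
        grads[f"bu{i}"] = dpre.sum(axis=(0, 1, 2))
        da = dpre @ params[f"Wu{i}"].T
    if drop is not None:
        da = da * drop[0]
    dpre0 = da * (cache["pre0"] > 0)
    grads["Wd0"] = np.einsum("bhwz,bhwd->zd", cache["Zq"], dpre0)
    grads["bd0"] = dpre0.sum(axis=(0, 1, 2))
    dZq = dpre0 @ params["Wd0"].T
    return grads, dZq


def _quantize_arrays(Z: np.ndarray, C: np.ndarray):
    """Nearest codebook vector per site; ties -> lowest index (argmin rule)."""
    flat = Z.reshape(-1, Z.shape[-1])
    # explicit differences keep small-integer arithmetic exact for tie-breaks
    d2 = ((flat[:, None, :] - C[None, :, :]) ** 2).sum(axis=-1)
    idx = np.argmin(d2, axis=1)
    Zq = C[idx].reshape(Z.shape)
    return Zq, idx.reshape(Z.shape[:-1])


def _drop_masks(config, rng, shapes):
    if config.dropout <= 0.0:
        return None
    keep = 1.0 - config.dropout
    return [rng.random(s).__lt__(keep).astype(float) / keep for s in shapes]


def _dropout_shapes(config, B, h, w):
    shapes = [(B, h, w, config.hidden)]
    hh, ww = h, w
    for _ in range(config.n_stages - 1):
        hh, ww = 2 * hh, 2 * ww
        shapes.append((B, hh, ww, config.hidden))
    return shapes


# ---------------------------------------------------------------- public ops

def encode(model: VqvaeModel, x: np.ndarray) -> np.ndarray:
    """Deterministically encode image(s) to the continuous latent grid."""
    single = x.ndim == 2
    xb = x[None] if single else x
    f = model.config.factor
    if xb.shape[1] % f or xb.shape[2] % f:
        raise ValueError(f"image size {xb.shape[1:]} not divisible by factor {f}")
    Z, _ = _encode_fwd(model.params, model.config, xb)
    return Z[0] if single else Z


def quantize(Z: np.ndarray, codebook: Codebook) -> QuantizedLatent:
    """Replace each latent site by its nearest codebook vector."""
    if Z.shape[-1] != codebook.n_z:
        raise ValueError("latent feature dimension does not match codebook")
    Zq, idx = _quantize_arrays(Z, codebook.vectors)
    return QuantizedLatent(Z=Z, Z_q=Zq, Z_iq=idx)


def embed(codebook: Codebook, Z_iq: np.ndarray) -> np.ndarray:
    """Look token indices back up in the codebook -> quantized latent."""
    if Z_iq.min() < 0 or Z_iq.max() >= codebook.K:
        raise ValueError("token indices out of codebook range")
    return codebook.vectors[Z_iq]


def decode(model: VqvaeModel, Z_q: np.ndarray, stochastic: bool = False,
           seed=None) -> np.ndarray:
    """Decode quantized latent(s) to image space.

    With ``stochastic=True`` dropout is active and seeded: different seeds
    give different reconstructions, the same seed reproduces bit-identical
    output.
    """
    single = Z_q.ndim == 3
    Zb = Z_q[None] if single else Z_q
    cfg = model.config
    if Zb.shape[-1] != cfg.n_z:
        raise ValueError("latent feature dimension mismatch")
    masks = None
    if stochastic:
        rng = np.random.default_rng(seed)
        masks = _drop_masks(cfg, rng, _dropout_shapes(cfg, Zb.shape[0],
                                                      Zb.shape[1], Zb.shape[2]))
    xhat, _ = _decode_fwd(model.params, cfg, Zb, masks)
    return xhat[0] if single else xhat


def reconstruct(model: VqvaeModel, x: np.ndarray) -> np.ndarray:
    """decode(quantize(encode(x))) convenience round trip (deterministic)."""
    Z = encode(model, x)
    q = quantize(Z, model.codebook)
    return decode(model, q.Z_q, stochastic=False)


def tokens_for(model: VqvaeModel, x: np.ndarray) -> np.ndarray:
    """Index grid(s) Z_iq for image(s) x."""
    Z = encode(model, x)
    Zq, idx = _quantize_arrays(Z, model.params["C"])
    return idx


# ---------------------------------------------------------------- training

def train_vqvae(dataset, config: VqvaeConfig = VqvaeConfig(),
                seed: int = 0) -> VqvaeModel:
    """Train on a ContaminatedDataset or an (N, H, W) image array.

    Returns the model with a per-epoch loss log; epoch 0 entries record the
    initial-state losses, so the reconstruction-improvement contract
    (final MSE < initial MSE) can be read straight off the log.
    """
    images = dataset if isinstance(dataset, np.ndarray) else dataset.images
    if len(images) == 0:
        raise ValueError("dataset is empty")
    images = np.asarray(images, dtype=float)
    f = 2 ** config.n_stages
    if images.shape[1] % f or images.shape[2] % f:
        raise ValueError("image size not divisible by downsampling factor")

    rng = np.random.default_rng(seed)
    params = init_params(config, rng)
    model = VqvaeModel(params=params, config=config)
    if config.epochs == 0:
        return model
    opt = Adam(params, lr=config.lr)
    n = len(images)
    h, w = images.shape[1] // f, images.shape[2] // f

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        used_codes = np.zeros(config.K, dtype=bool)
        ep = {"recon": 0.0, "codebook": 0.0, "commit": 0.0}
        last_Z = None
        for start in range(0, n, config.batch_size):
            xb = images[order[start:start + config.batch_size]]
            B = len(xb)
            Z, ce = _encode_fwd(params, config, xb)
            Zq, idx = _quantize_arrays(Z, params["C"])
            used_codes[np.unique(idx)] = True
            masks = _drop_masks(config, rng, _dropout_shapes(config, B, h, w))
            xhat, cd = _decode_fwd(params, config, Zq, masks)

            diff = xhat - xb
            l_rec = np.mean(diff * diff)
            l_cb = np.mean((Zq - Z) ** 2)
            l_commit = config.beta * l_cb
            if not np.isfinite(l_rec + l_cb):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch} (recon={l_rec}, cb={l_cb})")

            dxhat = 2.0 * diff / diff.size
            dec_grads, dZq = _decode_bwd(params, config, cd, dxhat)
            # straight-through + commitment pull on the encoder
            dZ = dZq + 2.0 * config.beta * (Z - Zq) / Z.size
            enc_grads = _encode_bwd(params, config, ce, dZ)
            # codebook loss gradient
            dC = np.zeros_like(params["C"])
            flatZ = Z.reshape(-1, config.n_z)
            np.add.at(dC, idx.ravel(),
                      2.0 * (params["C"][idx.ravel()] - flatZ) / Z.size)

            grads = {**enc_grads, **dec_grads, "C": dC}
            opt.step(grads)
            wgt = B / n
            ep["recon"] += l_rec * wgt
            ep["codebook"] += l_cb * wgt
            ep["commit"] += l_commit * wgt
            last_Z = flatZ

        if config.revive_dead_codes and last_Z is not None:
            dead = np.flatnonzero(~used_codes)
            if dead.size:
                picks = rng.integers(0, len(last_Z), size=dead.size)
                params["C"][dead] = (last_Z[picks]
                                     + 0.01 * rng.standard_normal((dead.size,
                                                                   config.n_z)))
        model.loss_log.append({"epoch": epoch, **ep})
    return model


# ---------------------------------------------------------------- checkpoints

def save_vqvae(model: VqvaeModel, path) -> None:
    """Single-archive checkpoint with the config embedded."""
    with open(Path(path), "wb") as f:
        np.savez(f, __config__=json.dumps(asdict(model.config)),
                 __loss_log__=json.dumps(model.loss_log), **model.params)


def load_vqvae(path) -> VqvaeModel:
    with np.load(Path(path), allow_pickle=False) as z:
        config = VqvaeConfig(**json.loads(str(z["__config__"])))
        log = json.loads(str(z["__loss_log__"]))
        params = {k: z[k] for k in z.files if not k.startswith("__")}
    return VqvaeModel(params=params, config=config, loss_log=log)
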